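# Methods

This note documents the models implemented in `solscreen`, the defaults
they ship with, and the design choices made where the design was
genuinely open.

## Intrinsic solubility profile

The per-residue profile `S_i` is built in three steps.

**Base propensity.** Each of the 20 standard residues gets a fixed value:
a weighted combination of four tabulated scales, each standardized
(z-scored) across the alphabet so the weights are comparable —

| scale | weight | sign | rationale |
|---|---|---|---|
| hydrophilicity (negated Kyte–Doolittle hydropathy) | 0.55 | + | burial-driven self-association is the dominant aggregation force |
| magnitude of net side-chain charge at neutral pH (D,E,K,R = 1; H = 0.1) | 0.25 | + | charged residues raise solubility regardless of sign |
| Chou–Fasman beta-sheet propensity | 0.15 | − | beta-formers nucleate ordered aggregates |
| Chou–Fasman alpha-helix propensity | 0.05 | − | weak penalty for strong secondary-structure formers |

The weighted sum is multiplied by an overall gain of 2
(`ProfileConfig.scale`) so that single-residue propensities span roughly
±2.6 and *sustained* charged or hydrophobic stretches still exceed the ±1
score thresholds after window averaging; without the gain, smoothing
compresses typical protein profiles entirely into the neutral band and
the aggregate score loses resolution.  The orientation is higher = more
soluble: K, R, D, E score positive, F, L, I, V, W negative.

These scales and weights are this package's own documented defaults.
They satisfy two calibration requirements: every charged residue scores
above every aliphatic hydrophobic one, and the downstream score-level
properties (threshold behaviour, ranking) hold.  They are configuration,
not fitted constants, and every piece is exposed in `ProfileConfig`.

**Smoothing.** `S_i` is the mean base propensity over a centred window of
7 residues.  At the termini the window shrinks symmetrically rather than
padding — padding would invent residues that are not there.  Window width
is configurable but must be odd.

**Corrections** (both on by default, individually toggleable so
properties can be tested term-by-term):

* *Gatekeeper bonus* (+0.2 per flank): where the smoothed value is
  negative and a charged residue (D, E, K, R) sits just beyond a window
  edge, the profile is raised — charged gatekeepers flanking hydrophobic
  stretches are a well-established aggregation brake.  The rule is
  symmetric in both flanks, which preserves the profile's reversal
  symmetry.
* *Hydrophobic-pattern penalty* (−0.3): every 5-residue stretch whose
  first, middle and last residues are hydrophobic (set
  {A,C,F,I,L,M,V,W,Y}) marks all five positions; marked positions are
  penalized once.  This targets the alternating hydrophobic patterns
  characteristic of beta-aggregation-prone segments.  The motif test is
  palindromic, again preserving reversal symmetry.

With corrections disabled the profile is a positive-weight moving average
of per-residue values, hence monotone: substituting any residue by one of
strictly higher propensity can never lower any `S_i`.

## Aggregate score

The score sums the profile's excursions beyond two thresholds and
normalizes by a power of the length:

    S_P = [ Σ_i  w_up (S_i − th_up)  · 1{S_i > th_up}
               + w_low (S_i − th_low) · 1{S_i < th_low} ] / (γ N^δ)

Defaults: `th_up = +1`, `th_low = −1` (profile regions above +1 behave as
aggregation-resistant, below −1 as aggregation-promoting), `w_up = w_low
= 1`, `γ = 1`, `δ = 1` (per-residue normalization: with δ = 1 a
duplicated profile scores the same as the original; with δ = 0 it scores
double).  Residues inside the neutral band contribute exactly zero.
Excursions are sorted before summation so the score depends only on the
multiset of profile values — permuting positions, or reordering chains in
the combined score, changes nothing, bit for bit.

**Combined-chains score.** For a multi-chain complex (e.g. an antibody's
VH + VL) the per-chain profiles are concatenated and scored with `N` the
total complex length.  Chain order is irrelevant (see above).

**Calibration.** Raw scores are dimensionless and their spread depends on
the profile configuration, so they are z-rescaled against an ensemble of
random sequences: `calibrated = (raw − μ_random)/σ_random` with μ, σ the
mean and population standard deviation of the raw score over the
ensemble.  The ensemble emulates the human proteome: residues i.i.d. from
UniProt human composition, lengths log-normal (median ≈ 376, log-sd 0.64,
truncated to [50, 2000]).  The default ensemble size is 10^5 sequences —
large enough that a fresh ensemble's calibrated mean is within ±0.013 of
zero with high probability — with a mandatory seed.  After calibration
the calibrating ensemble itself has mean 0 and sd 1 exactly, by
construction.  Parameter sets carry a version tag; scores are comparable
only within a version.

**Refitting.** `refit_parameters` re-derives the six coefficients on
user-supplied training data by uniform random search within bounds,
maximizing |Pearson R| against real-valued aggregation measurements plus
an exact pair-counting ROC AUC for binary soluble/insoluble labels.  The
initial parameters compete against all candidates, so the search never
returns something worse than its starting point; a fixed seed makes it
reproducible.  Simulated annealing and gradient methods were deliberately
avoided — the objective is cheap, the space is six-dimensional and
bounded, and uniform search is trivially auditable.

## Structural correction and hotspot ranking

A low intrinsic value only drives self-association if the residue is
solvent-accessible, so the structural profile is

    C_i = r_i · Σ_j w_ij S_j / Σ_j w_ij ,   w_ij = 1 − d_ij / cutoff

over residues j whose Cα lies within the cutoff (default 8 Å) of residue
i's Cα, the residue itself entering with weight 1.  `r_i ∈ [0, 1]` is the
Shrake–Rupley solvent-accessible surface area of the residue divided by
its maximal accessibility in an extended Gly-X-Gly tripeptide
(theoretical reference values), clamped to [0, 1].  Buried residues get
`C_i = 0`; in the limit cutoff → 0 with full exposure, `C` reduces to the
intrinsic profile.  Whether exposure should enter multiplicatively, and
whether smoothing should use side-chain centroids instead of Cα, are open
modelling questions; the multiplicative-Cα form is this package's
documented choice, and both the cutoff and the weighting are
configurable.  Residues with missing heavy atoms keep an exposure
estimate computed from the atoms present (a lower bound) and are flagged
rather than dropped.

Hotspot ranking sorts residues ascending by `C_i` after three explicit
filters: restriction to positions that differ from a reference variant
(when comparing a problematic antibody with a well-behaved relative),
minimum relative exposure (default 0.2), and optionally hydrophobic
residue types only — the same hydrophobic set as the pattern penalty, for
consistency.  An empty post-filter candidate list is reported, not an
error.

## PEG-precipitation analysis

The assay drives protein out of solution with increasing PEG; "soluble"
is operational — whatever passes a 0.2 μm filter — and the module never
reinterprets it thermodynamically.

**Sigmoid fit.** `y/c0 = a/(1 + e^{s(x − PEG_1/2)}) + b`, fitted by
bounded least squares (`scipy.optimize.least_squares`, trust-region
reflective) to the replicate means per PEG level — the plotted quantity —
with raw replicates retained for the bootstrap.  Bounds: `a ∈ (0.9, 1.1)`
fixed to 1 when no clear upper plateau exists (auto rule: lowest-PEG mean
fractional solubility < 0.9), `b ∈ (0, 0.1)`, `s > 0`, midpoint free
within the measured range ± one range-width (outside the measured range
it is flagged extrapolated).  Initialization: midpoint at the steepest
observed decrease, slope from the secant there (|f′| = s/4 at the
midpoint), plus five deterministically jittered restarts keeping the best
residual.  Monotonically non-decreasing or flat series raise a
"no transition" error rather than returning a meaningless fit.

**Bootstrap CIs.** Replicate measurements are resampled within the
machinery of two schemes, both centring each replicate on its PEG-level
mean and rescaling deviations by √(n/(n−1)) so the resampled level-mean
variance is unbiased at triplicate scale:

* `pooled` (default): centred deviations pooled across all PEG levels
  before resampling.  With triplicates, each level's spread estimate has
  only 2 degrees of freedom; conditioning on it yields intervals that are
  systematically short whenever a level's replicates happen to agree.
  Pooling borrows strength across levels (with 17 levels, ~34 df) and
  restores near-nominal coverage while remaining fully nonparametric.
* `case`: classical within-level case resampling — robust to strong
  across-level heteroscedasticity, at the cost of the degree-of-freedom
  starvation above.  Available for data where plateau and transition
  noise differ grossly.

Each resample is refitted starting from the original estimate; failures
are counted, reported, and excluded.  Intervals: percentile (default),
basic, or t (estimate ± t_df × bootstrap sd).  The default cycle count is
10^4.

Even with the pooled scheme, bootstrap intervals for a nonlinear
functional like the midpoint remain mildly anti-conservative at
triplicate scale: simulation at the package's default panel conditions
puts realized coverage of the nominal 95% interval around 90–92%, and the
residual gap is conditional-curvature undercoverage of the fit itself (it
persists even when the noise level is supplied exactly).  Users needing
strictly conservative intervals should raise replicate counts or use the
t-interval variant.

**Apparent solubility.** Points whose *fitted* fractional solubility lies
strictly between 5% and 95% of the transition amplitude are fitted with
`ln y = m x + q`; `exp(q)` is the zero-PEG intercept in mg/mL, with a CI
from the linear-fit covariance.  The log base is irrelevant (affine
reparameterization).  Fewer than three usable points flags the result
unreliable — the extrapolation is genuinely ill-conditioned for very
soluble proteins, where tiny displacements in the transition move the
intercept by large factors — and fewer than two is an error.

## Screening statistics

Pearson correlations use the product-moment estimate with the two-sided
t-transform p-value (t = R√((n−2)/(1−R²)), n−2 df).  Exclusions are
explicit: excluded ids are carried in every result record, and the
apparent solubility is natural-log-transformed before correlating with
the midpoint (R is invariant to the log base).  Outlier flagging uses
leave-one-out externally studentized prediction residuals against a
configurable threshold (default 2.5) — a systematic version of spotting
the point that sits far off everyone else's regression line.

Two-dimensional ranking requires the caller to declare each column's
orientation (an off-rate is lower-is-better; a solubility score
higher-is-better) — silently guessing would be worse than failing.
Candidates are stratified into non-domination levels (level 1 = Pareto
front) and ordered within a level by normalized Euclidean distance to the
ideal point.  Rank agreement between predicted and observed orderings is
a Kendall-type statistic computed by exhaustive pair counting (ties
contribute zero, normalization by all n(n−1)/2 pairs), appropriate when
agreement is monotone but not linear.

## Synthetic data

The generators define the conditions under which the package is tested;
all are pure functions of (spec, seed).

* **Antibody library**: a parent pair of chains (VH 120 aa, VL 110 aa,
  human-proteome residue composition) plus derived variants.  Each
  variant mutates its own *disjoint* set of positions (70% on the heavy
  chain, as in panels where diversity concentrates in VH), so the
  pairwise mutation count between variants a and b is exactly k_a + k_b —
  the distance matrix is guaranteed constructively, never by rejection
  sampling, and infeasible requests fail loudly.  The bundled default
  uses per-variant counts (0, 7, 14, 13, 8, 6, 5, 13, 18), giving 36
  pairwise totals with minimum 5 (variants 1 & 7), unique maximum 32
  (variants 3 & 9) and median 19 — the mutation structure of a realistic
  nine-antibody screening panel.
* **PEG panels**: sigmoid curves plus i.i.d. Gaussian replicate noise
  (default sd 0.02 in fractional units, triplicates, truncated at zero),
  on a 0–16% grid in 1% steps, or 0–8% in 0.5% steps for midpoints below
  2.5% — emulating how assay ranges are widened for poorly soluble
  variants.  The default nine-variant panel uses the bundled reference
  panel's measured midpoints as generating values.
* **Toy structures**: ideal-geometry CA/CB traces — an alpha helix
  (rise 1.5 Å, 100°/residue), an extended strand, and a "globule" of CA
  atoms on a 3.8 Å cubic lattice filling a ball, with designated buried
  positions mapped to the innermost lattice sites.  These are
  deliberately coarse: they exercise exposure computation, spatial
  smoothing and hotspot logic exactly, but they are not protein-like
  beyond local geometry.

**What passing tests on synthetic data do and do not show.**  The
generators share their model classes with the fitting code (the PEG
generator *is* the sigmoid; the library generator guarantees its own
distance matrix), so round-trip tests demonstrate correctness of the
estimation machinery, not real-world predictive validity.  Real replicate
noise is not exactly Gaussian, real libraries do not have disjoint
mutation sets, and real structures are not lattices.  The bundled
reference panel — printed characterization values of nine real
antibodies — is the one place where the package's statistics meet real
measurements: the correlation, outlier and concordance analyses are
validated against it.

## Numerical choices and degenerate inputs

* Sequences: strictly the 20 standard one-letter codes; gaps stripped on
  read; non-standard codes rejected with position and character.
  Mutation counting demands equal lengths — silent alignment would change
  counts invisibly.
* Profile values are finite by construction; empty sequences, even
  windows, and non-positive cutoffs are errors.
* Score parameters validate `th_low < th_up`, positive weights, γ and
  σ_random; a zero-variance calibration ensemble is an error, not a NaN.
* Sigmoid exponents are clipped at ±500 to avoid overflow far from the
  midpoint; all-equal and monotonically increasing series are rejected.
* The structural module resolves altlocs to highest occupancy, keeps the
  first model of multi-model files, and appends insertion codes to
  residue ids.
* Ensemble sizes: calibration defaults to 10^5 sequences (the calibrated
  scale is insensitive to further growth; the fresh-ensemble mean bound
  scales as n^{−1/2}).

## Known limitations

The per-residue scales are plausible but not fitted to aggregation data —
`refit_parameters` exists precisely so users with measurements can
recalibrate.  The structural correction is a local smoothing, blind to
quaternary context and conformational flexibility.  Homology models are
consumed, not built.  Thermal-stability columns in screening tables are
carried as metadata only.  Apparent-solubility extrapolations beyond the
measured concentration range should be read as order-of-magnitude
estimates; the midpoint `PEG_1/2` is the robust solubility proxy.
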