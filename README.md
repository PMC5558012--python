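# solscreen

In-silico solubility screening of antibody (and general protein) libraries.

Screening campaigns — phage display, ribosome display, targeted
mutagenesis — typically yield many candidates that bind a target well, but
binding strength alone is a poor basis for lead selection: candidates with
insufficient solubility aggregate under storage conditions and fail late,
expensively, in development.  `solscreen` supports selecting leads on two
axes at once — measured binding and *predicted* solubility — so that
developability enters the funnel at the sequencing stage, when thousands of
variants can still be compared.

The package provides:

* **Intrinsic solubility profiles** — one dimensionless number `S_i` per
  residue, computed from sequence alone (window-smoothed physicochemical
  propensities with gatekeeper and hydrophobic-pattern corrections).
  Regions with `S_i > 1` behave as aggregation-resistant, `S_i < -1` as
  aggregation-promoting.
* **Aggregate solubility scores** — the profile's excursions beyond the
  thresholds, summed and length-normalized,

  ```
        sum_i [ w_up (S_i - th_up)  if S_i > th_up
                w_low (S_i - th_low) if S_i < th_low
                0                    otherwise ]
  S_P = -----------------------------------------------
                     gamma * N^delta
  ```

  then z-rescaled against a random-sequence ensemble with human-proteome
  composition so that a random protein scores 0 +/- 1.  A combined-chains
  score concatenates per-chain profiles (e.g. VH + VL) with `N` the total
  complex length; it is invariant to chain order.
* **Structurally-corrected profiles** — `C_i = r_i * <S_j>_neighbours`,
  the intrinsic profile weighted by relative solvent exposure `r_i` and
  smoothed over spatial neighbours on a 3D model, for mapping aggregation
  hotspots on the protein surface and ranking candidate mutation sites.
* **PEG-precipitation assay analysis** — bounded least-squares fits of
  `y/c0 = a / (1 + exp(s (x - PEG_1/2))) + b` to soluble-concentration
  curves, bootstrap confidence intervals, and log-linear back-extrapolation
  of the apparent solubility at zero PEG.
* **Screening statistics** — Pearson correlations with explicit outlier
  handling, leave-one-out studentized-residual outlier flagging, Pareto
  non-domination ranking over binding x solubility, and a pair-counting
  rank-concordance statistic.
* **Synthetic data** — generators for antibody libraries with exact
  pairwise mutation structure, sigmoidal assay panels with replicate
  noise, and toy helix/sheet/globule structures, so the full pipeline runs
  without any external data.  A nine-variant reference characterization
  table (predicted scores and measured solubilities of an anti-NGF
  antibody panel) ships with the package.

## Worked example

```python
from solscreen import (
    intrinsic_profile, combined_score, correlate, flag_outliers,
    load_reference_panel,
)

# Compare a parent VH fragment with a variant carrying a hydrophobic CDR1
parent = intrinsic_profile("EVQLVESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGLEWVS")
mutant = intrinsic_profile("EVQLVESGGGLVQPGGSLRLSCAASGFTFWFLYAMSWVRQAPGKGLEWVS")
vl = intrinsic_profile("DIQMTQSPSSLSASVGDRVTITCRASQSISSYLNWYQQKPGKA")
print(round(combined_score([parent, vl]).raw, 4))   # -0.001
print(round(combined_score([mutant, vl]).raw, 4))   # -0.0329
```

The S→W, S→F, S→L substitutions in the binding loop lower the combined
score from -0.001 to -0.0329: the mutant is predicted markedly less
soluble, exactly the kind of difference the two-dimensional screening
surfaces before a lead is picked.

```python
# Validate predicted scores against measured solubility on the bundled panel
panel = load_reference_panel()
print(flag_outliers(panel, "score_vh", "peg_half"))   # {'mAb3'}
res = correlate(panel, "score_vh", "peg_half", exclude={"mAb3"})
print(round(res.r, 2), res.n)                  # 0.97 8
res_all = correlate(panel, "score_vh", "peg_half")
print(round(res_all.r, 2))                     # 0.79
```

On the bundled panel the VH-domain score correlates with the measured
PEG-precipitation midpoint at R = 0.97 across eight of the nine variants;
mAb3, flagged automatically by its leave-one-out studentized residual, is
predicted more soluble than it measures — including it lowers the
correlation to 0.79.

A command-line interface mirrors the library:

```
solscreen profile variants.fasta        # per-residue S_i table
solscreen score variants.fasta --combine
solscreen mutations variants.fasta     # pairwise mutation counts
solscreen peg-fit assay.tsv --bootstrap 10000
solscreen screen --predictor score_vh --response peg_half --exclude mAb3
```

## Limitations

The profile's per-residue scales are this package's own documented
defaults, chosen to satisfy stated orientation and calibration
requirements; scores are comparable only within one parameter-set version.
Structural correction consumes externally built models (it does no
homology modelling), and the apparent-solubility extrapolation is
intrinsically noisy for highly soluble proteins — results with fewer than
three usable transition points are flagged unreliable.  See
`docs/methods.md` for the full model description and design rationale.
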