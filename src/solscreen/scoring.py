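"""Aggregate solubility score and its random-ensemble calibration.

The aggregate score S_P of a protein collapses its per-residue profile into
a single number by summing the excursions of the profile beyond two
thresholds and normalizing by a power of the length::

    S_P = [ sum_i  w_up*(S_i - th_up)  if S_i > th_up
                   w_low*(S_i - th_low) if S_i < th_low
                   0                    otherwise      ] / (gamma * N**delta)

Residues whose profile value lies inside [th_low, th_up] contribute exactly
zero: only pronounced soluble (S_i > th_up) or aggregation-prone
(S_i < th_low) regions move the score.  With delta = 1 the score is an
average excursion per residue, invariant under duplication of a profile.

Because S_P is dimensionless and its scale depends on the chosen profile
coefficients, scores are z-rescaled against a large ensemble of random
sequences drawn with the amino-acid frequencies and length distribution of
the human proteome, so that the calibrated score of a random protein is 0
on average with unit standard deviation.

The combined-chains score of a multi-chain complex applies the same
formula to the concatenated per-chain profiles, with N the total residue
count; it is invariant under permutation of the chain order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .seqio import Chain, STANDARD_AA
from .profiles import (
    DEFAULT_CONFIG,
    ProfileConfig,
    SolubilityProfile,
    intrinsic_profile,
    joined_profile,
)

# Amino-acid frequencies of the human proteome (UniProt reference
# proteome composition, renormalized over the 20 standard residues).
HUMAN_PROTEOME_FREQS = {
    "A": 0.0701, "R": 0.0564, "N": 0.0359, "D": 0.0473, "C": 0.0230,
    "Q": 0.0477, "E": 0.0710, "G": 0.0657, "H": 0.0263, "I": 0.0434,
    "L": 0.0996, "K": 0.0572, "M": 0.0213, "F": 0.0365, "P": 0.0631,
    "S": 0.0833, "T": 0.0536, "W": 0.0122, "Y": 0.0266, "V": 0.0598,
}


@dataclass(frozen=True)
class ScoreParameters:
    """Coefficients of the aggregate score plus calibration constants.

    th_up / th_low bound the neutral band of the profile; omega_up /
    omega_low weight the positive and negative excursions; gamma and delta
    control length normalization.  mu_random / sigma_random are the mean
    and standard deviation of the raw score over a random-sequence
    ensemble, used for z-rescaling.  `version` tags the parameter set:
    calibrated scores are comparable only within one version.
    """

    th_up: float = 1.0
    th_low: float = -1.0
    omega_up: float = 1.0
    omega_low: float = 1.0
    gamma: float = 1.0
    delta: float = 1.0
    mu_random: float = 0.0
    sigma_random: float = 1.0
    version: str = "default-v2"

    def __post_init__(self):
        if self.th_low >= self.th_up:
            raise ValueError("th_low must be < th_up")
        if self.omega_up <= 0 or self.omega_low <= 0:
            raise ValueError("omega_up and omega_low must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.sigma_random <= 0:
            raise ValueError("sigma_random must be > 0")


DEFAULT_PARAMETERS = ScoreParameters()


@dataclass(frozen=True)
class SolubilityScore:
    """Raw and calibrated aggregate score of a chain or chain set."""

    chain_id: str
    raw: float
    calibrated: float
    version: str


def raw_score(
    profile: SolubilityProfile | np.ndarray,
    params: ScoreParameters = DEFAULT_PARAMETERS,
) -> float:
    """Aggregate a profile into the raw (uncalibrated) score S_P."""
    values = profile.values if isinstance(profile, SolubilityProfile) else np.asarray(profile, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("empty profile")
    up = values - params.th_up
    low = values - params.th_low
    # sort the excursions before summing so the result depends only on the
    # multiset of profile values: permuting positions or reordering chains
    # then leaves the score bit-for-bit identical
    total = (
        params.omega_up * np.sort(up[up > 0]).sum()
        + params.omega_low * np.sort(low[low < 0]).sum()
    )
    return float(total / (params.gamma * n**params.delta))


def calibrated_score(
    profile: SolubilityProfile,
    params: ScoreParameters = DEFAULT_PARAMETERS,
) -> SolubilityScore:
    raw = raw_score(profile, params)
    return SolubilityScore(
        chain_id=profile.chain_id,
        raw=raw,
        calibrated=(raw - params.mu_random) / params.sigma_random,
        version=params.version,
    )


def combined_score(
    profiles: Sequence[SolubilityProfile],
    params: ScoreParameters = DEFAULT_PARAMETERS,
) -> SolubilityScore:
    """Aggregate score of a multi-chain complex.

    The per-chain profiles are concatenated and scored with N equal to the
    total residue count of the complex; since the score is a sum over
    positions, the chain order does not affect the result.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    return calibrated_score(joined_profile(list(profiles)), params)


@dataclass(frozen=True)
class RandomEnsemble:
    """Specification of a random-sequence ensemble for calibration.

    Residues are drawn i.i.d. from `frequencies`; lengths from `lengths`
    (an empirical list sampled uniformly with replacement, the default
    emulating the human-proteome length distribution with a log-normal
    law truncated to [50, 2000]).
    """

    frequencies: dict = field(default_factory=lambda: dict(HUMAN_PROTEOME_FREQS))
    n: int = 100_000
    seed: int = 0
    length_log_mean: float = 5.93   # median length ~ exp(5.93) ~ 376
    length_log_sd: float = 0.64
    length_min: int = 50
    length_max: int = 2000
    lengths: tuple | None = None    # explicit empirical lengths, if given

    def __post_init__(self):
        freqs = np.array([self.frequencies[aa] for aa in STANDARD_AA])
        if np.any(freqs < 0) or not np.isclose(freqs.sum(), 1.0, atol=1e-6):
            raise ValueError("frequencies must be nonnegative and sum to 1")
        if self.n < 1:
            raise ValueError("ensemble size must be >= 1")


def generate_random_ensemble(spec: RandomEnsemble) -> list[Chain]:
    """Draw the random sequences described by `spec` (reproducible by seed)."""
    rng = np.random.default_rng(spec.seed)
    freqs = np.array([spec.frequencies[aa] for aa in STANDARD_AA])
    freqs = freqs / freqs.sum()
    if spec.lengths is not None:
        lengths = rng.choice(np.asarray(spec.lengths, dtype=int), size=spec.n)
    else:
        raw = rng.lognormal(spec.length_log_mean, spec.length_log_sd, size=spec.n)
        lengths = np.clip(raw.round().astype(int), spec.length_min, spec.length_max)
    alphabet = np.frombuffer(STANDARD_AA.encode(), dtype=np.uint8)
    chains = []
    for k, length in enumerate(lengths):
        codes = rng.choice(alphabet, size=int(length), p=freqs)
        chains.append(Chain(id=f"rnd{k}", sequence=codes.tobytes().decode("ascii")))
    return chains


def ensemble_raw_scores(
    chains: Sequence[Chain],
    params: ScoreParameters = DEFAULT_PARAMETERS,
    config: ProfileConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Raw scores of an ensemble (vector, one value per chain)."""
    return np.array(
        [raw_score(intrinsic_profile(c, config=config), params) for c in chains]
    )


def calibrate(
    params: ScoreParameters,
    ensemble: Sequence[Chain],
    config: ProfileConfig = DEFAULT_CONFIG,
) -> ScoreParameters:
    """Set mu_random / sigma_random from the raw scores of an ensemble.

    After calibration the calibrated scores of the SAME ensemble have mean
    0 and standard deviation 1 exactly (population standard deviation).
    """
    if len(ensemble) < 2:
        raise ValueError("ensemble must contain at least 2 sequences")
    raws = ensemble_raw_scores(ensemble, params, config)
    mu = float(raws.mean())
    sigma = float(raws.std())
    if sigma == 0.0:
        raise ValueError("degenerate ensemble: raw scores have zero variance")
    return replace(params, mu_random=mu, sigma_random=sigma)


def save_parameters(params: ScoreParameters, path) -> None:
    """Serialize a parameter set as a key-value config file."""
    with open(path, "w") as fh:
        for key in ("th_up", "th_low", "omega_up", "omega_low", "gamma",
                    "delta", "mu_random", "sigma_random", "version"):
            fh.write(f"{key} = {getattr(params, key)}\n")


def load_parameters(path) -> ScoreParameters:
    """Read a parameter set written by :func:`save_parameters`."""
    kwargs = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            kwargs[key] = value if key == "version" else float(value)
    return ScoreParameters(**kwargs)


# --- Parameter refitting ---------------------------------------------------

@dataclass(frozen=True)
class ParameterBounds:
    """Uniform search box for `refit_parameters` (low, high) per coefficient."""

    th_up: tuple = (0.5, 2.0)
    th_low: tuple = (-2.0, -0.5)
    omega_up: tuple = (0.1, 5.0)
    omega_low: tuple = (0.1, 5.0)
    gamma: tuple = (0.5, 2.0)
    delta: tuple = (0.0, 1.5)

    def __post_init__(self):
        if self.th_low[0] >= self.th_up[1]:
            raise ValueError("th_low bounds must lie below th_up bounds")


def _auc_by_pair_counting(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exact ROC AUC by counting concordant positive/negative pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both positive and negative labels")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg)))


def refit_objective(
    params: ScoreParameters,
    regression_profiles: Sequence[SolubilityProfile],
    measurements: np.ndarray,
    binary_profiles: Sequence[SolubilityProfile],
    labels: np.ndarray,
) -> float:
    """Composite fitting objective: |Pearson R| + ROC AUC.

    The regression term rewards correlation of the raw score with
    real-valued aggregation measurements; the discrimination term rewards
    separating soluble (label 1) from insoluble (label 0) sequences.
    """
    scores_r = np.array([raw_score(p, params) for p in regression_profiles])
    scores_b = np.array([raw_score(p, params) for p in binary_profiles])
    sd_s, sd_m = scores_r.std(), np.asarray(measurements, dtype=float).std()
    if sd_s == 0 or sd_m == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(scores_r, measurements)[0, 1])
    return abs(r) + _auc_by_pair_counting(scores_b, np.asarray(labels))


def refit_parameters(
    initial: ScoreParameters,
    regression_profiles: Sequence[SolubilityProfile],
    measurements: Sequence[float],
    binary_profiles: Sequence[SolubilityProfile],
    labels: Sequence[int],
    bounds: ParameterBounds = ParameterBounds(),
    iterations: int = 200,
    seed: int = 0,
) -> ScoreParameters:
    """Monte-Carlo recalibration of the score coefficients.

    Uniform random search within `bounds`, keeping the candidate with the
    highest composite objective; the initial parameters compete, so the
    result is never worse than the starting point.  Deterministic under a
    fixed seed.  iterations=0 returns `initial` unchanged.
    """
    if len(regression_profiles) == 0 or len(binary_profiles) == 0:
        raise ValueError("empty training data")
    measurements = np.asarray(list(measurements), dtype=float)
    labels = np.asarray(list(labels), dtype=int)
    rng = np.random.default_rng(seed)
    best = initial
    best_obj = refit_objective(
        initial, regression_profiles, measurements, binary_profiles, labels
    )
    for _ in range(iterations):
        while True:
            th_up = rng.uniform(*bounds.th_up)
            th_low = rng.uniform(*bounds.th_low)
            if th_low < th_up:
                break
        cand = ScoreParameters(
            th_up=th_up,
            th_low=th_low,
            omega_up=rng.uniform(*bounds.omega_up),
            omega_low=rng.uniform(*bounds.omega_low),
            gamma=rng.uniform(*bounds.gamma),
            delta=rng.uniform(*bounds.delta),
            version=initial.version + "-refit",
        )
        obj = refit_objective(
            cand, regression_profiles, measurements, binary_profiles, labels
        )
        if obj > best_obj:
            best, best_obj = cand, obj
    return best
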