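"""Per-residue intrinsic solubility profiles computed from sequence alone.

The profile assigns one dimensionless number per amino acid, oriented so
that HIGHER means more soluble.  Each residue carries a base propensity — a
fixed linear combination of four tabulated physicochemical scales
(hydrophilicity as the negated Kyte–Doolittle hydropathy, magnitude of net
side-chain charge at neutral pH, and Chou–Fasman alpha-helix and beta-sheet
propensities, the last two entering with negative weight because
secondary-structure formers promote ordered self-association).  Each scale
is standardized across the 20 residues before weighting, so the base
propensities have zero mean and a spread of order one by construction.

The per-residue profile value S_i is the base propensity smoothed over a
centred window (default 7 residues, shrinking symmetrically at the
termini), plus two local corrections:

* a *gatekeeper bonus* when charged residues (D, E, K, R) flank a window
  whose smoothed propensity is negative — charged gatekeepers are known to
  disrupt aggregation nuclei at the edges of hydrophobic stretches;
* a *hydrophobic-pattern penalty* for stretches of five consecutive
  positions whose first, middle and last residues are all hydrophobic — an
  alternating pattern characteristic of beta-aggregation-prone segments.

Both corrections are toggleable so profile properties can be tested
term-by-term.  Regions with S_i > 1 behave as aggregation-resistant and
S_i < -1 as aggregation-promoting in the downstream aggregate score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqio import Chain, STANDARD_AA

# --- Tabulated per-residue scales -----------------------------------------

#: Kyte-Doolittle hydropathy (higher = more hydrophobic).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Net side-chain charge at neutral pH (His carries a small average charge).
NET_CHARGE = {aa: 0.0 for aa in STANDARD_AA}
NET_CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1})

#: Chou-Fasman alpha-helix propensity P_alpha.
CHOU_FASMAN_ALPHA = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
    "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
}

#: Chou-Fasman beta-sheet propensity P_beta.
CHOU_FASMAN_BETA = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19,
    "Q": 1.10, "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60,
    "L": 1.30, "K": 0.74, "M": 1.05, "F": 1.38, "P": 0.55,
    "S": 0.75, "T": 1.19, "W": 1.37, "Y": 1.47, "V": 1.70,
}

#: Hydrophobic residues used by the pattern penalty (shared with the
#: structural module's hydrophobic filter).
HYDROPHOBIC_SET = frozenset("ACFILMVWY")

#: Charged gatekeeper residues.
CHARGED_SET = frozenset("DEKR")


def _zscore_scale(scale: dict[str, float]) -> dict[str, float]:
    vals = np.array([scale[aa] for aa in STANDARD_AA])
    mu, sd = vals.mean(), vals.std()
    return {aa: (scale[aa] - mu) / sd for aa in STANDARD_AA}


@dataclass(frozen=True)
class ProfileConfig:
    """Parameters of the intrinsic profile calculation.

    Weights apply to the standardized scales; they sum to 1 in the default
    configuration, which keeps base propensities on a z-score-like scale.
    """

    window: int = 7
    weight_hydrophilicity: float = 0.55
    weight_charge_magnitude: float = 0.25
    weight_beta: float = 0.15   # subtracted
    weight_alpha: float = 0.05  # subtracted
    # overall gain: the weights above sum to 1, so single-residue
    # propensities span roughly +/-1.3 before smoothing; the gain maps
    # sustained charged or hydrophobic stretches beyond the +/-1 score
    # thresholds after window averaging
    scale: float = 2.0
    gatekeeper: bool = True
    gatekeeper_bonus: float = 0.2
    pattern: bool = True
    pattern_penalty: float = 0.3
    hydrophobic: frozenset = HYDROPHOBIC_SET
    charged: frozenset = CHARGED_SET

    def __post_init__(self):
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")


DEFAULT_CONFIG = ProfileConfig()


def _propensity_map(config: ProfileConfig) -> dict[str, float]:
    hyd = _zscore_scale({aa: -v for aa, v in KYTE_DOOLITTLE.items()})
    chg = _zscore_scale({aa: abs(v) for aa, v in NET_CHARGE.items()})
    alpha = _zscore_scale(CHOU_FASMAN_ALPHA)
    beta = _zscore_scale(CHOU_FASMAN_BETA)
    return {
        aa: config.scale
        * (
            config.weight_hydrophilicity * hyd[aa]
            + config.weight_charge_magnitude * chg[aa]
            - config.weight_beta * beta[aa]
            - config.weight_alpha * alpha[aa]
        )
        for aa in STANDARD_AA
    }


# Lookup tables cached per config (the default path hits the cache).
_PROPENSITY_CACHE: dict[tuple, tuple[dict, np.ndarray, np.ndarray, np.ndarray]] = {}


def _tables(config: ProfileConfig):
    key = (
        config.weight_hydrophilicity, config.weight_charge_magnitude,
        config.weight_beta, config.weight_alpha, config.scale,
        config.hydrophobic, config.charged,
    )
    if key not in _PROPENSITY_CACHE:
        pmap = _propensity_map(config)
        prop = np.zeros(128)
        hyd = np.zeros(128, dtype=bool)
        chg = np.zeros(128, dtype=bool)
        for aa in STANDARD_AA:
            prop[ord(aa)] = pmap[aa]
            hyd[ord(aa)] = aa in config.hydrophobic
            chg[ord(aa)] = aa in config.charged
        _PROPENSITY_CACHE[key] = (pmap, prop, hyd, chg)
    return _PROPENSITY_CACHE[key]


def residue_propensity(aa: str, config: ProfileConfig = DEFAULT_CONFIG) -> float:
    """Base solubility propensity of a single residue (higher = more soluble)."""
    if len(aa) != 1 or aa.upper() not in STANDARD_AA:
        raise ValueError(f"unknown amino-acid code {aa!r}")
    return _tables(config)[0][aa.upper()]


@dataclass(frozen=True)
class SolubilityProfile:
    """Per-residue intrinsic solubility values aligned to a chain.

    ``values[i]`` is S_{i+1} (1-based residue numbering in reports).
    """

    chain_id: str
    sequence: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if len(v) != len(self.sequence):
            raise ValueError("profile length must match sequence length")
        if not np.all(np.isfinite(v)):
            raise ValueError("profile values must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path) -> None:
        """Write (position, residue, value) as a tab-separated table."""
        with open(path, "w") as fh:
            fh.write("position\tresidue\tS\n")
            for i, (aa, s) in enumerate(zip(self.sequence, self.values), start=1):
                fh.write(f"{i}\t{aa}\t{s:.6f}\n")


def _sliding_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with symmetric shrinkage at the termini."""
    n = len(x)
    h = window // 2
    cs = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    return (cs[hi + 1] - cs[lo]) / (hi - lo + 1)


def intrinsic_profile(
    chain: Chain | str,
    window: int | None = None,
    config: ProfileConfig = DEFAULT_CONFIG,
) -> SolubilityProfile:
    """Compute the intrinsic solubility profile of a chain.

    Deterministic: the same sequence and configuration always produce an
    identical profile.  Output length equals sequence length.
    """
    if window is not None and window != config.window:
        config = replace(config, window=window)
    seq = chain.sequence if isinstance(chain, Chain) else chain
    cid = chain.id if isinstance(chain, Chain) else "<anonymous>"
    if not seq:
        raise ValueError("empty sequence")
    values = _profile_values(seq, config)
    return SolubilityProfile(chain_id=cid, sequence=seq, values=values)


def _profile_values(seq: str, config: ProfileConfig) -> np.ndarray:
    _, prop_tab, hyd_tab, chg_tab = _tables(config)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    base = prop_tab[codes]
    n = len(base)

    s = _sliding_mean(base, config.window)

    if config.gatekeeper and config.gatekeeper_bonus != 0.0:
        charged = chg_tab[codes].astype(float)
        h = config.window // 2
        flanks = np.zeros(n)
        # charged residue just beyond each window edge, symmetric in +/-
        if n > h + 1:
            flanks[: n - (h + 1)] += charged[h + 1 :]
            flanks[h + 1 :] += charged[: n - (h + 1)]
        s = s + np.where(s < 0, config.gatekeeper_bonus * flanks, 0.0)

    if config.pattern and config.pattern_penalty != 0.0 and n >= 5:
        hyd = hyd_tab[codes]
        # 5-residue motif with hydrophobic first, middle and last position
        starts = hyd[:-4] & hyd[2:-2] & hyd[4:]
        marked = np.zeros(n, dtype=bool)
        for off in range(5):
            marked[off : off + len(starts)] |= starts
        s = s - config.pattern_penalty * marked

    return s


def joined_profile(profiles: list[SolubilityProfile]) -> SolubilityProfile:
    """Concatenate per-chain profiles into one multi-chain profile.

    Used by the combined-chains aggregate score; N becomes the total number
    of residues in the complex.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    return SolubilityProfile(
        chain_id="+".join(p.chain_id for p in profiles),
        sequence="".join(p.sequence for p in profiles),
        values=np.concatenate([p.values for p in profiles]),
    )
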