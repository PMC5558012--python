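"""PEG-precipitation assay analysis.

In a PEG-precipitation assay increasing amounts of polyethylene glycol
drive protein out of solution by excluded-volume competition; the soluble
concentration remaining after filtration (0.2 um filter) is measured at
each PEG level.  The resulting curve is sigmoidal and is fitted with

    y / c0 = a / (1 + exp(s * (x - PEG_half))) + b

where x is percent PEG (w/v), c0 the starting concentration, s > 0 the
slope and PEG_half the midpoint — the percent PEG at which half the
protein remains soluble, used as a relative-solubility proxy.  The
plateau parameters are constrained to a in (0.9, 1.1) and b in (0, 0.1);
for poorly soluble proteins that show no clear upper plateau, a is fixed
to 1 (the `fix_a='auto'` rule applies this whenever the lowest-PEG mean
fractional solubility falls below 0.9).

Uncertainty on the fitted parameters is estimated by case-resampling
bootstrap: replicates are resampled with replacement within each PEG
level, the curve is refitted, and percentile confidence intervals are
taken over the resampled estimates.

The apparent solubility extrapolates the log-linear transition region
back to zero PEG: points whose fitted fractional solubility lies strictly
between the plateaus are fitted with log(y) = m*x + q, and exp(q) is the
zero-PEG intercept in mg/mL.  This extrapolation is intrinsically noisy —
small displacements of the transition points move the intercept a lot —
so results based on fewer than three transition points are flagged
unreliable rather than silently reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "PEGSeries",
    "SigmoidFitResult",
    "ApparentSolubilityResult",
    "sigmoid",
    "fit_sigmoid",
    "bootstrap_ci",
    "apparent_solubility",
    "read_peg_table",
]


def sigmoid(x, a, b, s, peg_half):
    """Decreasing logistic: a / (1 + exp(s*(x - peg_half))) + b."""
    x = np.asarray(x, dtype=float)
    # clip the exponent to avoid overflow far from the midpoint
    z = np.clip(s * (x - peg_half), -500.0, 500.0)
    return a / (1.0 + np.exp(z)) + b


@dataclass(frozen=True)
class PEGSeries:
    """One variant's PEG-precipitation measurements.

    `points` rows are (peg_percent, soluble concentration mg/mL,
    replicate index); `c0` is the starting concentration used to
    normalize before fitting.
    """

    variant_id: str
    points: np.ndarray = field(repr=False)  # shape (n, 3): x, y, replicate
    c0: float = 1.0

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array of (x, y, replicate)")
        if np.any(pts[:, 0] < 0) or np.any(pts[:, 1] < 0):
            raise ValueError("PEG percentages and concentrations must be >= 0")
        if self.c0 <= 0:
            raise ValueError("starting concentration c0 must be > 0")
        object.__setattr__(self, "points", pts)

    @property
    def levels(self) -> np.ndarray:
        return np.unique(self.points[:, 0])

    def level_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Distinct PEG levels and the replicate-mean fractional solubility."""
        x = self.levels
        frac = self.points[:, 1] / self.c0
        means = np.array([frac[self.points[:, 0] == xi].mean() for xi in x])
        return x, means


@dataclass(frozen=True)
class SigmoidFitResult:
    """Fitted sigmoid parameters with optional bootstrap 95% CIs."""

    variant_id: str
    a: float
    b: float
    s: float
    peg_half: float
    a_fixed: bool
    residual: float           # root-mean-square residual on level means
    extrapolated: bool        # midpoint outside the measured PEG range
    ci: dict = field(default_factory=dict)   # param -> (lo, hi)
    n_boot_failures: int = 0

    def params(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.s, self.peg_half)


class NoTransitionError(ValueError):
    """The series shows no decreasing transition to fit."""


_A_BOUNDS = (0.9, 1.1)
_B_BOUNDS = (0.0, 0.1)
_S_BOUNDS = (1e-6, 60.0)


def _initial_guesses(x: np.ndarray, means: np.ndarray) -> tuple[float, float]:
    """Midpoint at the steepest observed decrease, slope from a two-point
    secant estimate of the logistic derivative (|f'| = s/4 at midpoint)."""
    dy = np.diff(means)
    dx = np.diff(x)
    rates = dy / dx
    k = int(np.argmin(rates))  # steepest decrease
    m0 = 0.5 * (x[k] + x[k + 1])
    s0 = float(np.clip(-4.0 * rates[k], 0.1, 20.0))
    return m0, s0


def fit_sigmoid(series: PEGSeries, fix_a: bool | str = "auto") -> SigmoidFitResult:
    """Bounded least-squares fit of the sigmoid to replicate-mean data.

    Fitting uses the replicate means per PEG level (the plotted quantity);
    raw replicates are kept on the series for the bootstrap.  Five
    deterministically jittered initializations are tried and the best
    residual kept.
    """
    x, means = series.level_means()
    if len(x) < 4:
        raise ValueError(
            f"{series.variant_id}: need >= 4 distinct PEG levels, got {len(x)}"
        )
    if np.ptp(means) < 1e-12:
        raise NoTransitionError(f"{series.variant_id}: all-equal measurements")
    # overall trend must be decreasing somewhere
    if np.all(np.diff(means) >= 0):
        raise NoTransitionError(
            f"{series.variant_id}: no transition (monotonically increasing data)"
        )
    if fix_a == "auto":
        fix_a = bool(means[np.argmin(x)] < 0.9)

    m0, s0 = _initial_guesses(x, means)
    result = _fit_levels(x, means, m0, s0, fix_a)
    a, b, s, m = result["params"]
    return SigmoidFitResult(
        variant_id=series.variant_id,
        a=a, b=b, s=s, peg_half=m,
        a_fixed=bool(fix_a),
        residual=result["rms"],
        extrapolated=not (x.min() <= m <= x.max()),
    )


def _fit_levels(x, means, m0, s0, fix_a, restarts: int = 5):
    """Core bounded least-squares with jittered restarts (deterministic)."""
    rng = np.random.default_rng(12345)
    span = max(np.ptp(x), 1.0)
    lo_m, hi_m = x.min() - span, x.max() + span

    if fix_a:
        def resid(p):
            b, s, m = p
            return sigmoid(x, 1.0, b, s, m) - means
        lower = [_B_BOUNDS[0], _S_BOUNDS[0], lo_m]
        upper = [_B_BOUNDS[1], _S_BOUNDS[1], hi_m]
        base = [0.01, s0, m0]
    else:
        def resid(p):
            a, b, s, m = p
            return sigmoid(x, a, b, s, m) - means
        lower = [_A_BOUNDS[0], _B_BOUNDS[0], _S_BOUNDS[0], lo_m]
        upper = [_A_BOUNDS[1], _B_BOUNDS[1], _S_BOUNDS[1], hi_m]
        base = [1.0, 0.01, s0, m0]

    best = None
    for trial in range(restarts):
        p0 = np.array(base, dtype=float)
        if trial > 0:
            jitter = 1.0 + 0.2 * rng.standard_normal(len(p0))
            p0 = p0 * jitter
        p0 = np.clip(p0, np.array(lower) + 1e-9, np.array(upper) - 1e-9)
        try:
            sol = least_squares(resid, p0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        cost = float(np.sum(sol.fun**2))
        if best is None or cost < best[0]:
            best = (cost, sol.x)
    if best is None:
        raise RuntimeError("sigmoid fit failed to converge from all starts")
    cost, p = best
    params = (1.0, *p) if fix_a else tuple(p)
    return {"params": params, "rms": float(np.sqrt(cost / len(x)))}


def bootstrap_ci(
    series: PEGSeries,
    fit: SigmoidFitResult,
    cycles: int = 10_000,
    seed: int = 0,
    scheme: str = "pooled",
    interval: str = "percentile",
) -> SigmoidFitResult:
    """Bootstrap 95% CIs for the sigmoid parameters.

    Replicate measurements are resampled, level means recomputed, and the
    sigmoid refitted starting from the original estimate; failed refits
    are counted and excluded.  Reproducible under `seed`.

    Resampling schemes (both resample replicate measurements, centred
    within their PEG level and rescaled by sqrt(n/(n-1)) so the resampled
    level-mean variance is unbiased at small replicate counts):

    * ``pooled`` (default) — centred deviations are pooled across all PEG
      levels before resampling.  With triplicates, per-level spread is
      estimated with only 2 degrees of freedom and conditioning on it
      produces intervals that are too short whenever a level's replicates
      happen to agree; pooling borrows strength across levels and restores
      near-nominal coverage while remaining fully nonparametric.
    * ``case`` — classical within-level case resampling; each level's
      deviations stay in that level (robust to strong heteroscedasticity
      across levels, at the cost of the df starvation above).

    Interval types: ``percentile`` (2.5/97.5 percentiles of the resampled
    estimates), ``basic`` (reflected percentiles), ``t`` (estimate +/-
    t_df x bootstrap sd, df = total replicate df across levels).
    """
    import warnings

    if cycles < 100:
        warnings.warn(
            f"bootstrap with {cycles} cycles gives unstable percentiles",
            stacklevel=2,
        )
    if scheme not in ("pooled", "case"):
        raise ValueError(f"unknown resampling scheme {scheme!r}")
    if interval not in ("percentile", "basic", "t"):
        raise ValueError(f"unknown interval type {interval!r}")
    rng = np.random.default_rng(seed)
    x_levels = series.levels
    frac = series.points[:, 1] / series.c0
    groups = [frac[series.points[:, 0] == xi] for xi in x_levels]
    gmeans = np.array([g.mean() for g in groups])
    sizes = [len(g) for g in groups]
    # centred, small-sample-corrected deviations
    deviations = [
        (g - g.mean()) * (np.sqrt(len(g) / (len(g) - 1)) if len(g) > 1 else 1.0)
        for g in groups
    ]
    pooled = np.concatenate(deviations)

    estimates = []
    failures = 0
    for _ in range(cycles):
        if scheme == "pooled":
            means = gmeans + np.array(
                [pooled[rng.integers(0, len(pooled), size=m)].mean() for m in sizes]
            )
        else:
            means = gmeans + np.array(
                [d[rng.integers(0, len(d), size=len(d))].mean() for d in deviations]
            )
        try:
            res = _fit_levels(
                x_levels, means, fit.peg_half, fit.s, fit.a_fixed, restarts=1
            )
        except Exception:
            failures += 1
            continue
        estimates.append(res["params"])
    if not estimates:
        raise RuntimeError("all bootstrap refits failed")
    est = np.array(estimates)
    names = ("a", "b", "s", "peg_half")
    point = dict(zip(names, fit.params()))
    ci = {}
    for k, name in enumerate(names):
        if interval == "t":
            from scipy import stats as _stats

            df = sum(m - 1 for m in sizes)
            half = _stats.t.ppf(0.975, df) * est[:, k].std()
            ci[name] = (float(point[name] - half), float(point[name] + half))
        else:
            lo, hi = np.percentile(est[:, k], [2.5, 97.5])
            if interval == "basic":
                lo, hi = 2 * point[name] - hi, 2 * point[name] - lo
            ci[name] = (float(lo), float(hi))
    return replace(fit, ci=ci, n_boot_failures=failures)


@dataclass(frozen=True)
class ApparentSolubilityResult:
    """Zero-PEG back-extrapolation of the log-linear transition region."""

    variant_id: str
    apparent_solubility: float     # mg/mL
    ci: tuple                      # 95% CI on the intercept, mg/mL
    slope: float                   # d ln(y) / d x, per % PEG
    n_points: int
    point_levels: np.ndarray = field(repr=False)
    reliable: bool = True


def apparent_solubility(
    series: PEGSeries, fit: SigmoidFitResult
) -> ApparentSolubilityResult:
    """Extrapolate the apparent solubility from the log-linear region.

    Selects PEG levels whose FITTED fractional solubility lies between
    5% and 95% of the transition amplitude (strictly between the
    plateaus), fits ln(y) = m*x + q to the replicate-mean concentrations
    there, and returns exp(q) with a CI from the linear-fit covariance.
    The log base is irrelevant: the intercept in original units is
    invariant under affine reparameterization of the log.
    """
    x, means = series.level_means()
    fitted_frac = (sigmoid(x, *fit.params()) - fit.b) / fit.a
    sel = (fitted_frac > 0.05) & (fitted_frac < 0.95) & (means > 0)
    xs, ys = x[sel], means[sel] * series.c0
    reliable = sel.sum() >= 3
    if sel.sum() < 2:
        raise ValueError(
            f"{series.variant_id}: fewer than 2 points in the transition region"
        )
    X = np.column_stack([xs, np.ones_like(xs)])
    logy = np.log(ys)
    beta, res_ss, *_ = np.linalg.lstsq(X, logy, rcond=None)
    m, q = float(beta[0]), float(beta[1])
    if len(xs) > 2:
        ss = float(res_ss[0]) if len(res_ss) else float(
            np.sum((logy - X @ beta) ** 2)
        )
        s2 = ss / (len(xs) - 2)
        cov_q = s2 * np.linalg.inv(X.T @ X)[1, 1]
        se_q = float(np.sqrt(cov_q))
        ci = (float(np.exp(q - 1.96 * se_q)), float(np.exp(q + 1.96 * se_q)))
    else:
        ci = (float("nan"), float("nan"))
    return ApparentSolubilityResult(
        variant_id=series.variant_id,
        apparent_solubility=float(np.exp(q)),
        ci=ci,
        slope=m,
        n_points=int(sel.sum()),
        point_levels=xs,
        reliable=bool(reliable),
    )


def read_peg_table(path) -> list[PEGSeries]:
    """Read a tidy assay table (variant, peg_percent, concentration,
    replicate[, c0]) into one PEGSeries per variant."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"variant", "peg_percent", "concentration", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for vid, grp in df.groupby("variant", sort=False):
        c0 = float(grp["c0"].iloc[0]) if "c0" in df.columns else 1.0
        pts = grp[["peg_percent", "concentration", "replicate"]].to_numpy(float)
        out.append(PEGSeries(variant_id=str(vid), points=pts, c0=c0))
    return out
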