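"""Two-dimensional affinity x solubility lead-selection analysis.

Library screening yields many binders; the variants worth developing are
those combining strong target engagement with high predicted solubility.
This module provides the statistics for validating predicted solubility
scores against assay measurements (Pearson correlations with explicit
outlier exclusion, leave-one-out studentized-residual outlier flagging)
and the two-dimensional ranking itself (Pareto non-domination over a
declared binding column and solubility column, with a rank-based
concordance statistic for monotone agreement checks).

The packaged reference dataset (nine anti-NGF antibody variants with
predicted VH / VL / combined solubility scores, measured PEG_half and
apparent solubility with bootstrap confidence bounds, and thermal
stability metadata) ships with the module and is the substrate of the
worked examples.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with provenance of any excluded points."""

    n: int
    excluded: tuple
    r: float
    p_value: float
    slope: float
    intercept: float


def load_reference_panel(checksum: str | None = None) -> pd.DataFrame:
    """Load the packaged nine-variant reference characterization table.

    Optionally verifies the file's SHA-256 against `checksum`.
    """
    ref = resources.files("solscreen.data").joinpath("reference_panel.tsv")
    raw = ref.read_bytes()
    if checksum is not None:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != checksum:
            raise ValueError(f"reference table checksum mismatch: {digest}")
    import io

    df = pd.read_csv(io.BytesIO(raw), sep="\t", comment="#")
    return df.set_index("variant", drop=False)


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test p-value.

    p is computed from t = R * sqrt((n-2) / (1-R^2)) against the t
    distribution with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationResult(
        n=n, excluded=(), r=float(r), p_value=float(p),
        slope=float(fit.slope), intercept=float(fit.intercept),
    )


def correlate(
    table: pd.DataFrame,
    predictor: str,
    response: str,
    exclude: set | None = None,
    log_response: bool = False,
) -> CorrelationResult:
    """Correlate two columns of a screening table with explicit exclusions.

    Excluded ids are recorded in the result — points are never silently
    dropped.  `log_response` applies a natural log to the response before
    correlating (Pearson R is invariant to the log base).
    """
    exclude = set(exclude or ())
    for col in (predictor, response):
        if col not in table.columns:
            raise ValueError(f"column {col!r} not in table")
    unknown = exclude - set(table.index)
    if unknown:
        import warnings

        warnings.warn(f"excluded ids not in table: {sorted(unknown)}", stacklevel=2)
    kept = table.loc[~table.index.isin(exclude)]
    if len(kept) < 3:
        raise ValueError(f"only {len(kept)} rows remain after exclusion; need >= 3")
    y = kept[response].to_numpy(float)
    if log_response:
        y = np.log(y)
    res = pearson(kept[predictor].to_numpy(float), y)
    return CorrelationResult(
        n=res.n, excluded=tuple(sorted(exclude & set(table.index))),
        r=res.r, p_value=res.p_value, slope=res.slope, intercept=res.intercept,
    )


def flag_outliers(
    table: pd.DataFrame,
    predictor: str,
    response: str,
    threshold: float = 2.5,
) -> set:
    """Ids whose leave-one-out studentized residual exceeds `threshold`.

    For each point the regression line is refitted WITHOUT that point and
    the point's externally studentized prediction residual is computed;
    large values mark points inconsistent with the trend of the rest.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 rows for leave-one-out residuals")
    x = table[predictor].to_numpy(float)
    y = table[response].to_numpy(float)
    ids = list(table.index)
    flagged = set()
    n = len(x)
    for i in range(n):
        keep = np.arange(n) != i
        xi, yi = x[keep], y[keep]
        if xi.std() == 0:
            raise ValueError("degenerate fit: predictor has zero variance")
        fit = stats.linregress(xi, yi)
        pred = fit.slope * x[i] + fit.intercept
        resid = yi - (fit.slope * xi + fit.intercept)
        dof = len(xi) - 2
        if dof <= 0:
            raise ValueError("too few points for studentization")
        s = np.sqrt(np.sum(resid**2) / dof)
        if s == 0:
            continue  # perfectly collinear remainder: never flag
        sxx = np.sum((xi - xi.mean()) ** 2)
        se_pred = s * np.sqrt(1 + 1 / len(xi) + (x[i] - xi.mean()) ** 2 / sxx)
        if abs(y[i] - pred) / se_pred > threshold:
            flagged.add(ids[i])
    return flagged


@dataclass(frozen=True)
class RankedCandidates:
    """Result of the two-dimensional ranking."""

    order: list                 # ids, best first
    pareto_front: set           # non-dominated ids
    levels: dict                # id -> non-domination level (1 = front)
    distances: dict = field(default_factory=dict)  # id -> distance to ideal


def rank_candidates(
    table: pd.DataFrame,
    binding: str,
    solubility: str,
    binding_higher_is_better: bool | None = None,
    solubility_higher_is_better: bool | None = None,
) -> RankedCandidates:
    """Two-dimensional candidate ranking over binding and solubility.

    The orientation of each column must be declared explicitly (e.g. an
    off-rate is lower-is-better while an affinity constant and a
    solubility score are higher-is-better).  Candidates are grouped into
    non-domination levels (level 1 = Pareto front) and ordered within a
    level by normalized Euclidean distance to the ideal point.
    """
    if binding_higher_is_better is None or solubility_higher_is_better is None:
        raise ValueError(
            "orientation of both columns must be declared "
            "(binding_higher_is_better / solubility_higher_is_better)"
        )
    b = table[binding].to_numpy(float) * (1 if binding_higher_is_better else -1)
    s = table[solubility].to_numpy(float) * (1 if solubility_higher_is_better else -1)
    ids = list(table.index)
    n = len(ids)

    def dominates(i, j):
        return (b[i] >= b[j] and s[i] >= s[j]) and (b[i] > b[j] or s[i] > s[j])

    levels: dict = {}
    remaining = set(range(n))
    level = 0
    while remaining:
        level += 1
        front = {
            i for i in remaining
            if not any(dominates(j, i) for j in remaining if j != i)
        }
        for i in front:
            levels[ids[i]] = level
        remaining -= front

    # normalized distance to the ideal (best observed) point
    def norm(v):
        rng = np.ptp(v)
        return (v - v.min()) / rng if rng > 0 else np.zeros_like(v)

    nb, ns = norm(b), norm(s)
    dist = {
        ids[i]: float(np.hypot(1 - nb[i], 1 - ns[i])) for i in range(n)
    }
    order = sorted(ids, key=lambda vid: (levels[vid], dist[vid], str(vid)))
    return RankedCandidates(
        order=order,
        pareto_front={vid for vid, lv in levels.items() if lv == 1},
        levels=levels,
        distances=dist,
    )


def rank_agreement(predicted, observed) -> float:
    """Kendall-type rank concordance by exhaustive pair counting.

    Counts concordant minus discordant pairs over all n(n-1)/2 pairs
    (ties in either list contribute zero) and normalizes by the total
    pair count: +1 for identical rankings, -1 for exactly reversed.
    Robust to monotone non-linearity in either variable.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if len(p) != len(o):
        raise ValueError("length mismatch")
    n = len(p)
    if n < 2:
        raise ValueError("need at least 2 values")
    net = 0
    for i in range(n):
        for j in range(i + 1, n):
            net += int(np.sign((p[i] - p[j]) * (o[i] - o[j])))
    return net / (n * (n - 1) / 2)
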