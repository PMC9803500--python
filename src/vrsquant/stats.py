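"""Cohort statistics: rank tests, correlations and the LOESS duration cutoff.

The analysis mirrors a three-group observational design: pairwise
Mann-Whitney U tests at a Bonferroni-adjusted significance level
(alpha / 3 = .017 for the three group pairs), Pearson correlations of the
VRs metrics against seizure duration and the course from seizure onset to
the scan, and a LOESS-based changepoint locating the seizure-duration
cutoff that separates the groups.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ComparisonResult, CorrelationResult, CutoffResult, LoessFit

logger = logging.getLogger(__name__)

__all__ = [
    "mann_whitney_u",
    "bonferroni_threshold",
    "pairwise_group_comparisons",
    "pearson_r",
    "correlation_panel",
    "loess_fit",
    "detect_cutoff",
    "seizure_duration_cutoff",
    "summarize_groups",
    "format_p",
    "VRS_METRICS",
    "GROUP_ORDER",
]

#: canonical group ordering for reports
GROUP_ORDER = ("SFS>5M", "SFS<=5M", "control")
VRS_METRICS = ("vrs_count", "vrs_volume_mm3", "wm_volume_mm3", "hc_cm", "brain_volume_mm3")

_EXACT_LIMIT = 16  # exact enumeration path bounded for desk-scale runtime


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p, method)`` where U is reported as min(U, n1*n2 - U)
    (ties counted half).  The p-value is exact (full enumeration of rank
    assignments) when n1 + n2 <= 16 and the pooled sample is tie-free,
    otherwise the normal approximation with tie-corrected variance and
    continuity correction is used; p is capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= _EXACT_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    u = float(min(res.statistic, x.size * y.size - res.statistic))
    p = float(min(res.pvalue, 1.0))
    return u, p, method


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise alpha divided by the number of comparisons."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def format_p(p: float) -> str:
    """Render a p-value to three decimals with the conventional floor."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0")


def _groups_in(cohort: pd.DataFrame) -> list[str]:
    present = list(pd.unique(cohort["group"]))
    ordered = [g for g in GROUP_ORDER if g in present]
    ordered += [g for g in present if g not in ordered]
    return ordered


def pairwise_group_comparisons(
    cohort: pd.DataFrame, metric: str, alpha: float = 0.05
) -> list[ComparisonResult]:
    """All pairwise Mann-Whitney comparisons of one metric across groups.

    Significance is flagged at the Bonferroni threshold over the number of
    group pairs (three pairs for the three-group design, rendering as
    .017); the number of metrics tested is deliberately not folded into
    the correction.
    """
    if metric not in cohort.columns:
        raise KeyError(f"metric column {metric!r} not in cohort")
    groups = _groups_in(cohort)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    adj = bonferroni_threshold(alpha, len(pairs))
    out = []
    for a, b in pairs:
        xa = cohort.loc[cohort["group"] == a, metric].dropna().to_numpy()
        xb = cohort.loc[cohort["group"] == b, metric].dropna().to_numpy()
        u, p, method = mann_whitney_u(xa, xb)
        out.append(
            ComparisonResult(
                metric=metric,
                group_a=a,
                group_b=b,
                u_statistic=u,
                p_value=p,
                n_a=len(xa),
                n_b=len(xb),
                adjusted_alpha=adj,
                significant=bool(p < adj),
                method=method,
            )
        )
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Sample Pearson correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), int(x.size)


_PANEL_PAIRS = (
    ("duration_min", "vrs_count"),
    ("duration_min", "vrs_volume_mm3"),
    ("course_days", "vrs_count"),
    ("course_days", "vrs_volume_mm3"),
)


def correlation_panel(cohort: pd.DataFrame, group: str) -> list[CorrelationResult]:
    """The four duration/course vs count/volume correlations for one
    seizure group; controls (no duration) are rejected."""
    sub = cohort[cohort["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} not present")
    if sub["duration_min"].isna().all():
        raise ValueError(f"not applicable to this group: {group!r} has no seizure duration")
    out = []
    for vx, vy in _PANEL_PAIRS:
        ok = sub[[vx, vy]].dropna()
        r, p, n = pearson_r(ok[vx], ok[vy])
        out.append(CorrelationResult(var_x=vx, var_y=vy, r=r, p_value=p, n=n))
    return out


def loess_fit(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.5,
    degree: int = 1,
    n_grid: int = 200,
) -> LoessFit:
    """Locally weighted regression on an equispaced grid over the x range.

    At each grid point the ceil(span * n) nearest x-neighbours are fitted
    by weighted least squares (tricube weights w = (1 - (d/dmax)^3)^3,
    local degree 0 or 1).  A degenerate local design (all neighbour x
    equal) falls back to the weighted mean with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if degree not in (0, 1):
        raise ValueError("local degree must be 0 or 1")
    k = int(math.ceil(span * x.size))
    if k < 3:
        raise ValueError(f"span {span} gives only {k} neighbours; need >= 3")
    grid = np.linspace(x.min(), x.max(), n_grid)
    fitted = np.empty(n_grid)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    warned = False
    for i, g in enumerate(grid):
        d = np.abs(xs - g)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = ys[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        xi, yi = xs[idx], ys[idx]
        if degree == 0 or np.ptp(xi) == 0:
            if degree == 1 and not warned:
                warnings.warn("degenerate local design; using local mean", RuntimeWarning)
                warned = True
            fitted[i] = np.average(yi, weights=w) if w.sum() > 0 else yi.mean()
            continue
        sw = w.sum()
        xm = (w * xi).sum() / sw
        ym = (w * yi).sum() / sw
        sxx = (w * (xi - xm) ** 2).sum()
        if sxx == 0:
            fitted[i] = ym
            continue
        slope = (w * (xi - xm) * (yi - ym)).sum() / sxx
        fitted[i] = ym + slope * (g - xm)
    return LoessFit(grid=grid, fitted=fitted, span=span, degree=degree, n_neighbors=k)


def detect_cutoff(
    fit: LoessFit,
    exclude_frac: float = 0.05,
    criterion: str = "max_abs_curvature",
) -> CutoffResult:
    """Changepoint of a smoothed curve by its second differences.

    ``max_abs_curvature`` (default) takes the grid point with the largest
    absolute second difference of the fitted values; ``max_convexity``
    takes the largest signed (convex) second difference.  The outer
    ``exclude_frac`` of the grid is excluded on both sides.  A flat
    profile (below 1e-9 of the curve's scale) raises.
    """
    if criterion not in ("max_abs_curvature", "max_convexity"):
        raise ValueError(f"unknown criterion {criterion!r}")
    f = fit.fitted
    n = f.size
    d2 = np.diff(f, 2)  # d2[i] belongs to grid index i + 1
    centers = np.arange(1, n - 1)
    margin = int(math.ceil(exclude_frac * n))
    keep = (centers >= margin) & (centers < n - margin)
    if not keep.any():
        raise ValueError("exclusion margin leaves no interior grid points")
    profile = d2[keep]
    scale = max(float(np.ptp(f)), 1.0)
    crit = np.abs(profile) if criterion == "max_abs_curvature" else profile
    if np.max(crit) < 1e-9 * scale:
        raise ValueError("no cutoff detectable: curvature profile is flat")
    best = int(np.argmax(crit))
    return CutoffResult(
        cutoff=float(fit.grid[centers[keep][best]]),
        criterion=criterion,
        profile_grid=fit.grid[centers[keep]],
        profile=profile,
        span=fit.span,
    )


def seizure_duration_cutoff(
    cohort: pd.DataFrame,
    metric: str = "vrs_count",
    span: float = 0.5,
    degree: int = 1,
    criterion: str = "max_abs_curvature",
    n_grid: int = 200,
) -> CutoffResult:
    """LOESS cutoff of seizure duration on the pooled seizure groups.

    Smooths ``metric`` against seizure duration over every subject with a
    recorded duration and hands the curve to :func:`detect_cutoff`.  The
    smoothed metric, span and criterion are deliberate free choices and
    are recorded on the result.
    """
    sub = cohort.dropna(subset=["duration_min", metric])
    if sub.empty:
        raise ValueError("no subjects with seizure duration in cohort")
    fit = loess_fit(
        sub["duration_min"].to_numpy(),
        sub[metric].to_numpy(),
        span=span,
        degree=degree,
        n_grid=n_grid,
    )
    return detect_cutoff(fit, criterion=criterion)


def summarize_groups(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean +/- SD of every numeric column, plus male counts.

    Long-form table with columns ``group, variable, mean, sd, n, flag``;
    the ``male`` row reports the count in the ``mean`` slot and the
    percentage in the ``sd`` slot.  Single-subject groups carry SD 0 and
    the flag ``"single-subject"``.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    numeric = [
        c
        for c in cohort.columns
        if c not in ("subject_id", "group", "sex")
        and pd.api.types.is_numeric_dtype(cohort[c])
    ]
    rows = []
    for g in _groups_in(cohort):
        sub = cohort[cohort["group"] == g]
        flag = "single-subject" if len(sub) == 1 else ""
        for var in numeric:
            vals = sub[var].dropna()
            if vals.empty:
                rows.append((g, var, np.nan, np.nan, 0, "all-missing"))
                continue
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows.append((g, var, float(vals.mean()), sd, len(vals), flag))
        if "sex" in cohort.columns:
            n_male = int((sub["sex"] == "M").sum())
            pct = 100.0 * n_male / len(sub) if len(sub) else np.nan
            rows.append((g, "male", float(n_male), pct, len(sub), flag))
    return pd.DataFrame(rows, columns=["group", "variable", "mean", "sd", "n", "flag"])
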