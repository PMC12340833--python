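"""Population statistics: ROUT outlier removal, rank-sum comparison, simple
linear regression, and replicate-mean (SuperPlot-style) summary tables.

The ROUT procedure combines a robust fit with false-discovery-rate outlier
identification. It was formulated for nonlinear regression; applied to a
scalar column of measurements the "model" degenerates to a constant
location, which is how it is implemented here: an iteratively reweighted
(Lorentzian-loss) estimate of the centre, a robust standard deviation of the
residuals (RSDR, from the 68.27th percentile of absolute residuals with a
small-sample correction), and a Benjamini–Hochberg step at rate Q on the
two-tailed t-tail probabilities of the standardized residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "rout_outliers",
    "rank_sum_test",
    "linear_correlation",
    "superplot_table",
    "RankSumResult",
    "RegressionResult",
]


def _robust_center(values: np.ndarray, n_iter: int = 100, tol: float = 1e-10) -> float:
    """Lorentzian-loss location estimate via iteratively reweighted means."""
    center = float(np.median(values))
    for _ in range(n_iter):
        resid = values - center
        scale = _rsdr(resid)
        if scale == 0:
            return center
        w = 1.0 / (1.0 + (resid / scale) ** 2)
        new = float(np.sum(w * values) / np.sum(w))
        if abs(new - center) < tol:
            return new
        center = new
    return center


def _rsdr(residuals: np.ndarray, n_params: int = 1) -> float:
    """Robust standard deviation of residuals.

    The 68.27th percentile of the absolute residuals estimates sigma for a
    Gaussian; the n/(n - K) factor corrects for the K fitted parameters.
    """
    n = len(residuals)
    p68 = float(np.percentile(np.abs(residuals), 68.27))
    return p68 * n / max(n - n_params, 1)


def rout_outliers(
    values: np.ndarray, q: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Identify outliers in a scalar sample by the ROUT procedure at rate Q.

    Returns ``(keep_mask, outlier_mask)`` over the input order. With fewer
    than 5 values no point is ever flagged (a warning is issued): the robust
    scale is meaningless at such n.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 5:
        warnings.warn("ROUT needs n >= 5; returning all values", stacklevel=2)
        return np.ones(n, dtype=bool), np.zeros(n, dtype=bool)
    center = _robust_center(values)
    resid = values - center
    scale = _rsdr(resid)
    if scale == 0:  # all (robustly) identical: nothing to flag
        return np.ones(n, dtype=bool), np.zeros(n, dtype=bool)
    tvals = resid / scale
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df=n - 1)
    # Benjamini-Hochberg step-up at rate Q
    order = np.argsort(pvals)
    ranked = pvals[order]
    thresholds = q * (np.arange(1, n + 1)) / n
    below = ranked <= thresholds
    outlier_mask = np.zeros(n, dtype=bool)
    if below.any():
        cutoff = np.max(np.nonzero(below)[0])
        outlier_mask[order[: cutoff + 1]] = True
    return ~outlier_mask, outlier_mask


@dataclass
class RankSumResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"


def rank_sum_test(group_a: np.ndarray, group_b: np.ndarray) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when both samples are small (n <= 20) and tie-free;
    otherwise the normal approximation with mid-rank tie correction. The U
    statistic reported is for the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    use_exact = not has_ties and max(len(a), len(b)) <= 20
    res = sps.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=False,
    )
    return RankSumResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="exact" if use_exact else "asymptotic",
    )


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided, for the slope


def linear_correlation(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Simple linear regression with a two-sided t-test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )


def superplot_table(
    values: np.ndarray,
    group: np.ndarray,
    replicate: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-mean summary in the SuperPlot convention.

    Returns ``(replicate_means, group_summary)``. ``replicate_means`` has one
    row per (group, replicate) with the replicate mean and its n;
    ``group_summary`` reports, per group, mean ± SEM at the individual
    measurement level (n) and at the biological-replicate level (N).
    """
    df = pd.DataFrame({"value": values, "group": group, "replicate": replicate})
    if df["value"].isna().any():
        df = df.dropna(subset=["value"])
    rep = (
        df.groupby(["group", "replicate"], sort=True)["value"]
        .agg(replicate_mean="mean", n="count")
        .reset_index()
    )

    def sem(v):
        v = np.asarray(v, dtype=float)
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan

    rows = []
    for g, sub in df.groupby("group", sort=True):
        reps = rep[rep["group"] == g]["replicate_mean"].to_numpy()
        rows.append(
            {
                "group": g,
                "n_points": len(sub),
                "mean": float(sub["value"].mean()),
                "sem": sem(sub["value"]),
                "n_replicates": len(reps),
                "replicate_mean": float(np.mean(reps)),
                "replicate_sem": sem(reps),
            }
        )
    return rep, pd.DataFrame(rows)
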