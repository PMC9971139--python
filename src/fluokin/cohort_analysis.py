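"""Cohort-level statistics: SBR cutoffs, group comparisons, correlation map.

The central question — below which signal-to-background ratio does target
discrimination deteriorate — is answered per metric by a two-segment
piecewise-linear fit: the breakpoint is scanned on a fine SBR grid and the
location minimizing the total squared error of two independently fitted line
segments is reported, together with the fit R² and a flag when a one-segment
line explains the data (almost) as well, i.e. when there is no clear cutoff.
Count/binary outcomes (handling errors) are first averaged within narrow SBR
bins so the fit sees rates rather than raw 0/1 data.

Also provided: Welch two-sample comparison of a metric between SBR groups,
and the Pearson-correlation matrix of the kinematic features with
average-linkage hierarchical clustering for the reordered heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import squareform

BREAKPOINT_GRID_STEP = 0.01
SBR_BIN_WIDTH = 0.1
MIN_R2_IMPROVEMENT = 0.01


@dataclass
class CutoffResult:
    """Breakpoint of a metric-vs-SBR relation."""

    metric: str
    breakpoint: float
    r_squared: float
    method: str
    r2_improvement: float       # over the single-line fit
    no_clear_cutoff: bool


def _segment_sse(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) == 0:
        return 0.0
    if len(x) == 1 or np.ptp(x) == 0:
        return float(np.sum((y - y.mean()) ** 2))
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    return float(np.sum(resid**2))


def detect_cutoff(
    metric_values: Sequence[float],
    sbr_values: Sequence[float],
    metric_name: str = "metric",
    bin_counts: bool = False,
    grid_step: float = BREAKPOINT_GRID_STEP,
    bin_width: float = SBR_BIN_WIDTH,
    min_improvement: float = MIN_R2_IMPROVEMENT,
) -> CutoffResult:
    """Locate the SBR at which a metric changes regime.

    Fits, for every candidate breakpoint on a ``grid_step``-resolution grid
    over the interior of the observed SBR range, two independent least-squares
    lines (left and right of the break; the segments may be discontinuous,
    matching a threshold phenomenon) and keeps the breakpoint with the lowest
    total SSE.  Each side must contain at least two observations.

    With ``bin_counts=True`` the metric is first averaged within SBR bins of
    ``bin_width`` — use this for handling-error counts or success indicators.

    ``no_clear_cutoff`` is set when the two-segment fit improves R² over a
    single line by less than ``min_improvement``.
    """
    y = np.asarray(metric_values, dtype=float)
    x = np.asarray(sbr_values, dtype=float)
    if len(x) != len(y):
        raise ValueError("metric and SBR vectors must have equal length")
    if len(x) < 10:
        raise ValueError("need at least 10 paired observations")
    if np.ptp(y) == 0:
        raise ValueError(f"metric '{metric_name}' has no variation")
    method = "two-segment least squares"
    if bin_counts:
        edges = np.arange(x.min(), x.max() + bin_width, bin_width)
        idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
        centers, means = [], []
        for b in range(len(edges) - 1):
            sel = idx == b
            if np.any(sel):
                centers.append(edges[b] + bin_width / 2)
                means.append(y[sel].mean())
        x, y = np.asarray(centers), np.asarray(means)
        method += f", SBR-binned ({bin_width})"
        if np.ptp(y) == 0:
            raise ValueError(f"binned metric '{metric_name}' has no variation")

    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    sst = float(np.sum((y - y.mean()) ** 2))
    sse_one = _segment_sse(x, y)

    # candidate breaks: interior grid such that both sides keep >= 2 points
    candidates = np.arange(
        np.ceil(x[0] / grid_step) * grid_step,
        x[-1] + grid_step / 2,
        grid_step,
    )
    best_bp, best_sse = None, np.inf
    for bp in candidates:
        left = x < bp
        if left.sum() < 2 or (~left).sum() < 2:
            continue
        sse = _segment_sse(x[left], y[left]) + _segment_sse(x[~left], y[~left])
        if sse < best_sse - 1e-15:
            best_sse, best_bp = sse, float(bp)
    if best_bp is None:
        raise ValueError("SBR range too narrow for a breakpoint search")
    r2_two = 1.0 - best_sse / sst if sst > 0 else 0.0
    r2_one = 1.0 - sse_one / sst if sst > 0 else 0.0
    improvement = r2_two - r2_one
    return CutoffResult(
        metric=metric_name,
        breakpoint=best_bp,
        r_squared=r2_two,
        method=method,
        r2_improvement=improvement,
        no_clear_cutoff=improvement < min_improvement,
    )


def average_cutoffs(results: Sequence) -> float:
    """Arithmetic mean of breakpoints, reported to 2 decimals."""
    if len(results) == 0:
        raise ValueError("no cutoffs to average")
    values = [r.breakpoint if isinstance(r, CutoffResult) else float(r) for r in results]
    return round(float(np.mean(values)), 2)


@dataclass
class GroupComparison:
    """Two-group comparison of a metric."""

    mean_a: float
    mean_b: float
    ratio: float                # larger mean / smaller mean
    t_statistic: float
    p_value: float
    group_a: str
    group_b: str


def group_compare(values, labels, equal_var: bool = False) -> GroupComparison:
    """Compare a metric between two groups (Welch t-test by default).

    ``labels`` must take exactly two values; the reported ratio is the larger
    group mean over the smaller.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()), key=str)
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {len(groups)}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    hi, lo = max(mean_a, mean_b), min(mean_a, mean_b)
    ratio = 1.0 if hi == lo else (np.inf if lo == 0 else hi / lo)
    if np.array_equal(np.sort(a), np.sort(b)):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        mean_a=mean_a, mean_b=mean_b, ratio=float(ratio),
        t_statistic=float(t_stat), p_value=float(p),
        group_a=str(groups[0]), group_b=str(groups[1]),
    )


def mean_ratio(mean_a: float, mean_b: float) -> float:
    """Larger-over-smaller ratio of two group means."""
    hi, lo = max(mean_a, mean_b), min(mean_a, mean_b)
    if lo == 0:
        raise ValueError("ratio undefined for a zero mean")
    return hi / lo


def correlation_cluster(
    table: pd.DataFrame,
    columns: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation matrix of the features with a clustered ordering.

    Constant features get NaN correlations and are excluded from the
    clustering (reported missing).  Features are ordered by average-linkage
    hierarchical clustering on the 1 − r distance.

    Returns ``(correlation matrix reordered, leaf order)``.
    """
    num = table[list(columns)] if columns is not None else table.select_dtypes("number")
    if num.shape[1] < 3:
        raise ValueError("need at least 3 features")
    if num.shape[0] < 3:
        raise ValueError("need at least 3 exercises")
    corr = num.corr(method="pearson")
    valid = [c for c in corr.columns if not corr[c].isna().all()]
    sub = corr.loc[valid, valid].fillna(0.0)
    dist = squareform(np.clip(1.0 - sub.to_numpy(), 0.0, 2.0), checks=False)
    lnk = linkage(dist, method="average")
    order_idx = dendrogram(lnk, no_plot=True)["leaves"]
    order = [valid[i] for i in order_idx] + [c for c in corr.columns if c not in valid]
    return corr.loc[order, order], order


def plot_correlation_heatmap(corr: pd.DataFrame, path: str) -> None:
    """Render a clustered correlation matrix to a PNG heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    mesh = ax.pcolormesh(corr.to_numpy(), cmap="RdYlGn_r", vmin=-1, vmax=1)
    ax.set_xticks(np.arange(len(corr)) + 0.5, corr.columns, rotation=90)
    ax.set_yticks(np.arange(len(corr)) + 0.5, corr.index)
    fig.colorbar(mesh, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
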