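"""Cohort aggregation, summary metrics and rank-based group comparisons.

Decoded traces from many filaments are aggregated pointwise (mean, s.d.,
s.e.m. on a shared grid, after optional peak normalization), summarized by
windowed metrics (average, peak, least-squares slope over a recovered-time
window) and peak detection, and compared across experimental groups with
the rank-based tests used for this kind of non-normal imaging data:
Kruskal-Wallis analysis of variance with post hoc Dunn tests (all pairs or
versus a control group; z statistics from the pooled tie-corrected ranks),
and the two-sided Wilcoxon rank-sum test for two groups.  Dunn p values
are reported both raw and Holm-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks as _scipy_find_peaks
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SummaryBand",
    "GroupComparison",
    "normalize_to_peak",
    "aggregate",
    "window_metrics",
    "WindowMetrics",
    "find_peaks",
    "group_compare",
    "dunn_test",
]


@dataclass
class SummaryBand:
    """Pointwise mean / s.d. / s.e.m. of a cohort of traces on one grid."""

    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    sem: np.ndarray
    n: int


def normalize_to_peak(values: np.ndarray) -> np.ndarray:
    """Divide a trace by its maximum so the output peaks at exactly 1."""
    values = np.asarray(values, dtype=float)
    peak = values.max()
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("trace has nonpositive peak; excluded from averages")
    return values / peak


def aggregate(traces: Sequence[np.ndarray], grid: np.ndarray) -> SummaryBand:
    """Pointwise mean, s.d. (n-1 denominator) and s.e.m. of traces."""
    if len(traces) == 0:
        raise ValueError("no traces to aggregate")
    arr = np.vstack([np.asarray(t, dtype=float) for t in traces])
    if arr.shape[1] != len(grid):
        raise ValueError("traces and grid lengths differ")
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    return SummaryBand(grid=np.asarray(grid), mean=mean, sd=sd, sem=sd / np.sqrt(n), n=n)


@dataclass
class WindowMetrics:
    average: float
    peak: float
    slope: float


def window_metrics(
    times: np.ndarray, values: np.ndarray, window: tuple[float, float]
) -> WindowMetrics:
    """Average, maximum and OLS slope (per day) of a trace over a window."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    t0, t1 = window
    mask = (times >= t0 - 1e-12) & (times <= t1 + 1e-12)
    if not np.any(mask):
        raise ValueError(f"empty window [{t0}, {t1}]")
    t, v = times[mask], values[mask]
    slope = float(np.polyfit(t, v, 1)[0]) if len(t) > 1 else 0.0
    return WindowMetrics(average=float(v.mean()), peak=float(v.max()), slope=slope)


def find_peaks(
    times: np.ndarray,
    values: np.ndarray,
    prominence: float | None = None,
) -> list[tuple[float, float]]:
    """Local maxima of a trace above a prominence threshold.

    ``prominence`` defaults to 10% of the trace range; a flat trace yields
    an empty list.  Returns (time, value) pairs ordered in time.
    """
    values = np.asarray(values, dtype=float)
    rng = float(np.ptp(values))
    if rng == 0:
        return []
    if prominence is None:
        prominence = 0.1 * rng
    idx, _ = _scipy_find_peaks(values, prominence=prominence)
    return [(float(times[i]), float(values[i])) for i in idx]


@dataclass
class GroupComparison:
    """Omnibus and pairwise rank-test results for >= 2 groups."""

    kruskal_stat: float
    kruskal_p: float
    pairwise: pd.DataFrame  # group1, group2, z, p_raw, p_holm
    ranksum_p: float | None = None  # two-sided Wilcoxon rank-sum (2 groups)
    group_n: dict = field(default_factory=dict)


def dunn_test(
    groups: Mapping[str, Sequence[float]],
    control: str | None = None,
) -> pd.DataFrame:
    """Post hoc Dunn z tests on pooled tie-corrected ranks.

    With ``control`` given, only control-versus-other pairs are tested;
    otherwise all pairs.  Two-sided p values from the normal distribution,
    plus Holm-adjusted values.
    """
    names = list(groups)
    data = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    pooled = np.concatenate([data[k] for k in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_rank, sizes = {}, {}
    start = 0
    for k in names:
        m = len(data[k])
        mean_rank[k] = ranks[start : start + m].mean()
        sizes[k] = m
        start += m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_unit = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_unit -= tie_term / (12.0 * (n_total - 1))
    if control is not None:
        pairs = [(control, k) for k in names if k != control]
    else:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_unit * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        rows.append({"group1": a, "group2": b, "z": z, "p_raw": 2 * stats.norm.sf(abs(z))})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_holm"] = multipletests(df["p_raw"], method="holm")[1]
    return df


def group_compare(
    groups: Mapping[str, Sequence[float]],
    control: str | None = None,
) -> GroupComparison:
    """Kruskal-Wallis omnibus test plus post hoc pairwise tests.

    Each group needs n >= 2.  When every value is tied across all groups
    the statistic is 0 and p = 1 (reported, not an error).  For exactly
    two groups the two-sided Wilcoxon rank-sum p value is also computed
    (exact where sample sizes permit).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    data = [np.asarray(list(groups[k]), dtype=float) for k in names]
    if any(len(d) < 2 for d in data):
        raise ValueError("each group needs n >= 2")
    if np.ptp(np.concatenate(data)) == 0:  # all values identical across groups
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*data)
    pairwise = dunn_test(groups, control=control)
    ranksum_p = None
    if len(names) == 2:
        if np.ptp(np.concatenate(data)) == 0:
            ranksum_p = 1.0
        else:
            ranksum_p = float(
                stats.mannwhitneyu(data[0], data[1], alternative="two-sided").pvalue
            )
    return GroupComparison(
        kruskal_stat=float(stat),
        kruskal_p=float(p),
        pairwise=pairwise,
        ranksum_p=ranksum_p,
        group_n={k: len(d) for k, d in zip(names, data)},
    )
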