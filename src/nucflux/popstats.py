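"""Population-level statistics: cycle length, cell length, rank-sum tests,
box summaries and the size-homeostasis regression.

The rank-sum test is the two-sided Wilcoxon rank sum with continuity
correction (normal approximation with midranks and tie-corrected variance,
matching R's ``wilcox.test`` default); an exact permutation version is
available for small groups and doubles as the test oracle. Size
homeostasis is the ordinary least-squares regression of cycle length on
birth length, reported with the Pearson correlation coefficient.
Quartiles use the linear-interpolation (type-7) convention throughout;
box whiskers sit on the most extreme observations within 1.5 IQR of the
quartiles.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "TestResult", "BoxSummary", "HomeostasisFit",
    "wilcoxon_rank_sum", "wilcoxon_exact", "homeostasis_fit",
    "box_summary", "cycle_metrics",
]


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str
    n_x: int
    n_y: int


@dataclass
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n: int


@dataclass
class HomeostasisFit:
    slope: float
    intercept: float
    pearson_r: float
    n: int

    def summary(self) -> str:
        return (f"cycle length = {self.intercept:.2f} "
                f"{self.slope:+.3f} x birth length (min, µm); "
                f"R = {self.pearson_r:.3f}, n = {self.n}")


def wilcoxon_rank_sum(x, y, continuity: bool = True) -> TestResult:
    """Two-sided Wilcoxon rank sum test (normal approximation).

    Midranks for ties, tie-corrected variance, and a 0.5 continuity
    correction by default — the behaviour of R's ``wilcox.test`` with
    ``correct = TRUE``. The statistic reported is W, the number of pairs
    (x_i, y_j) with x_i > y_j (counting ties as 1/2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=continuity)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue),
                      method="wilcoxon rank sum, normal approximation"
                             + (" with continuity correction" if continuity else ""),
                      n_x=x.size, n_y=y.size)


def wilcoxon_exact(x, y) -> TestResult:
    """Exact two-sided rank-sum p-value by full enumeration (n <= 10 per
    group); ties handled with midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size > 10 or y.size > 10:
        raise ValueError("exact enumeration limited to 10 per group")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, m = x.size, y.size
    w_obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    total = math.comb(n + m, n)
    count = 0
    for combo in itertools.combinations(range(n + m), n):
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= dev_obs - 1e-9:
            count += 1
    return TestResult(statistic=float(w_obs - n * (n + 1) / 2.0),
                      pvalue=count / total,
                      method="wilcoxon rank sum, exact permutation",
                      n_x=n, n_y=m)


def homeostasis_fit(birth_lengths, cycle_lengths) -> HomeostasisFit:
    """OLS regression of cycle length on birth length, with Pearson R."""
    x = np.asarray(birth_lengths, dtype=float)
    y = np.asarray(cycle_lengths, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in birth length")
    res = stats.linregress(x, y)
    return HomeostasisFit(slope=float(res.slope),
                          intercept=float(res.intercept),
                          pearson_r=float(res.rvalue), n=x.size)


def box_summary(values) -> BoxSummary:
    """Median, type-7 quartiles and 1.5-IQR whiskers at data points."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxSummary(median=float(med), q1=float(q1), q3=float(q3),
                      whisker_low=float(inside.min()),
                      whisker_high=float(inside.max()), n=v.size)


def cycle_metrics(trace_df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-cycle length metrics from a tidy lineage trace table.

    Expects columns ``cell_id``, ``t_min``, ``cell_length_um``,
    ``event_birth``, ``event_division``: one block of rows per observed
    cycle. Cycle length is the time between consecutive division events of
    the same tracked cell; birth length and pre-division length are read
    from the first and last observed frames of the following cycle.
    Returns ``(metrics, n_excluded)``; cells without two consecutive
    divisions in the observation window are excluded and counted.
    """
    rows = []
    excluded = 0
    for cid, g in trace_df.groupby("cell_id"):
        cycles = (g[["event_birth", "event_division"]].drop_duplicates()
                  .sort_values("event_birth"))
        complete = 0
        prev_div = None
        for _, cyc in cycles.iterrows():
            block = g[(g.event_birth == cyc.event_birth)].sort_values("t_min")
            if prev_div is not None and abs(cyc.event_birth - prev_div) < 1e-6:
                rows.append({
                    "cell_id": cid,
                    "cycle_length_min": cyc.event_division - cyc.event_birth,
                    "birth_length_um": float(block.cell_length_um.iloc[0]),
                    "predivision_length_um": float(block.cell_length_um.iloc[-1]),
                })
                complete += 1
            prev_div = cyc.event_division
        if complete == 0:
            excluded += 1
            log.info("cell %s excluded: fewer than two divisions observed", cid)
    return pd.DataFrame(rows), excluded
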