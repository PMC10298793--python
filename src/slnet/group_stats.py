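"""Nonparametric group comparison of graph metrics across tasks.

The workflow: a Shapiro–Wilk gate establishes that per-subject SWN and
global-efficiency samples are not normal, pairwise task differences are
then tested with the two-tailed asymptotic Mann–Whitney U test (normal
approximation with tie and continuity corrections), and the three
difficulty levels within a task type are compared with the Friedman test.
Raw p-values are reported; a Bonferroni option exists but is off by
default, matching the convention of reporting uncorrected pairwise tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricSample",
    "TestResult",
    "normality_check",
    "mann_whitney_u",
    "friedman_test",
    "pairwise_task_table",
]


@dataclass(frozen=True)
class MetricSample:
    """One number per subject for one (metric, band, task) cell."""

    metric: str
    band: str
    task: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.metric not in ("SWN", "Eg"):
            raise ValueError("metric must be 'SWN' or 'Eg'")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def normality_check(values: Sequence[float]) -> TestResult:
    """Shapiro–Wilk test of normality."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    w, p = stats.shapiro(x)
    return TestResult(float(w), float(p), "shapiro-wilk", (x.size,))


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   use_continuity: bool = True) -> TestResult:
    """Two-tailed asymptotic Mann–Whitney U test.

    Normal approximation with tie correction and (by default) continuity
    correction. When every pooled value ties — the two samples are
    indistinguishable — the tie-corrected variance vanishes; the test is
    then reported as z = 0, p = 1.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    n = n1 + n2
    sd = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))))
    if sd == 0:
        return TestResult(n1 * n2 / 2.0, 1.0, "mann-whitney-u-asymptotic",
                          (n1, n2))
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic",
        use_continuity=use_continuity,
    )
    return TestResult(float(res.statistic), float(res.pvalue),
                      "mann-whitney-u-asymptotic", (n1, n2))


def friedman_test(blocks: np.ndarray) -> TestResult:
    """Friedman chi-square over repeated conditions.

    ``blocks`` is subjects x conditions (e.g. the three difficulty levels);
    the statistic is computed on within-subject ranks with df = k - 1.
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2:
        raise ValueError("blocks must be subjects x conditions")
    n, k = blocks.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    if np.any(~np.isfinite(blocks)):
        raise ValueError("missing cell in blocks")
    if np.all(np.ptp(blocks, axis=1) == 0):
        # every subject ranks all conditions equal: no evidence either way
        return TestResult(0.0, 1.0, "friedman", (n, k))
    stat, p = stats.friedmanchisquare(*(blocks[:, j] for j in range(k)))
    return TestResult(float(stat), float(p), "friedman", (n, k))


def pairwise_task_table(
    samples: Mapping[str, Sequence[float]],
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Symmetric table of pairwise two-tailed U-test p-values across tasks.

    Rows/columns follow the iteration order of ``samples``; the diagonal is
    NaN. With ``bonferroni`` the p-values are multiplied by the number of
    pairs (clipped at 1).
    """
    tasks = list(samples)
    if len(tasks) < 2:
        raise ValueError("need at least 2 tasks")
    table = pd.DataFrame(np.nan, index=tasks, columns=tasks, dtype=float)
    n_pairs = len(tasks) * (len(tasks) - 1) // 2
    for i, t1 in enumerate(tasks):
        for t2 in tasks[i + 1:]:
            p = mann_whitney_u(samples[t1], samples[t2]).p_value
            if bonferroni:
                p = min(1.0, p * n_pairs)
            table.loc[t1, t2] = p
            table.loc[t2, t1] = p
    return table
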