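"""Nonparametric statistics for cohort comparisons.

Mann-Whitney U for two independent groups, Pearson chi-square for
contingency tables, the Friedman rank test for repeated measures across
visits, and median/IQR summarisation.

Mann-Whitney uses exact enumeration when both groups have at most 8
observations and no ties occur, else the normal approximation with tie
correction.  Friedman is computed in-package (average ranks, tie-corrected,
chi-square reference distribution with k-1 df) because the contract covers
k = 2 treatments and degenerate all-tied inputs; scipy's implementation is
used as an independent cross-check in the test suite.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DomainError


class TestMethod(str, enum.Enum):
    MANN_WHITNEY = "mann_whitney"
    CHI_SQUARE = "chi_square"
    FRIEDMAN = "friedman"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: TestMethod
    n: tuple[int, ...]
    n_dropped: int = 0  # incomplete blocks removed (Friedman only)


@dataclass(frozen=True)
class SummaryStat:
    median: float
    q1: float
    q3: float
    n: int
    pct_missing: float


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test; statistic is U of the first sample."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both samples must be non-empty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise DomainError("samples must not contain missing values")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue),
                      TestMethod.MANN_WHITNEY, (a.size, b.size))


def chi_square(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise DomainError("table must be at least 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise DomainError("table must hold nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DomainError("table has a zero marginal")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(float(stat), float(p), TestMethod.CHI_SQUARE,
                      tuple(int(x) for x in t.shape))


def friedman_statistic(matrix: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square statistic for an n x k complete matrix."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    ranks = sps.rankdata(m, axis=1, method="average")
    rj = ranks.sum(axis=0)
    uncorrected = 12.0 / (n * k * (k + 1)) * float(np.sum(rj ** 2)) - 3.0 * n * (k + 1)
    srt = np.sort(m, axis=1)
    if not (np.diff(srt, axis=1) == 0).any():
        return uncorrected
    tie_term = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts.astype(float) ** 3 - counts))
    c = 1.0 - tie_term / (n * (k ** 3 - k))
    if c <= 0:  # every block fully tied: no information, statistic 0 by convention
        return 0.0
    return uncorrected / c


def friedman(matrix: Sequence[Sequence[float]]) -> TestResult:
    """Friedman test on an n-blocks x k-treatments matrix.

    Blocks (rows) containing missing values are dropped listwise and counted
    in ``n_dropped``.  p-value from the chi-square distribution with k-1 df.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise DomainError("matrix must be 2-dimensional (blocks x treatments)")
    if m.shape[1] < 2:
        raise DomainError("need at least 2 treatments")
    complete = ~np.isnan(m).any(axis=1)
    dropped = int(np.sum(~complete))
    m = m[complete]
    if m.shape[0] < 2:
        raise DomainError("fewer than 2 complete blocks after listwise deletion")
    n, k = m.shape
    stat = friedman_statistic(m)
    p = float(sps.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    return TestResult(float(stat), p, TestMethod.FRIEDMAN, (n, k), n_dropped=dropped)


def summarize(values: Sequence[Optional[float]]) -> SummaryStat:
    """Median and quartiles (linear interpolation); missing excluded and counted."""
    arr = np.asarray([np.nan if v is None else float(v) for v in values], dtype=float)
    n_total = arr.size
    vals = arr[~np.isnan(arr)]
    n = int(vals.size)
    pct_missing = float((n_total - n) / n_total) if n_total else 0.0
    if n == 0:
        return SummaryStat(float("nan"), float("nan"), float("nan"), 0, pct_missing)
    q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
    return SummaryStat(float(med), float(q1), float(q3), n, pct_missing)
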