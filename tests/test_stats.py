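"""Nonparametric tests vs brute-force oracles."""

import itertools

import numpy as np
import pytest
import scipy.stats as sps

from ckdurine import chi_square, friedman, mann_whitney, summarize
from ckdurine.errors import DomainError
from ckdurine.stats import friedman_statistic


def mw_exact_oracle(a, b):
    """Exhaustive enumeration over all C(n1+n2, n1) group labelings.

    Returns (U of first sample, two-sided p as twice the smaller tail,
    capped at 1), the convention of the exact Mann-Whitney distribution.
    """
    pooled = list(a) + list(b)
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(idx)]
        us.append(float(np.sum(r) - n1 * (n1 + 1) / 2))
    us = np.asarray(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2 * min(lo, hi))


def pearson_chi2_oracle(table):
    t = np.asarray(table, dtype=float)
    total = t.sum()
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    return float(np.sum((t - exp) ** 2 / exp))


def friedman_oracle(matrix):
    """Independent rank computation: average ranks, classical tie correction."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    rank_sum = np.zeros(k)
    tie_term = 0.0
    for row in m:
        r = sps.rankdata(row)
        rank_sum += r
        _, counts = np.unique(row, return_counts=True)
        tie_term += np.sum(counts ** 3 - counts)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rank_sum ** 2) - 3 * n * (k + 1)
    c = 1 - tie_term / (n * (k ** 3 - k))
    return 0.0 if c <= 0 else stat / c


class TestMannWhitney:
    def test_identical_multisets_symmetric(self):
        res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(8.0)  # n1*n2/2
        # tie-corrected normal approximation with continuity correction
        assert res.p_value > 0.8

    def test_complete_separation_small_n(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2/20 labelings

    def test_exact_path_matches_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n1, n2 = rng.integers(2, 5, size=2)
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            u_oracle, p_oracle = mw_exact_oracle(a, b)
            res = mann_whitney(a, b)
            assert res.statistic == pytest.approx(u_oracle)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(1.0, 1.0, size=12)
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(np.exp(a), np.exp(b))
        assert r1.statistic == r2.statistic and r1.p_value == r2.p_value

    def test_exact_and_asymptotic_paths_agree(self):
        """At n1 = n2 = 8 the two p-value routes differ by < 0.02."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            a = rng.normal(size=8)
            b = rng.normal(0.5, 1.0, size=8)
            exact = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            asym = sps.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic")
            assert abs(exact.pvalue - asym.pvalue) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney([], [1.0])


class TestChiSquare:
    def test_proportional_rows_independent(self):
        res = chi_square([[10, 20], [5, 10]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_table(self):
        res = chi_square([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)

    def test_matches_pearson_oracle_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.integers(1, 12, size=(rng.integers(2, 4), rng.integers(2, 4)))
            res = chi_square(t)
            assert res.statistic == pytest.approx(pearson_chi2_oracle(t), rel=1e-12)

    def test_permutation_of_rows_and_columns_invariant(self):
        t = np.array([[3, 7, 2], [8, 1, 5]])
        base = chi_square(t).statistic
        assert chi_square(t[::-1]).statistic == pytest.approx(base, rel=1e-12)
        assert chi_square(t[:, ::-1]).statistic == pytest.approx(base, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(DomainError):
            chi_square([[0, 0], [3, 4]])


class TestFriedman:
    def test_perfectly_consistent_ranking(self):
        # every block ranks the treatments (1,2,3): statistic 6 at n=3, k=3
        m = [[1, 2, 3], [10, 20, 30], [0.1, 0.5, 0.9]]
        res = friedman(m)
        assert res.statistic == pytest.approx(6.0)
        assert res.p_value == pytest.approx(sps.chi2.sf(6.0, 2), rel=1e-12)

    def test_identical_columns_no_signal(self):
        res = friedman([[5, 5, 5], [2, 2, 2], [9, 9, 9]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_block_permutation_invariance(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(10, 3))
        perm = m[rng.permutation(10)]
        assert friedman(m).statistic == pytest.approx(friedman(perm).statistic,
                                                      rel=1e-12)

    def test_matches_independent_oracle_with_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            m = rng.integers(0, 4, size=(rng.integers(3, 8), rng.integers(2, 5)))
            m = m.astype(float)
            if np.ptp(m, axis=1).sum() == 0:
                continue
            assert friedman_statistic(m) == pytest.approx(friedman_oracle(m),
                                                          rel=1e-12)

    def test_matches_scipy_for_three_treatments(self):
        """scipy's implementation is the independent cross-check for k >= 3."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            m = rng.normal(size=(12, 3))
            ours = friedman(m)
            ref_stat, ref_p = sps.friedmanchisquare(m[:, 0], m[:, 1], m[:, 2])
            assert ours.statistic == pytest.approx(ref_stat, rel=1e-10)
            assert ours.p_value == pytest.approx(ref_p, rel=1e-10)

    def test_two_treatments_supported(self):
        res = friedman([[1, 2], [1, 3], [2, 5], [0, 1]])
        assert res.statistic == pytest.approx(4.0)  # sign-test chi2, 4/4 wins

    def test_listwise_deletion_counted(self):
        m = [[1, 2, 3], [4, np.nan, 6], [7, 8, 9], [1, 3, 2]]
        res = friedman(m)
        assert res.n == (3, 3) and res.n_dropped == 1

    def test_all_rows_dropped_rejected(self):
        with pytest.raises(DomainError):
            friedman([[np.nan, 1, 2], [3, np.nan, 4]])


class TestSummarize:
    def test_one_to_nine(self):
        s = summarize(range(1, 10))
        assert (s.median, s.q1, s.q3, s.n) == (5.0, 3.0, 7.0, 9)

    def test_single_value(self):
        s = summarize([4.2])
        assert s.median == s.q1 == s.q3 == 4.2

    def test_empty_all_missing(self):
        s = summarize([])
        assert s.n == 0 and np.isnan(s.median)

    def test_missing_excluded_and_counted(self):
        s = summarize([1.0, None, 3.0, np.nan])
        assert s.n == 2 and s.pct_missing == 0.5 and s.median == 2.0


def test_friedman_null_type1_error_rate():
    """Under exchangeable visits the 5%-level rejection rate stays near 5%."""
    rng = np.random.default_rng(2026)
    n_rej = 0
    reps = 400
    for _ in range(reps):
        m = rng.normal(size=(150, 3))
        if friedman(m).p_value < 0.05:
            n_rej += 1
    assert 0.02 <= n_rej / reps <= 0.08
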