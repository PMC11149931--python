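"""Exact rank tests, Fisher tests, Spearman-t, PVE, correspondence analysis."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from swimscore import (correspondence_analysis, fisher_exact,
                       paired_rank_test, pve, spearman_t, unpaired_rank_test)


def enumerate_fisher_p(table):
    """Oracle: exact two-sided Fisher p by enumerating all 2x2 tables
    with the observed margins (probability <= observed rule)."""
    table = np.asarray(table)
    r0, r1 = table.sum(axis=1)
    c0, _ = table.sum(axis=0)
    p_obs = sps.hypergeom.pmf(table[0, 0], r0 + r1, r0, c0)
    p = 0.0
    for a in range(max(0, c0 - r1), min(r0, c0) + 1):
        pa = sps.hypergeom.pmf(a, r0 + r1, r0, c0)
        if pa <= p_obs * (1 + 1e-9):
            p += pa
    return p


def enumerate_signed_rank_p(diffs):
    """Oracle: exact two-sided signed-rank p over all sign assignments."""
    diffs = np.asarray(diffs, float)
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    total = ranks.sum()
    stats = [sum(r for r, s in zip(ranks, signs) if s)
             for signs in itertools.product([False, True], repeat=n)]
    # two-sided: distance of W+ from its mean
    mu = total / 2
    extreme = sum(abs(w - mu) >= abs(w_obs - mu) - 1e-12 for w in stats)
    return extreme / len(stats)


class TestFisher:
    def test_balanced_2x2_enumerated(self):
        res = fisher_exact([[3, 1], [1, 3]])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(34 / 70)
        assert res.p_value == pytest.approx(enumerate_fisher_p([[3, 1], [1, 3]]))

    def test_diagonal_2x2_enumerated(self):
        res = fisher_exact([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(2 / 252)

    def test_identical_compositions_p_is_one(self):
        assert fisher_exact([[4, 6], [4, 6]]).p_value == pytest.approx(1.0)

    def test_monte_carlo_converges_to_enumeration(self):
        # 3x2 table small enough for scipy's network enumeration oracle
        table = [[4, 1], [2, 3], [1, 5]]
        exact = sps.fisher_exact(np.array(table)).pvalue
        res = fisher_exact(table, mc_reps=20_000, seed=0)
        assert res.method == "monte_carlo"
        assert res.p_value == pytest.approx(exact, abs=3 * res.standard_error)

    def test_monte_carlo_reproducible_given_seed(self):
        table = [[4, 1], [2, 3], [1, 5]]
        a = fisher_exact(table, mc_reps=2000, seed=5)
        b = fisher_exact(table, mc_reps=2000, seed=5)
        assert a.p_value == b.p_value

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [1, 2]])


class TestPairedRank:
    def test_three_positive_diffs(self):
        p = paired_rank_test([0, 0, 0], [1, 2, 3])
        assert p == pytest.approx(0.25)
        assert p == pytest.approx(enumerate_signed_rank_p([1, 2, 3]))

    def test_six_positive_diffs(self):
        p = paired_rank_test(np.zeros(6), [1, 2, 3, 4, 5, 6])
        assert p == pytest.approx(2 / 64)

    def test_identical_samples_p_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert paired_rank_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_matches_enumeration_on_mixed_signs(self):
        diffs = np.array([1.0, -2.0, 3.0, -4.0, 5.0])
        p = paired_rank_test(np.zeros(5), diffs)
        assert p == pytest.approx(enumerate_signed_rank_p(diffs))


class TestUnpairedRank:
    def test_two_vs_two_enumerated(self):
        assert unpaired_rank_test([1, 2], [3, 4]) == pytest.approx(2 / 6)

    def test_identical_groups_capped_at_one(self):
        assert unpaired_rank_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_bonferroni_multiplies_and_caps(self):
        p1 = unpaired_rank_test([1, 2], [3, 4], m_comparisons=1)
        p3 = unpaired_rank_test([1, 2], [3, 4], m_comparisons=3)
        assert p3 == pytest.approx(min(1.0, 3 * p1))
        assert unpaired_rank_test([1, 2], [3, 4], m_comparisons=10) == 1.0


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_t([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == 1.0 and p == 0.0

    def test_adjacent_swap_gives_rho_point_nine(self):
        # n=5, sum d^2 = 2 -> rho = 1 - 12/120 = 0.9; t = 3.576
        rho, p = spearman_t([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        assert rho == pytest.approx(0.9)
        t = 0.9 * np.sqrt(3 / (1 - 0.81))
        assert t == pytest.approx(3.576, abs=1e-3)
        assert p == pytest.approx(2 * sps.t.sf(t, df=3), abs=1e-12)
        assert p == pytest.approx(0.0374, abs=5e-4)

    def test_null_permutation_correlation_is_small(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=1000)
        x = rng.permutation(y)
        rho, _ = spearman_t(x, y)
        assert abs(rho) < 0.08

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_t([1, 1, 1, 1], [1, 2, 3, 4])


class TestPve:
    def test_perfect_group_separation(self):
        res = pve([1, 1, 3, 3], ["A", "A", "B", "B"], kind="categorical",
                  n_permutations=500, seed=0)
        assert res.pve == pytest.approx(100.0)
        assert res.p_value < 0.5

    def test_constant_scores_zero_with_warning(self):
        with pytest.warns(UserWarning):
            res = pve([2, 2, 2, 2], ["A", "A", "B", "B"], kind="categorical")
        assert res.pve == 0.0

    def test_shuffled_labels_not_significant(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=200)
        labels = rng.permutation(["A"] * 100 + ["B"] * 100)
        res = pve(scores, labels, kind="categorical", n_permutations=2000,
                  seed=1)
        assert res.p_value > 0.05

    def test_continuous_predictor_is_squared_correlation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = 2 * x + rng.normal(0, 0.5, 50)
        res = pve(y, x, kind="continuous", n_permutations=500, seed=0)
        r = np.corrcoef(x, y)[0, 1]
        assert res.pve == pytest.approx(100 * r ** 2)
        assert res.p_value < 0.01


class TestCorrespondenceAnalysis:
    def test_two_by_two_inertia_is_chi2_over_n(self):
        res = correspondence_analysis([[10, 20], [20, 10]])
        assert res.total_inertia == pytest.approx(1 / 9, abs=1e-12)

    def test_identical_rows_zero_inertia(self):
        res = correspondence_analysis([[5, 10, 15], [5, 10, 15]])
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_inertia_identity_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            tab = rng.integers(1, 40, size=(rng.integers(2, 5),
                                            rng.integers(2, 6)))
            res = correspondence_analysis(tab)
            chi2 = sps.chi2_contingency(tab, correction=False)[0]
            assert res.total_inertia == pytest.approx(chi2 / tab.sum(),
                                                      abs=1e-9)
            assert np.sum(res.singular_values ** 2) == pytest.approx(
                res.total_inertia, abs=1e-12)
            k = min(tab.shape) - 1
            assert res.singular_values.size == k

    def test_permutation_invariance_of_inertia(self):
        rng = np.random.default_rng(2)
        tab = rng.integers(1, 30, size=(3, 4))
        base = correspondence_analysis(tab)
        perm = correspondence_analysis(tab[[2, 0, 1]][:, [3, 1, 0, 2]])
        assert perm.total_inertia == pytest.approx(base.total_inertia,
                                                   abs=1e-12)
        np.testing.assert_allclose(
            np.sort(perm.singular_values), np.sort(base.singular_values),
            atol=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            correspondence_analysis([[0, 0], [1, 2]])
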