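"""Statistical battery: oracle equivalences and cross-library checks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gistmask as gm

# ---------------------------------------------------------------------- #
# independent oracles
# ---------------------------------------------------------------------- #
def auc_by_pair_enumeration(scores, labels):
    """Fraction of concordant (positive, negative) pairs, ties 0.5."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def mann_whitney_u_by_enumeration(x, y):
    u = 0.0
    for a in x:
        for b in y:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


def fisher_p_by_hypergeom_enumeration(table):
    """Two-sided Fisher p for a 2x2 table by enumerating all tables
    with the observed margins."""
    from scipy.stats import hypergeom

    a, b = table[0]
    c, d = table[1]
    r1, n1 = a + b, a + c
    n = a + b + c + d
    dist = hypergeom(n, r1, n1)
    p_obs = dist.pmf(a)
    return sum(
        dist.pmf(k)
        for k in range(max(0, r1 + n1 - n), min(r1, n1) + 1)
        if dist.pmf(k) <= p_obs * (1 + 1e-9)
    )


# ---------------------------------------------------------------------- #
# ROC
# ---------------------------------------------------------------------- #
class TestRoc:
    def test_perfect_separation_gives_auc_one(self):
        r = gm.roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.youden_j == pytest.approx(1.0)
        assert 3 < r.optimal_cutoff < 10

    def test_independent_scores_give_half_auc(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        r = gm.roc_analysis(scores, labels)
        assert r.auc == pytest.approx(0.5, abs=0.05)
        assert r.ci_low < 0.5 < r.ci_high

    def test_six_point_toy_equals_pair_enumeration(self):
        scores = [1, 2, 3, 4, 5, 6]
        labels = [0, 0, 1, 0, 1, 1]
        r = gm.roc_analysis(scores, labels)
        assert r.auc == pytest.approx(auc_by_pair_enumeration(scores, labels))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_sets_equal_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        scores = rng.integers(0, 15, n).astype(float)  # force ties
        labels = np.r_[np.ones(3, int), rng.integers(0, 2, n - 6), np.zeros(3, int)]
        r = gm.roc_analysis(scores, labels)
        assert r.auc == pytest.approx(auc_by_pair_enumeration(scores, labels))

    def test_auc_is_mann_whitney_u_over_n1n0(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu(
            scores[labels == 1], scores[labels == 0], alternative="two-sided"
        ).statistic
        r = gm.roc_analysis(scores, labels)
        n1, n0 = (labels == 1).sum(), (labels == 0).sum()
        assert r.auc == pytest.approx(u / (n1 * n0))

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(6)
        scores = rng.normal(size=100) + rng.integers(0, 2, 100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        assert gm.roc_analysis(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores)
        )

    def test_delong_ci_matches_frozen_proc_oracle(self):
        """CI frozen from an independent DeLong implementation."""
        scores = [3.2, 1.1, 5.4, 2.2, 4.8, 0.7, 6.3, 2.9, 3.7, 1.8,
                  7.1, 4.1, 5.9, 2.5, 6.8, 3.3, 0.9, 5.1, 4.4, 1.4]
        labels = [1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 1, 1, 0, 1, 0, 0, 1, 0, 0]
        r = gm.roc_analysis(scores, labels)
        assert r.auc == pytest.approx(0.96)
        assert r.ci_low == pytest.approx(0.8860851294, abs=1e-8)
        assert r.ci_high == pytest.approx(1.0)

    def test_youden_cutoff_lies_between_observations(self):
        scores = [1.0, 2.0, 3.0, 7.0, 8.0, 9.0]
        labels = [0, 0, 0, 1, 1, 1]
        r = gm.roc_analysis(scores, labels)
        assert r.optimal_cutoff == pytest.approx(5.0)  # midpoint of 3 and 7
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(gm.DegenerateInputError):
            gm.roc_analysis([1, 2, 3], [1, 1, 1])


# ---------------------------------------------------------------------- #
# Odds ratio
# ---------------------------------------------------------------------- #
class TestOddsRatio:
    def test_symmetric_table_gives_unity(self):
        assert gm.odds_ratio([[1, 1], [1, 1]]).or_value == pytest.approx(1.0)

    def test_cross_product_arithmetic(self):
        r = gm.odds_ratio([[12, 8], [4, 33]])
        assert r.or_value == pytest.approx((12 * 33) / (8 * 4))
        assert not r.haldane_corrected

    def test_double_swap_invariance(self):
        a = gm.odds_ratio([[12, 8], [4, 33]])
        b = gm.odds_ratio([[33, 4], [8, 12]])  # both rows and columns swapped
        assert a.or_value == pytest.approx(b.or_value)
        assert a.ci_low == pytest.approx(b.ci_low)

    def test_zero_cell_gets_haldane_correction(self):
        r = gm.odds_ratio([[5, 0], [2, 7]])
        assert r.haldane_corrected
        assert r.or_value == pytest.approx((5.5 * 7.5) / (0.5 * 2.5))

    def test_zero_margin_is_undefined(self):
        with pytest.raises(gm.DegenerateInputError):
            gm.odds_ratio([[0, 0], [3, 4]])

    def test_woolf_ci_matches_statsmodels(self):
        import statsmodels.api as sm

        t = np.array([[12, 8], [4, 33]])
        res = sm.stats.Table2x2(t)
        r = gm.odds_ratio(t)
        lo, hi = res.oddsratio_confint()
        assert r.or_value == pytest.approx(res.oddsratio)
        assert r.ci_low == pytest.approx(lo)
        assert r.ci_high == pytest.approx(hi)

    @given(
        st.tuples(*[st.integers(0, 40)] * 4).filter(
            lambda t: (t[0] + t[1]) > 0 and (t[2] + t[3]) > 0
            and (t[0] + t[2]) > 0 and (t[1] + t[3]) > 0
        )
    )
    def test_transpose_and_reciprocal_identities(self, cells):
        a, b, c, d = cells
        r = gm.odds_ratio([[a, b], [c, d]])
        rt = gm.odds_ratio([[a, c], [b, d]])
        assert r.or_value == pytest.approx(rt.or_value)
        swapped = gm.odds_ratio([[b, a], [d, c]])
        assert r.or_value * swapped.or_value == pytest.approx(1.0)


# ---------------------------------------------------------------------- #
# Terciles
# ---------------------------------------------------------------------- #
class TestTerciles:
    def test_nine_points_split_evenly(self):
        g, (b1, b2) = gm.tercile_split(np.arange(1.0, 10.0))
        assert np.bincount(g).tolist() == [3, 3, 3]
        assert b1 < b2

    def test_override_boundaries_bin_by_hand(self):
        scores = [0.5, 3.4, 3.5, 7.0, 9.99, 10.0, 25.0]
        g, _ = gm.tercile_split(scores, (3.5, 10.0))
        assert g.tolist() == [0, 0, 1, 1, 1, 2, 2]

    def test_constant_scores_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            gm.tercile_split(np.full(9, 5.0), (3.5, 10.0))

    def test_too_few_scores_rejected(self):
        with pytest.raises(gm.DegenerateInputError):
            gm.tercile_split([1.0, 2.0])


# ---------------------------------------------------------------------- #
# Group comparisons
# ---------------------------------------------------------------------- #
class TestCompareGroups:
    def test_identical_category_distribution_gives_zero_chi2(self):
        values = ["a"] * 30 + ["b"] * 30
        groups = ([0] * 15 + [1] * 15) * 2
        r = gm.compare_groups(values, groups, kind="categorical")
        assert r.test == "chi-square"
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_sparse_2x2_uses_fisher_and_matches_enumeration(self):
        values = ["x"] * 5 + ["y"] * 5
        groups = [0] * 5 + [1] * 5  # table (5,0 / 0,5)
        r = gm.compare_groups(values, groups, kind="categorical")
        assert r.test == "fisher-exact"
        expected = fisher_p_by_hypergeom_enumeration([[5, 0], [0, 5]])
        assert r.p_value == pytest.approx(expected)
        assert r.p_value == pytest.approx(1 / 126)  # hand value: 2/C(10,5)

    def test_sparse_rxc_uses_seeded_monte_carlo(self):
        values = ["a", "a", "b", "b", "c", "c", "a", "b", "c"]
        groups = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        r1 = gm.compare_groups(values, groups, kind="categorical", seed=4)
        r2 = gm.compare_groups(values, groups, kind="categorical", seed=4)
        assert r1.test == "fisher-mc"
        assert r1.p_value == r2.p_value
        assert 0 < r1.p_value <= 1

    def test_mann_whitney_matches_pair_enumeration(self):
        x = [1.0, 5.0, 7.0, 7.0, 12.0]
        y = [2.0, 2.0, 7.0, 9.0]
        r = gm.compare_groups(x + y, [0] * 5 + [1] * 4, kind="continuous")
        assert r.test == "mann-whitney"
        assert r.statistic == pytest.approx(mann_whitney_u_by_enumeration(x, y))

    def test_three_groups_use_kruskal(self):
        rng = np.random.default_rng(8)
        vals = np.r_[rng.normal(0, 1, 20), rng.normal(2, 1, 20), rng.normal(4, 1, 20)]
        groups = np.repeat([0, 1, 2], 20)
        r = gm.compare_groups(vals, groups, kind="continuous")
        assert r.test == "kruskal"
        assert r.p_value < 0.001

    def test_single_group_rejected(self):
        with pytest.raises(gm.DegenerateInputError):
            gm.compare_groups([1, 2, 3], [0, 0, 0])


class TestSpearman:
    def test_perfect_monotone_relations(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert gm.spearman_corr(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert gm.spearman_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_tied_example_equals_pearson_of_average_ranks(self):
        from scipy.stats import rankdata

        x = [1.0, 2.0, 2.0, 4.0, 5.0]
        y = [2.0, 1.0, 3.0, 4.0, 4.0]
        rho, _ = gm.spearman_corr(x, y)
        expected = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
        assert rho == pytest.approx(expected)

    def test_constant_input_rejected(self):
        with pytest.raises(gm.DegenerateInputError):
            gm.spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------- #
# Kaplan–Meier / log-rank
# ---------------------------------------------------------------------- #
class TestSurvival:
    def test_km_without_censoring_is_empirical_survival(self):
        times = np.array([2.0, 3.0, 3.0, 5.0, 8.0, 13.0])
        events = np.ones(6, bool)
        km = gm.kaplan_meier(times, events)
        for t, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx((times > t).mean())

    def test_km_matches_lifelines_with_censoring(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(9)
        times = rng.exponential(10, 60).round(2)
        events = rng.uniform(size=60) < 0.7
        events[0] = True
        km = gm.kaplan_meier(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0])
            )

    def test_identical_groups_give_zero_statistic(self):
        times = [3.0, 5.0, 7.0, 9.0] * 2
        events = [1, 1, 0, 1] * 2
        groups = [0] * 4 + [1] * 4
        r = gm.km_logrank(times, events, groups)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_eight_observation_life_table_matches_hypergeometric_oracle(self):
        from scipy.stats import hypergeom

        times = [5.0, 6.0, 6.0, 8.0, 10.0, 12.0, 3.0, 9.0]
        events = [1, 1, 0, 1, 1, 0, 1, 1]
        groups = ["A", "A", "A", "A", "B", "B", "B", "B"]
        r = gm.km_logrank(times, events, groups)
        t_arr, e_arr = np.array(times), np.array(events, bool)
        g1 = np.array(groups) == "A"
        for row in r.life_table.itertuples():
            at_risk = t_arr >= row.time
            n, n1 = at_risk.sum(), (at_risk & g1).sum()
            d = ((t_arr == row.time) & e_arr).sum()
            dist = hypergeom(n, n1, d)  # draws of group-A events at this time
            assert row.e1 == pytest.approx(dist.mean())
            assert row.var == pytest.approx(dist.var())
        # observed events per group conserve
        assert sum(r.observed) == e_arr.sum()

    def test_statistic_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(10)
        t1 = rng.exponential(10, 40)
        t2 = rng.exponential(20, 40)
        times = np.r_[t1, t2]
        events = rng.uniform(size=80) < 0.8
        events[:2] = True
        groups = np.repeat([0, 1], 40)
        r = gm.km_logrank(times, events, groups)
        ll = logrank_test(t1, t2, events[:40], events[40:])
        assert r.statistic == pytest.approx(ll.test_statistic)
        assert r.p_value == pytest.approx(ll.p_value)

    def test_no_events_rejected(self):
        with pytest.raises(gm.DegenerateInputError):
            gm.km_logrank([1.0, 2.0], [0, 0], [0, 1])

    def test_three_groups_rejected(self):
        with pytest.raises(gm.DegenerateInputError):
            gm.km_logrank([1.0, 2.0, 3.0], [1, 1, 1], [0, 1, 2])
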