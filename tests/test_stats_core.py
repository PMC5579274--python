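"""Rank correlation, FDR, MIC, ROC/DeLong, concordance and Kaplan-Meier."""

import numpy as np
import pytest
from scipy import stats as sps

from radrisk.mic import mic
from radrisk.stats_core import (
    SurvivalData,
    benjamini_hochberg,
    concordance_index,
    delong_test,
    km_logrank,
    roc_metrics,
    spearman,
    univariate_screen,
)

from _oracles import (
    auc_pair_oracle,
    bh_oracle,
    ci_pair_oracle,
    logrank_oracle,
    mic_small_oracle,
)


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_constant_input_degenerate(self):
        r = spearman([1, 1, 1], [1, 2, 3])
        assert r == (0.0, 1.0, True)

    def test_ties_equal_midrank_pearson(self, rng):
        for _ in range(10):
            x = rng.integers(0, 4, 15).astype(float)
            y = rng.integers(0, 3, 15).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r = spearman(x, y)
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            assert r.rho == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    def test_t_approximation_matches_scipy(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        ours = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert ours.rho == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        np.testing.assert_array_equal(
            benjamini_hochberg([0.001, 0.2, 0.9], 0.1), [True, False, False]
        )

    def test_all_ones_no_flags(self):
        assert not benjamini_hochberg([1.0, 1.0, 1.0], 0.1).any()

    def test_empty_input(self):
        assert benjamini_hochberg([], 0.1).size == 0

    def test_matches_exhaustive_threshold_search(self, rng):
        for _ in range(25):
            p = rng.random(rng.integers(1, 30))
            q = rng.choice([0.05, 0.1, 0.2])
            np.testing.assert_array_equal(benjamini_hochberg(p, q), bh_oracle(p, q))

    def test_monotonicity_lowering_p_keeps_flags(self, rng):
        p = rng.random(20)
        base = benjamini_hochberg(p, 0.1)
        p2 = p.copy()
        p2[np.argmax(p)] = 0.0
        after = benjamini_hochberg(p2, 0.1)
        assert (after[base] | (np.arange(20) == np.argmax(p))[base]).all()


class TestMIC:
    def test_identity_relation_saturates(self, rng):
        x = rng.random(100)
        assert mic(x, x) >= 0.99

    def test_quadratic_noiseless(self, rng):
        x = rng.uniform(-1, 1, 150)
        assert mic(x, x**2) >= 0.9

    def test_independent_low_on_average(self, rng):
        vals = [mic(rng.random(200), rng.random(200)) for _ in range(8)]
        assert np.mean(vals) < 0.3

    def test_symmetry(self, rng):
        x, y = rng.random(80), rng.random(80)
        assert mic(x, y) == pytest.approx(mic(y, x), abs=1e-9)

    def test_constant_input_zero(self, rng):
        assert mic(np.ones(50), rng.random(50)) == 0.0

    def test_close_to_exhaustive_oracle_small_n(self, rng):
        # the heuristic search is a lower bound on the exhaustive optimum and
        # should come close for monotone data at tiny n
        x = rng.permutation(np.arange(12, dtype=float))
        y = x + rng.normal(0, 0.4, 12)
        ours = mic(x, y)
        exact = mic_small_oracle(x, y, b=4)
        assert ours <= exact + 1e-9
        assert ours >= exact - 0.25


class TestROC:
    def test_perfect_separation(self):
        r = roc_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r == (1.0, 1.0, 1.0, 1.0)

    def test_constant_scores_give_half(self):
        assert roc_metrics([0.3] * 6, [1, 1, 0, 0, 0, 0]).auc == 0.5

    def test_one_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_metrics([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(6, 25)
            scores = rng.choice(np.linspace(0, 1, 7), n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_metrics(scores, labels).auc == pytest.approx(
                auc_pair_oracle(scores, labels)
            )

    def test_auc_invariant_under_monotone_transform(self, rng):
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        a1 = roc_metrics(s, y).auc
        a2 = roc_metrics(np.exp(3 * s), y).auc
        assert a1 == pytest.approx(a2)


class TestDeLong:
    def test_identical_predictors_p_one(self, rng):
        s = rng.random(40)
        y = (rng.random(40) < 0.4).astype(int)
        assert delong_test(s, s, y) == 1.0

    def test_structural_components_hand_case(self):
        # 2 cases (0.9, 0.6), 3 controls (0.1, 0.5, 0.7)
        s = np.array([0.9, 0.6, 0.1, 0.5, 0.7])
        y = np.array([1, 1, 0, 0, 0])
        from radrisk.stats_core import _delong_structural

        auc, v10, v01 = _delong_structural(s, y)
        assert auc == pytest.approx(auc_pair_oracle(s, y))
        # V10 per case: fraction of controls below it
        np.testing.assert_allclose(v10, [1.0, 2 / 3])
        np.testing.assert_allclose(v01, [1.0, 1.0, 0.5])

    def test_agrees_with_permutation_oracle(self, rng):
        n = 30
        x = rng.normal(size=n)
        y = (rng.random(n) < 0.5).astype(int)
        y[:2] = [0, 1]
        sa = x + rng.normal(0, 0.5, n)
        sb = x + rng.normal(0, 0.5, n)
        p_dl = delong_test(sa, sb, y)
        # permutation oracle: swap the paired scores at random
        from radrisk.stats_core import auc_mann_whitney

        obs = abs(auc_mann_whitney(sa, y) - auc_mann_whitney(sb, y))
        count = 0
        n_perm = 400
        for _ in range(n_perm):
            swap = rng.random(n) < 0.5
            pa = np.where(swap, sb, sa)
            pb = np.where(swap, sa, sb)
            if abs(auc_mann_whitney(pa, y) - auc_mann_whitney(pb, y)) >= obs - 1e-12:
                count += 1
        assert p_dl == pytest.approx(count / n_perm, abs=0.08)


class TestConcordance:
    def test_perfect_anti_ordering(self):
        sv = SurvivalData([5, 4, 3, 2, 1], [1, 1, 1, 1, 1])
        assert concordance_index([1, 2, 3, 4, 5], sv) == 1.0

    def test_all_tied_scores_half(self):
        sv = SurvivalData([5, 4, 3, 2, 1], [1, 1, 1, 1, 1])
        assert concordance_index([2, 2, 2, 2, 2], sv) == 0.5

    def test_censored_toy_matches_pair_oracle(self, rng):
        for _ in range(15):
            t = rng.integers(1, 12, 6).astype(float)
            e = rng.integers(0, 2, 6)
            r = rng.choice([0.1, 0.4, 0.4, 0.8], 6)
            if not ((e == 1) & (t < t.max())).any():
                continue
            assert concordance_index(r, SurvivalData(t, e)) == pytest.approx(
                ci_pair_oracle(r, t, e)
            )

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines.utils import concordance_index as ll_ci

        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        e[0] = 1
        r = rng.random(50)
        ours = concordance_index(r, SurvivalData(t, e))
        theirs = ll_ci(t, -r, e)  # lifelines: higher score = longer survival
        assert ours == pytest.approx(theirs)

    def test_reduces_to_auc_with_distinct_event_times(self, rng):
        t = rng.permutation(np.arange(1.0, 21.0))
        e = np.ones(20, dtype=int)
        r = rng.random(20)
        # label = 1 for the earlier half: CI generalizes pairwise ordering,
        # here every pair is permissible so CI equals rank agreement
        ci = concordance_index(r, SurvivalData(t, e))
        assert ci == pytest.approx(ci_pair_oracle(r, t, e))

    def test_no_permissible_pairs_errors(self):
        sv = SurvivalData([5, 5], [0, 0])
        with pytest.raises(ValueError, match="permissible"):
            concordance_index([0.1, 0.2], sv)


class TestKaplanMeierLogRank:
    def test_identical_groups_null(self):
        t = np.array([3, 5, 7, 9, 11.0] * 2)
        e = np.array([1, 0, 1, 1, 0] * 2)
        g = np.array(["a"] * 5 + ["b"] * 5)
        res = km_logrank(g, SurvivalData(t, e))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_toy_matches_hand_table(self):
        t = np.array([2, 4, 6, 8, 10, 3, 5, 7, 9, 11.0])
        e = np.array([1, 1, 0, 1, 0, 1, 0, 1, 1, 1])
        g = np.array(["a"] * 5 + ["b"] * 5)
        res = km_logrank(g, SurvivalData(t, e))
        assert res.statistic == pytest.approx(logrank_oracle(t, e, g), rel=1e-6)

    def test_single_group_curve_steps(self):
        t = np.array([1, 2, 3, 4.0])
        e = np.ones(4, dtype=int)
        g = np.array(["a", "a", "a", "b"])
        res = km_logrank(g, SurvivalData(t, e))
        surv = res.curves["a"].survival_function_.iloc[:, 0].to_numpy()
        np.testing.assert_allclose(surv, [1.0, 2 / 3, 1 / 3, 0.0])

    def test_three_group_pairwise(self, rng):
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        e[:10] = 1
        g = np.repeat(["low", "med", "high"], 20)
        res = km_logrank(g, SurvivalData(t, e))
        assert len(res.pairwise) == 3
        assert all(0 <= p <= 1 for p in res.pairwise.values())

    def test_empty_group_errors(self):
        sv = SurvivalData([1, 2, 3.0], [1, 0, 1])
        with pytest.raises(ValueError):
            km_logrank(np.array(["a", "a", "a"]), sv)


def test_univariate_screen_flags_injected_signal(rng):
    import pandas as pd

    n = 120
    y = (rng.random(n) < 0.3).astype(int)
    X = pd.DataFrame({f"noise{i}": rng.normal(size=n) for i in range(20)})
    X["signal"] = y * 2.0 + rng.normal(0, 0.5, n)
    res = univariate_screen(X, y, q=0.10)
    by_name = {r.feature_name: r for r in res}
    assert by_name["signal"].significant_after_fdr
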