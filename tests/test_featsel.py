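"""Boruta-style shadow testing, LASSO, LMG importance, ABC aggregation."""

from itertools import permutations

import numpy as np
import pytest
from scipy import stats

from olfrisk.featsel import (
    abc_analysis,
    boruta_select,
    final_feature_set,
    lasso_select,
    lmg_importance,
    resampled_selection,
)


class TestBoruta:
    def test_near_zero_false_confirmations_on_noise(self):
        confirmed = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 15))
            y = rng.normal(size=200)
            confirmed.append(
                len(boruta_select(X, y, seed=seed, max_iter=50, n_trees=60))
            )
        assert np.mean(confirmed) < 0.5

    def test_dominant_predictor_confirmed(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(150, 10))
            y = X[:, 0] + 0.3 * rng.normal(size=150)
            sel = boruta_select(X, y, seed=seed, max_iter=50, n_trees=60)
            hits += 0 in sel
        assert hits >= 19  # >= 95% of 20 seeds

    def test_decision_thresholds_match_binomial_quantiles(self):
        # a feature is confirmed at trials t iff hits >= smallest h with
        # two-sided binomial p < alpha/d and h > t/2 — the closed-form quantile
        alpha, d = 0.01, 15
        a_eff = alpha / d
        for trials in (10, 20, 35, 50):
            decisions = [
                stats.binomtest(h, trials, 0.5).pvalue < a_eff and h > trials / 2
                for h in range(trials + 1)
            ]
            confirm_from = next(
                (h for h, dec in enumerate(decisions) if dec), trials + 1
            )
            # closed-form: smallest h with 2 * P(Bin >= h) < a_eff
            closed = next(
                (
                    h
                    for h in range(trials // 2 + 1, trials + 1)
                    if 2.0 * stats.binom.sf(h - 1, trials, 0.5) < a_eff
                ),
                trials + 1,
            )
            assert confirm_from == closed
            assert all(decisions[confirm_from:]) or confirm_from > trials

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError):
            boruta_select(rng.normal(size=(30, 4)), np.ones(30))


class TestLasso:
    def test_dominant_predictor_selected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 10))
            y = X[:, 0] + 0.5 * rng.normal(size=200)
            hits += 0 in lasso_select(X, y, seed=seed)
        assert hits >= 19

    def test_noise_design_selects_little(self):
        sizes = []
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            X = rng.normal(size=(120, 12))
            y = rng.normal(size=120)
            sizes.append(len(lasso_select(X, y, seed=seed)))
        assert np.median(sizes) <= 2

    def test_n_smaller_than_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            lasso_select(rng.normal(size=(3, 4)), rng.normal(size=3), folds=5)


class TestLmgImportance:
    def test_orthogonal_predictors_marginal_r2(self):
        rng = np.random.default_rng(2)
        n = 4000
        X = rng.normal(size=(n, 3))
        y = 1.0 * X[:, 0] + 0.5 * X[:, 1] + rng.normal(size=n)
        imp = lmg_importance(X, y)
        for j in range(3):
            marg = np.corrcoef(X[:, j], y)[0, 1] ** 2
            assert imp[j] == pytest.approx(marg, abs=0.01)

    def test_two_predictors_hand_averaged_orderings(self, rng):
        n = 300
        x1 = rng.normal(size=n)
        x2 = 0.6 * x1 + 0.8 * rng.normal(size=n)
        y = x1 + 0.5 * x2 + rng.normal(size=n)
        X = np.column_stack([x1, x2])
        imp = lmg_importance(X, y)
        r1 = np.corrcoef(x1, y)[0, 1] ** 2
        r2 = np.corrcoef(x2, y)[0, 1] ** 2
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        R = np.corrcoef(Z, rowvar=False)
        ry = np.array([np.corrcoef(x1, y)[0, 1], np.corrcoef(x2, y)[0, 1]])
        rfull = float(ry @ np.linalg.solve(R, ry))
        assert imp[0] == pytest.approx(0.5 * r1 + 0.5 * (rfull - r2), abs=1e-9)
        assert imp[1] == pytest.approx(0.5 * r2 + 0.5 * (rfull - r1), abs=1e-9)

    def test_importances_sum_to_model_r2(self, rng):
        X = rng.normal(size=(100, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=100)
        imp = lmg_importance(X, y)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        beta = np.linalg.lstsq(Z, zy, rcond=None)[0]
        r2 = 1 - np.sum((zy - Z @ beta) ** 2) / np.sum(zy**2)
        assert imp.sum() == pytest.approx(r2, abs=1e-6)
        assert (imp > -1e-9).all()

    def test_monte_carlo_close_to_exact(self, rng):
        X = rng.normal(size=(150, 6))
        X[:, 1] += 0.5 * X[:, 0]
        y = X[:, 0] + 0.7 * X[:, 2] + rng.normal(size=150)
        exact = lmg_importance(X, y)
        mc = lmg_importance(X, y, max_exact=2, n_orderings=4000, seed=0)
        np.testing.assert_allclose(mc, exact, atol=0.01)

    def test_singular_design_rejected(self, rng):
        X = rng.normal(size=(50, 3))
        X[:, 2] = 5.0
        with pytest.raises(ValueError):
            lmg_importance(X, rng.normal(size=50))


class TestAbcAnalysis:
    def test_single_dominant_item_is_a(self):
        res = abc_analysis(np.array([100.0, 1, 1, 1, 1]))
        assert res.set_a == [0]
        assert set(res.set_b) | set(res.set_c) == {1, 2, 3, 4}

    def test_uniform_values_keep_order_and_cover(self):
        res = abc_analysis(np.full(10, 3.0))
        assert res.ab_limit >= 1
        assert res.bc_limit == 10  # break-even at the mean covers every item
        assert sorted(res.set_a + res.set_b + res.set_c) == list(range(10))

    def test_ordering_property(self, rng):
        for _ in range(20):
            v = rng.exponential(size=rng.integers(3, 30)) + 1e-6
            res = abc_analysis(v)
            if res.set_a and res.set_b:
                assert v[res.set_a].min() >= v[res.set_b].max()
            if res.set_b and res.set_c:
                assert v[res.set_b].max() >= v[res.set_c].max() - 1e-12

    def test_positive_rescaling_invariance(self, rng):
        v = rng.exponential(size=25) + 0.1
        a = abc_analysis(v)
        b = abc_analysis(v * 37.5)
        assert (a.set_a, a.set_b, a.set_c) == (b.set_a, b.set_b, b.set_c)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            abc_analysis(np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            abc_analysis(np.array([]))


class TestResampledSelection:
    def test_strong_feature_counted_every_run(self, rng):
        X = rng.normal(size=(120, 6))
        y = 2.0 * X[:, 3] + 0.2 * rng.normal(size=120)
        counts, sizes, fails = resampled_selection(
            "lasso", X, y, runs=40, seed=0
        )
        assert counts[3] == 40
        assert fails == 0
        assert (counts <= 40).all()

    def test_reproducible_from_seed(self, rng):
        X = rng.normal(size=(90, 5))
        y = X[:, 0] + rng.normal(size=90)
        a = resampled_selection("lasso", X, y, runs=20, seed=3)
        b = resampled_selection("lasso", X, y, runs=20, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_subsamples_are_two_thirds_without_replacement(self, rng):
        seen = []

        def recorder(X, y, seed):
            seen.append(X.shape[0])
            return [0]

        n = 100
        X = rng.normal(size=(n, 4))
        y = rng.normal(size=n)
        resampled_selection(recorder, X, y, runs=25, seed=1)
        assert seen == [int(np.floor(2 * n / 3))] * 25

    def test_selector_failures_counted(self, rng):
        def flaky(X, y, seed):
            raise ValueError("no")

        counts, sizes, fails = resampled_selection(
            flaky, rng.normal(size=(30, 3)), rng.normal(size=30), runs=5, seed=0
        )
        assert fails == 5
        assert sizes.size == 0 or (sizes >= 0).all()


class TestFinalFeatureSet:
    def test_informative_features_form_final_set(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(150, 15))
            y = X[:, 0] + X[:, 1] + X[:, 2] + 0.5 * rng.normal(size=150)
            counts, sizes, _ = resampled_selection("lasso", X, y, runs=30, seed=seed)
            rep = final_feature_set(counts, sizes)
            wins += set(rep.final_set) >= {"x0", "x1", "x2"} and rep.modal_set_size <= 6
        assert wins >= 6  # majority of seeds

    def test_unanimous_runs_reproduce_the_set(self):
        counts = np.array([10, 10, 0, 0, 10])
        sizes = np.full(10, 3)
        rep = final_feature_set(counts, sizes, ["a", "b", "c", "d", "e"])
        assert rep.final_set == ["a", "b", "e"]
        assert rep.modal_set_size == 3
        assert rep.abc_labels["c"] == "never"

    def test_disagreement_flag_on_rule_conflict(self):
        # modal size 1 but ABC set A holds two equally-counted features
        counts = np.array([10, 10, 1, 0])
        sizes = np.array([1, 1, 1, 1, 2])
        rep = final_feature_set(counts, sizes, ["a", "b", "c", "d"])
        assert rep.modal_set_size == 1
        assert rep.disagreement  # tie at the cut widened the set
        assert set(rep.final_set) == {"a", "b"}

    def test_all_zero_counts_empty_final_set(self):
        rep = final_feature_set(np.zeros(4, int), np.zeros(6, int), list("abcd"))
        assert rep.final_set == []
        assert rep.modal_set_size == 0

    def test_empty_runs_rejected(self):
        with pytest.raises(ValueError):
            final_feature_set(np.array([1, 2]), np.array([], dtype=int))


class TestAbcProperties:
    """Hypothesis-driven invariants of the ABC partition."""

    from hypothesis import given, settings, strategies as st

    @given(
        st.lists(st.integers(1, 10_000), min_size=1, max_size=40),
        st.integers(2, 1000),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_partition_exhaustive_ordered_and_scale_invariant(self, vals, scale):
        v = np.asarray(vals, float)
        res = abc_analysis(v)
        assert sorted(res.set_a + res.set_b + res.set_c) == list(range(len(v)))
        if res.set_a and res.set_b:
            assert v[res.set_a].min() >= v[res.set_b].max()
        scaled = abc_analysis(v * scale)  # integer scale: exact arithmetic
        assert (scaled.set_a, scaled.set_b, scaled.set_c) == (
            res.set_a, res.set_b, res.set_c
        )
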