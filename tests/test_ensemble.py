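"""Balanced-subset ensembles, aggregation, weights, stability selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppiface.ensemble import (
    EasyEnsembleClassifier,
    aggregate,
    make_balanced_subsets,
    stability_select,
    train_ensemble,
    training_weights,
)
from ppiface.hierarchy import HierarchyLogisticClassifier
from ppiface.learners import BaseLearnerSpec, LassoLogistic, positive_proba
from ppiface.evaluation import tp_at_k


def imbalanced_y(n_pos=10, n_neg=1000):
    return np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]


class TestBalancedSubsets:
    def test_sizes_and_exact_balance(self):
        subs = make_balanced_subsets(imbalanced_y(), T=5, seed=0)
        assert len(subs) == 5
        for s in subs:
            assert len(s.positive) == len(s.negative) == 10
            assert len(s.indices) == 20
            assert len(np.unique(s.negative)) == 10  # without replacement

    def test_identical_positive_set_across_subsets(self):
        subs = make_balanced_subsets(imbalanced_y(), T=4, seed=1)
        for s in subs[1:]:
            np.testing.assert_array_equal(s.positive, subs[0].positive)

    def test_deterministic(self):
        a = make_balanced_subsets(imbalanced_y(), T=3, seed=9)
        b = make_balanced_subsets(imbalanced_y(), T=3, seed=9)
        for s, t in zip(a, b):
            np.testing.assert_array_equal(s.indices, t.indices)

    def test_negative_coverage_grows(self):
        # 50 subsets x 10 negatives = 500 draws from 1000; the occupancy
        # bound E[unique] = 1000 (1 - (1 - 1/100)^50) ~ 394 scales with T
        subs = make_balanced_subsets(imbalanced_y(), T=50, seed=2)
        union = set(np.concatenate([s.negative for s in subs]))
        assert len(union) > 300
        subs10 = make_balanced_subsets(imbalanced_y(), T=10, seed=2)
        union10 = set(np.concatenate([s.negative for s in subs10]))
        assert len(union10) < len(union)

    def test_default_T(self):
        subs = make_balanced_subsets(imbalanced_y(10, 230), seed=0)
        assert len(subs) == 23

    def test_errors(self):
        with pytest.raises(ValueError, match="classes"):
            make_balanced_subsets(np.ones(5, int), T=2)
        with pytest.raises(ValueError, match="fewer negatives"):
            make_balanced_subsets(imbalanced_y(50, 10), T=2)


class TestAggregate:
    def test_mean_and_median_column(self):
        P = np.array([[0.2], [0.4], [0.6]])
        assert aggregate(P, "mean")[0] == pytest.approx(0.4)
        assert aggregate(P, "median")[0] == pytest.approx(0.4)

    def test_degenerate_weight_selects_row(self):
        P = np.random.default_rng(0).random((3, 8))
        np.testing.assert_allclose(
            aggregate(P, "weighted_mean", weights=[1, 0, 0]), P[0]
        )

    def test_weighted_requires_weights(self):
        with pytest.raises(ValueError, match="weights"):
            aggregate(np.ones((2, 3)), "weighted_mean")
        with pytest.raises(ValueError, match="not all zero"):
            aggregate(np.ones((2, 3)), "weighted_mean", weights=[0, 0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_by_row_extremes(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((rng.integers(1, 6), rng.integers(1, 7)))
        w = rng.random(P.shape[0]) + 1e-3
        for agg in (
            aggregate(P, "mean"),
            aggregate(P, "median"),
            aggregate(P, "weighted_mean", weights=w),
        ):
            assert np.all(agg <= P.max(axis=0) + 1e-12)
            assert np.all(agg >= P.min(axis=0) - 1e-12)

    def test_mean_is_linear(self):
        P = np.random.default_rng(3).random((4, 5))
        np.testing.assert_allclose(aggregate(0.5 * P, "mean"), 0.5 * aggregate(P, "mean"))


class TestEnsemble:
    def test_T1_equals_single_model(self, separated_xy):
        X, y = separated_xy
        ens = train_ensemble(X, y, BaseLearnerSpec("lasso_logistic", {"lam": 0.01}, 3), T=1)
        single = positive_proba(ens.models_[0], X)
        for agg in ("mean", "median"):
            ens.aggregation = agg
            np.testing.assert_allclose(positive_proba(ens, X), single)

    def test_ensemble_bounded_by_member_extremes(self, separated_xy):
        X, y = separated_xy
        ens = train_ensemble(X, y, BaseLearnerSpec("lasso_logistic", {"lam": 0.01}, 0), T=5)
        P = ens.proba_matrix(X)
        agg = positive_proba(ens, X)
        assert np.all(agg <= P.max(axis=0) + 1e-12)
        assert np.all(agg >= P.min(axis=0) - 1e-12)

    def test_ensemble_improves_over_median_member(self, separated_xy):
        from sklearn.metrics import roc_auc_score

        X, y = separated_xy
        ens = train_ensemble(X, y, BaseLearnerSpec("lasso_logistic", {"lam": 0.01}, 5), T=15)
        aucs = [roc_auc_score(y, positive_proba(m, X)) for m in ens.models_]
        auc_ens = roc_auc_score(y, positive_proba(ens, X))
        assert auc_ens >= np.median(aucs)

    def test_frequency_of_universally_selected_term(self, separated_xy):
        X, y = separated_xy
        ens = train_ensemble(X, y, BaseLearnerSpec("lasso_logistic", {"lam": 0.01}, 1), T=8)
        freqs = ens.selection_frequencies()
        assert max(freqs.values()) == 1.0
        assert all(0 <= f <= 1 for f in freqs.values())


class TestTrainingWeights:
    def test_perfect_model_counts_all_dimers(self):
        rng = np.random.default_rng(0)
        n = 400
        y = (rng.random(n) < 0.05).astype(int)
        y[:2] = 1
        dimers = np.repeat(["A", "B"], n // 2)

        class Perfect:
            def predict_proba(self, X):
                p = y.astype(float)
                return np.column_stack([1 - p, p])

        ens = EasyEnsembleClassifier()
        ens.models_ = [Perfect()]
        X = rng.standard_normal((n, 3))
        w = training_weights(ens, X, y, dimers, k=20)
        assert list(w) == [2]

    def test_adversarial_model_scores_zero(self):
        n = 200
        y = np.zeros(n, int)
        y[-5:] = 1  # worst rank for descending-probability order below
        dimers = np.array(["D"] * n)

        class Adversarial:  # ranks all negatives above all positives
            def predict_proba(self, X):
                p = np.linspace(1, 0, n)
                p[-5:] = 0.0
                return np.column_stack([1 - p, p])

        ens = EasyEnsembleClassifier()
        ens.models_ = [Adversarial()]
        w = training_weights(ens, np.zeros((n, 2)), y, dimers, k=20)
        assert list(w) == [0]

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(8)
        frames = []
        y_all, d_all, p_all = [], [], []
        for d in range(10):
            n = rng.integers(50, 150)
            y = (rng.random(n) < 0.08).astype(int)
            if y.sum() == 0:
                y[0] = 1
            y_all.append(y)
            d_all.append(np.full(n, f"D{d}"))
        y = np.concatenate(y_all)
        dimers = np.concatenate(d_all)
        T = 4
        P = rng.random((T, len(y)))

        class Fixed:
            def __init__(self, row):
                self.row = row

            def predict_proba(self, X):
                return np.column_stack([1 - self.row, self.row])

        ens = EasyEnsembleClassifier()
        ens.models_ = [Fixed(P[t]) for t in range(T)]
        w = training_weights(ens, np.zeros((len(y), 1)), y, dimers, k=20)
        # independent recount via tp_at_k
        expect = []
        for t in range(T):
            c = 0
            for d in np.unique(dimers):
                m = dimers == d
                c += tp_at_k(P[t, m], y[m], 20) >= 1
            expect.append(c)
        assert list(w) == expect


class TestStabilitySelection:
    @staticmethod
    def _ens_with_selected(sets):
        """Ensemble whose models' selected terms are given explicitly."""
        models = []
        for terms in sets:
            m = LassoLogistic()
            p = 40
            coef = np.zeros(p)
            for t in terms:
                if t.startswith("main:"):
                    coef[int(t.split(":")[1]) - 1] = 1.0
            m.coef_ = coef[None, :]
            if any(t.startswith("int:") for t in terms):
                h = HierarchyLogisticClassifier()
                h.intercept_ = 0.0
                h.main_effects_ = coef
                h.interaction_effects_ = {
                    tuple(int(v) - 1 for v in t.split(":")[1:]): 1.0
                    for t in terms
                    if t.startswith("int:")
                }
                models.append(h)
            else:
                models.append(m)
        ens = EasyEnsembleClassifier()
        ens.models_ = models
        return ens

    def test_majority_main_effect_included(self):
        sets = [{"main:1"}] * 19 + [set()]
        ens = self._ens_with_selected(sets)
        assert stability_select(ens) == {"main:1"}

    def test_interaction_at_exact_threshold_excluded(self):
        sets = [{"main:1", "main:2", "int:1:2"}] * 16 + [{"main:1"}] * 4
        ens = self._ens_with_selected(sets)  # int frequency exactly 0.80
        sel = stability_select(ens)
        assert "int:1:2" not in sel  # strictly-larger-than semantics
        assert "main:1" in sel

    def test_frequencies_invariant_to_subset_order(self):
        sets = [{"main:1"}, {"main:2"}, {"main:1", "main:2"}]
        a = self._ens_with_selected(sets).selection_frequencies()
        b = self._ens_with_selected(sets[::-1]).selection_frequencies()
        assert a == b

    def test_recovers_informative_features(self):
        from ppiface.simulate import simulate_sparse_logistic

        X, y, inf = simulate_sparse_logistic(6000, 30, 3, seed=3)
        ens = EasyEnsembleClassifier(
            kind="lasso_logistic", hyperparams={"lam": 0.01}, T=25, random_state=3
        ).fit(X, y)
        sel = stability_select(ens)
        want = {f"main:{i + 1}" for i in inf}
        assert want <= sel
        assert len(sel - want) <= 3
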