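"""Ranking metrics, correct-dimer curves, and attribute association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ppiface.data import table2_fixture
from ppiface.evaluation import (
    anova_ranks,
    bin_attributes,
    evaluate,
    pearson_attributes,
    rank_first_tp,
    sequential_f_tests,
    tp_at_k,
)


class TestRankFirstTP:
    def test_basic(self):
        assert rank_first_tp([0.9, 0.8, 0.7], [0, 1, 0]) == 2

    def test_stable_tie_break(self):
        assert rank_first_tp([0.5, 0.5, 0.5], [1, 0, 0]) == 1
        assert rank_first_tp([0.5, 0.5, 0.5], [0, 0, 1]) == 3

    def test_no_positive_error(self):
        with pytest.raises(ValueError, match="no positive"):
            rank_first_tp([0.1, 0.2], [0, 0])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        prob = rng.random(500)
        labels = (rng.random(500) < 0.02).astype(int)
        labels[7] = 1
        r = rank_first_tp(prob, labels)
        assert rank_first_tp(prob**3, labels) == r
        assert rank_first_tp(1 - np.exp(-5 * prob), labels) == r

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(12)
        prob = rng.random(1000)
        labels = (rng.random(1000) < 0.01).astype(int)
        labels[0] = 1
        order = sorted(range(1000), key=lambda i: (-prob[i], i))
        brute = next(k + 1 for k, i in enumerate(order) if labels[i] == 1)
        assert rank_first_tp(prob, labels) == brute


class TestEvaluate:
    @staticmethod
    def random_predictions(n_dimers=12, seed=4):
        rng = np.random.default_rng(seed)
        frames = []
        for d in range(n_dimers):
            n = int(rng.integers(80, 400))
            labels = (rng.random(n) < 0.05).astype(int)
            labels[int(rng.integers(n))] = 1
            frames.append(pd.DataFrame({
                "dimer_id": f"D{d}", "prob": rng.random(n), "label": labels,
            }))
        return pd.concat(frames, ignore_index=True)

    def test_perfect_ranking(self):
        preds = self.random_predictions()
        preds["prob"] = preds["label"].astype(float)
        res = evaluate(preds, k_max=30)
        n_dimers = preds.dimer_id.nunique()
        assert (res.curve.correct_dimers == n_dimers).all()
        assert res.curve.accuracy.iloc[0] == pytest.approx(1.0)  # k=1
        assert (res.per_dimer.rank_first_tp == 1).all()

    def test_worst_ranking_zero_correct(self):
        rng = np.random.default_rng(5)
        n = 500
        labels = np.zeros(n, int)
        labels[-3:] = 1
        preds = pd.DataFrame({
            "dimer_id": "D", "prob": np.linspace(1, 0.5, n) * (1 - labels),
            "label": labels,
        })
        res = evaluate(preds, k_max=100)
        assert (res.curve.correct_dimers == 0).all()

    def test_matches_independent_recount(self):
        preds = self.random_predictions()
        res = evaluate(preds, k_max=150)
        for k in (1, 7, 20, 150):
            correct = 0
            total_tp = 0
            for _, sub in preds.groupby("dimer_id"):
                tp = tp_at_k(sub.prob.to_numpy(), sub.label.to_numpy(), k)
                total_tp += tp
                correct += tp >= 1
            n_dimers = preds.dimer_id.nunique()
            assert res.correct_dimers(k) == correct
            assert res.accuracy(k) == pytest.approx(total_tp / (k * n_dimers))

    def test_metric_sanity_properties(self):
        preds = self.random_predictions(seed=9)
        res = evaluate(preds, k_max=150)
        n_dimers = preds.dimer_id.nunique()
        assert (np.diff(res.curve.correct_dimers) >= 0).all()
        pooled = res.curve.accuracy * res.curve.k * n_dimers
        np.testing.assert_allclose(pooled, np.round(pooled), atol=1e-9)


class TestPearson:
    def test_fixture_reproduces_printed_coefficients(self):
        assoc = pearson_attributes(table2_fixture())
        assert round(assoc.correlations.loc["p", "nsrp"], 2) == -0.65
        assert round(assoc.correlations.loc["p", "distance"], 2) == -0.38
        assert round(assoc.correlations.loc["distance", "nsrp"], 2) == 0.54
        assert np.allclose(assoc.correlations, assoc.correlations.T)
        assert np.allclose(np.diag(assoc.correlations), 1.0)

    def test_hand_dataset_matches_closed_form(self):
        df = pd.DataFrame({
            "p": [1.0, 2, 3, 4, 5], "distance": [2.0, 1, 4, 3, 7],
            "nsrp": [5.0, 4, 3, 2, 1],
        })
        assoc = pearson_attributes(df)
        x, y = df.p - df.p.mean(), df.distance - df.distance.mean()
        r_manual = (x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum())
        assert assoc.correlations.loc["p", "distance"] == pytest.approx(r_manual)
        assert assoc.correlations.loc["p", "nsrp"] == pytest.approx(-1.0)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"p": [1, 1, 1.0], "distance": [1, 2, 3.0], "nsrp": [3, 2, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            pearson_attributes(df)


class TestAnova:
    def test_constructed_response_loads_on_p(self):
        fx = table2_fixture().copy()
        fx["rank_fake"] = 1000.0 * fx.p
        table = anova_ranks(fx, "fake")
        assert table.loc["p", "F"] > 1e6
        assert table.loc["distance", "F"] < 1e-6
        assert table.loc["nsrp", "F"] < 1e-6

    def test_row_permutation_invariance(self):
        fx = table2_fixture()
        a = anova_ranks(fx, "svm")
        b = anova_ranks(fx.sample(frac=1.0, random_state=0), "svm")
        pd.testing.assert_frame_equal(a, b)

    def test_agrees_with_independent_sequential_ss(self):
        fx = table2_fixture()
        ours = anova_ranks(fx, "svm")
        other = sequential_f_tests(
            fx, "rank_svm", [["category"], ["p"], ["distance"], ["nsrp"]]
        )
        np.testing.assert_allclose(ours["F"].to_numpy(), other["F"].to_numpy(), rtol=1e-8)
        np.testing.assert_allclose(
            ours["PR(>F)"].to_numpy(), other["PR(>F)"].to_numpy(), rtol=1e-8
        )

    def test_missing_rank_column(self):
        with pytest.raises(ValueError, match="rank_xgb"):
            anova_ranks(table2_fixture(), "xgb")


class TestBinning:
    def test_paper_thresholds(self):
        df = pd.DataFrame({"p": [0.0056, 0.001, 0.003], "distance": [1.5, 2.0, 1.0],
                           "nsrp": [40000, 20000, 10000]})
        out = bin_attributes(df)
        assert list(out.p) == ["high", "low", "mid"]
        assert list(out.distance) == ["mid", "high", "low"]  # left-closed bounds
        assert list(out.nsrp) == ["high", "mid", "low"]

    def test_fixture_counts_match_hand_recount(self):
        fx = table2_fixture()
        out = bin_attributes(fx)
        # independent recount with explicit comparisons
        assert (out.p == "high").sum() == sum(v >= 0.004 for v in fx.p)
        assert (out.p == "low").sum() == sum(v < 0.002 for v in fx.p)
        assert (out.distance == "mid").sum() == sum(1.5 <= v < 2.0 for v in fx.distance)
        assert (out.nsrp == "high").sum() == sum(v >= 35000 for v in fx.nsrp)

    def test_unsorted_cutpoints_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            bin_attributes(pd.DataFrame({"p": [0.1]}), {"p": (0.4, 0.2)})
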