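"""Confusion matrices, one-vs-rest metrics, ROC/AUC, bootstrap, projection."""

import numpy as np
import pytest

from mosqid.evalkit import (accuracy_statistic, bootstrap_ci,
                            confusion_from_counts, confusion_from_results,
                            per_class_metrics, project_embeddings_2d,
                            roc_auc, round_half_up)
from mosqid.retrieval import EmbeddingIndex, RetrievalResult
from mosqid.synth import stereo_test_counts

from _oracles import mann_whitney_auc


def _result(qid, predicted, scores=None, matched=True):
    return RetrievalResult(query_id=qid, neighbours=[],
                           class_scores=scores or {},
                           predicted=predicted, matched=matched)


class TestConfusion:
    def test_marginals_conserve_query_counts(self):
        classes = ["a", "b", "c"]
        results = [_result("q0", "a"), _result("q1", "b"),
                   _result("q2", "a"), _result("q3", None, matched=False)]
        truth = {"q0": "a", "q1": "a", "q2": "c", "q3": "b"}
        cm = confusion_from_results(results, truth, classes)
        assert cm.total == 3
        assert cm.rejected.sum() == 1
        assert cm.counts.sum(axis=1).tolist() == [2, 0, 1]

    def test_single_wrong_prediction_is_one_off_diagonal(self):
        results = [_result(f"q{i}", "a") for i in range(5)] \
            + [_result("q5", "b")]
        truth = {f"q{i}": "a" for i in range(6)}
        cm = confusion_from_results(results, truth, ["a", "b"])
        assert cm.counts[0, 1] == 1
        assert np.sum(cm.counts) - np.trace(cm.counts) == 1

    def test_unknown_truth_label_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            confusion_from_results([_result("q", "a")], {"q": "zz"}, ["a"])

    def test_hand_tally_fixture(self, rng):
        classes = ["a", "b", "c"]
        actual = rng.choice(classes, size=30)
        predicted = rng.choice(classes, size=30)
        results = [_result(f"q{i}", p) for i, p in enumerate(predicted)]
        truth = {f"q{i}": a for i, a in enumerate(actual)}
        cm = confusion_from_results(results, truth, classes)
        for i, ca in enumerate(classes):
            for j, cp in enumerate(classes):
                expect = sum(1 for a, p in zip(actual, predicted)
                             if a == ca and p == cp)
                assert cm.counts[i, j] == expect


class TestWorkedExamples:
    """The printed miner-comparison arithmetic, reproduced exactly."""

    def setup_method(self):
        self.counts = stereo_test_counts()
        self.classes = list(self.counts)
        self.diag = list(self.counts.values())

    def test_all_correct_gives_all_hundreds(self):
        rep = per_class_metrics(confusion_from_counts(self.diag, self.classes))
        for c in self.classes:
            for key in ("precision", "sensitivity", "specificity", "accuracy"):
                assert rep.per_class[c][key] == 100.0

    def test_single_error_per_class_cells(self):
        cm = confusion_from_counts(self.diag, self.classes,
                                   [("sCgel_f", "sCvis_f", 1)])
        rep = per_class_metrics(cm)
        assert round_half_up(rep.per_class["sCgel_f"]["sensitivity"]) == 97.06
        assert round_half_up(rep.per_class["sCvis_f"]["precision"]) == 95.83

    def test_single_error_averages(self):
        cm = confusion_from_counts(self.diag, self.classes,
                                   [("sCgel_f", "sCvis_f", 1)])
        rep = per_class_metrics(cm)
        assert round_half_up(rep.micro["sensitivity"]) == 99.66
        assert round_half_up(rep.micro["precision"]) == 99.66
        assert round_half_up(rep.macro["specificity"]) == 99.97
        assert round_half_up(rep.macro["accuracy"]) == 99.95

    def test_triple_error_averages(self):
        cm = confusion_from_counts(self.diag, self.classes,
                                   [("sAeg_m", "sAeg_f", 1),
                                    ("sAlb_f", "sAlb_m", 2)])
        rep = per_class_metrics(cm)
        assert round_half_up(rep.micro["sensitivity"]) == 98.99
        assert round_half_up(rep.macro["specificity"]) == 99.92
        assert round_half_up(rep.macro["accuracy"]) == 99.86
        assert round_half_up(rep.per_class["sAlb_m"]["precision"]) == 83.33


class TestMetricArithmetic:
    def test_two_class_toy_matrix_hand_arithmetic(self):
        # [[3,1],[2,4]]: for class 0: Tp=3, Fn=1, Fp=2, Tn=4
        cm = confusion_from_counts([4, 6], ["x", "y"], [("x", "y", 1),
                                                        ("y", "x", 2)])
        rep = per_class_metrics(cm)
        x = rep.per_class["x"]
        assert x["precision"] == pytest.approx(100 * 3 / 5)
        assert x["sensitivity"] == pytest.approx(100 * 3 / 4)
        assert x["specificity"] == pytest.approx(100 * 4 / 6)
        assert x["accuracy"] == pytest.approx(100 * 7 / 10)
        assert x["f1"] == pytest.approx(100 * 2 * 0.6 * 0.75 / 1.35)

    def test_micro_equals_macro_when_all_correct(self):
        rep = per_class_metrics(confusion_from_counts([5, 5], ["x", "y"]))
        assert rep.micro["sensitivity"] == rep.macro["sensitivity"] == 100.0

    def test_zero_denominator_reported_absent_not_zero(self):
        # class y never predicted and never actual-positive beyond its row
        cm = confusion_from_counts([3, 2], ["x", "y"],
                                   [("y", "x", 2)])
        rep = per_class_metrics(cm)
        assert rep.per_class["y"]["precision"] is None

    def test_half_up_rounding(self):
        assert round_half_up(99.955) == 99.96
        assert round_half_up(97.0588) == 97.06


class TestRoc:
    def _results(self, pos_scores, neg_scores):
        results, truth = [], {}
        for i, s in enumerate(pos_scores):
            results.append(_result(f"p{i}", "A", {"A": s, "B": 100 - s}))
            truth[f"p{i}"] = "A"
        for i, s in enumerate(neg_scores):
            results.append(_result(f"n{i}", "B", {"A": s, "B": 100 - s}))
            truth[f"n{i}"] = "B"
        return results, truth

    def test_separable_scores_give_auc_one(self):
        results, truth = self._results([100] * 10, [0] * 10)
        curve = roc_auc(results, truth, ["A", "B"])
        assert curve.auc == pytest.approx(1.0)

    def test_constant_scores_give_chance_auc(self):
        results, truth = self._results([50] * 10, [50] * 10)
        curve = roc_auc(results, truth, ["A", "B"])
        assert curve.auc == pytest.approx(0.5)

    def test_threshold_grid_has_21_points_and_endpoints(self):
        results, truth = self._results([80, 60], [40, 20])
        curve = roc_auc(results, truth, ["A", "B"])
        assert len(curve.thresholds) == 21
        pts = curve.per_class["A"]
        assert pts[0].tolist() == [1.0, 1.0]   # threshold 0: all positive

    def test_auc_matches_rank_statistic_oracle(self, rng):
        # vote scores live on the 5% grid, where the trapezoid over the
        # threshold sweep equals the tie-corrected Mann-Whitney statistic
        pos = rng.choice(np.arange(0, 105, 5), size=25)
        neg = rng.choice(np.arange(0, 105, 5), size=15)
        results, truth = self._results(pos, neg)
        curve = roc_auc(results, truth, ["A"])
        expect = mann_whitney_auc(pos, neg)
        assert curve.per_class_auc["A"] == pytest.approx(expect, abs=1e-12)

    def test_class_without_positives_skipped_with_warning(self):
        results, truth = self._results([90] * 4, [10] * 4)
        with pytest.warns(UserWarning, match="no positive"):
            curve = roc_auc(results, truth, ["A", "B", "C"])
        assert "C" not in curve.per_class


class TestBootstrap:
    def test_all_correct_gives_degenerate_interval(self):
        results = [_result(f"q{i}", "A") for i in range(20)]
        truth = {f"q{i}": "A" for i in range(20)}
        lo, hi = bootstrap_ci(results, truth, accuracy_statistic, seed=1)
        assert (lo, hi) == (100.0, 100.0)

    def test_same_seed_reproduces_interval(self):
        rng = np.random.default_rng(3)
        results = [_result(f"q{i}", "A" if rng.random() < 0.8 else "B")
                   for i in range(50)]
        truth = {f"q{i}": "A" for i in range(50)}
        a = bootstrap_ci(results, truth, accuracy_statistic, seed=9)
        b = bootstrap_ci(results, truth, accuracy_statistic, seed=9)
        assert a == b

    def test_too_few_queries_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([_result("q", "A")], {"q": "A"},
                         accuracy_statistic)


class TestProjection:
    def test_two_separated_clusters_stay_separated_in_2d(self, rng):
        a = rng.normal(loc=0.0, scale=0.02, size=(20, 8))
        b = rng.normal(loc=1.0, scale=0.02, size=(20, 8))
        emb = np.vstack([a, b])
        emb /= np.linalg.norm(emb, axis=1, keepdims=True)
        idx = EmbeddingIndex(embeddings=emb,
                             labels=np.repeat(["a", "b"], 20),
                             image_ids=np.array([f"i{k}" for k in range(40)]),
                             provenance=np.array(["trained"] * 40))
        coords = project_embeddings_2d(idx, seed=4)
        assert coords.shape == (40, 2)
        coords2 = project_embeddings_2d(idx, seed=4)
        np.testing.assert_allclose(coords, coords2)
        from sklearn.metrics import silhouette_score
        assert silhouette_score(coords, idx.labels) > 0.5
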