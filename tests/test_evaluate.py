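"""Validation metrics: confusion, per-class counts, the five metrics,
macro summaries and ROC/AUC against a pairwise-concordance oracle."""

import numpy as np
import pytest

from histospect.evaluate import (ClassCounts, class_counts, confusion_matrix,
                                 evaluate_predictions, macro_summary,
                                 metrics_from_counts, roc_auc_ovr, roc_points)


def auc_pairwise(y, score, k):
    """O(n^2) concordance count; ties score one half."""
    pos = np.flatnonzero(y == k)
    neg = np.flatnonzero(y != k)
    total = 0.0
    for i in pos:
        for j in neg:
            if score[i] > score[j]:
                total += 1.0
            elif score[i] == score[j]:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_direct_count_example(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], ["a", "b"])
        assert cm.counts.tolist() == [[1, 1], [0, 2]]
        assert cm.overall_accuracy() == pytest.approx(0.75)

    def test_perfect_predictions_are_diagonal(self):
        y = [0, 1, 2, 0, 1, 2]
        cm = confusion_matrix(y, y, ["a", "b", "c"])
        assert np.array_equal(cm.counts, np.diag([2, 2, 2]))

    def test_empty_and_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([], [], ["a"])
        with pytest.raises(ValueError):
            confusion_matrix([0, 2], [0, 0], ["a", "b"])


class TestClassCounts:
    def test_one_vs_rest_readoff(self):
        cm = confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], ["a", "b"])
        c0 = class_counts(cm, 0)
        assert (c0.TP, c0.FN, c0.FP, c0.TN) == (1, 1, 0, 2)
        c1 = class_counts(cm, 1)
        assert (c1.TP, c1.FN, c1.FP, c1.TN) == (2, 0, 1, 1)
        assert c0.TP + c0.TN + c0.FP + c0.FN == cm.n

    def test_diagonal_matrix_has_no_errors(self):
        cm = confusion_matrix([0, 1, 2], [0, 1, 2], list("abc"))
        for k in range(3):
            c = class_counts(cm, k)
            assert c.FP == 0 and c.FN == 0

    def test_index_out_of_range(self):
        cm = confusion_matrix([0, 1], [0, 1], ["a", "b"])
        with pytest.raises(IndexError):
            class_counts(cm, 2)


class TestMetrics:
    def test_hand_substituted_example(self):
        m = metrics_from_counts(ClassCounts(TP=9, TN=8, FP=2, FN=1))
        assert m.accuracy == pytest.approx(0.85)
        assert m.sensitivity == pytest.approx(0.9)
        assert m.specificity == pytest.approx(0.8)
        assert m.precision == pytest.approx(9 / 11)
        assert m.f1 == pytest.approx(18 / 21)

    def test_perfect_classifier_scores_all_ones(self):
        m = metrics_from_counts(ClassCounts(TP=5, TN=7, FP=0, FN=0))
        assert (m.accuracy, m.sensitivity, m.specificity, m.precision, m.f1) \
            == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_degenerate_zero_over_zero_convention(self):
        with pytest.warns(RuntimeWarning):
            m = metrics_from_counts(ClassCounts(TP=0, TN=3, FP=0, FN=2))
        assert m.precision == 0.0
        assert m.sensitivity == 0.0

    def test_f1_equals_harmonic_mean_identity(self, rng):
        checked = 0
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 20, size=4)
            if tp + tn + fp + fn == 0:
                continue
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = metrics_from_counts(
                    ClassCounts(TP=int(tp), TN=int(tn), FP=int(fp), FN=int(fn)))
            if tp + fp > 0 and tp + fn > 0 and m.precision + m.sensitivity > 0:
                h = 2 * m.precision * m.sensitivity / (m.precision + m.sensitivity)
                assert m.f1 == pytest.approx(h, abs=1e-12)
                checked += 1
        assert checked > 500

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_counts(ClassCounts(0, 0, 0, 0))


class TestMacro:
    def test_mean_and_population_sd(self):
        a = metrics_from_counts(ClassCounts(TP=4, TN=5, FP=0, FN=1))  # sens .8
        b = metrics_from_counts(ClassCounts(TP=5, TN=5, FP=0, FN=0))  # sens 1.
        out = macro_summary([a, b])
        assert out["sensitivity"]["mean"] == pytest.approx(0.9)
        assert out["sensitivity"]["sd"] == pytest.approx(0.1)

    def test_identical_classes_have_zero_sd(self):
        m = metrics_from_counts(ClassCounts(TP=3, TN=3, FP=1, FN=1))
        out = macro_summary([m, m, m])
        assert all(v["sd"] == 0.0 for v in out.values())

    def test_single_class(self):
        m = metrics_from_counts(ClassCounts(TP=3, TN=3, FP=1, FN=1))
        out = macro_summary([m])
        assert out["f1"]["mean"] == pytest.approx(m.f1)
        assert out["f1"]["sd"] == 0.0


class TestAuc:
    def test_perfect_ranking_gives_one(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        assert roc_auc_ovr(y, scores) == [1.0, 1.0]

    def test_constant_scores_give_half(self):
        y = np.array([0, 1, 0, 1])
        scores = np.full((4, 2), 0.5)
        assert roc_auc_ovr(y, scores) == [0.5, 0.5]

    def test_matches_pairwise_oracle_exactly(self, rng):
        n = 200
        y = rng.integers(0, 3, n)
        y[:3] = [0, 1, 2]
        scores = np.round(rng.random((n, 3)), 2)  # coarse grid forces ties
        got = roc_auc_ovr(y, scores)
        for k in range(3):
            assert got[k] == pytest.approx(auc_pairwise(y, scores[:, k], k),
                                           abs=1e-12)
            assert 0.3 <= got[k] <= 0.7

    def test_absent_class_reported_missing(self):
        y = np.array([0, 0, 1, 1])
        scores = np.random.default_rng(0).random((4, 3))
        assert roc_auc_ovr(y, scores)[2] is None

    def test_roc_points_start_at_origin_and_end_at_unity(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        pts = roc_points(y, rng.random(50), positive_class=1)
        assert np.allclose(pts[0], [0, 0])
        assert np.allclose(pts[-1], [1, 1])
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()


class TestReport:
    def test_full_report_consistency(self, rng):
        y = rng.integers(0, 3, 60)
        y[:3] = [0, 1, 2]
        pred = y.copy()
        flip = rng.integers(0, 60, 10)
        pred[flip] = (pred[flip] + 1) % 3
        scores = np.eye(3)[pred] + rng.normal(0, 0.01, (60, 3))
        rep = evaluate_predictions(y, pred, list("abc"), scores)
        tp_sum = sum(c.TP for c in rep.per_class_counts)
        assert tp_sum == np.trace(rep.confusion.counts)
        assert rep.overall_accuracy == pytest.approx((y == pred).mean())
        for m in rep.per_class_metrics:
            for v in (m.accuracy, m.sensitivity, m.specificity, m.precision, m.f1):
                assert 0.0 <= v <= 1.0
        # one-vs-rest per-class accuracy differs from overall accuracy in general
        assert rep.per_class_metrics[0].accuracy >= rep.overall_accuracy
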