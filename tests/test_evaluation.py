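"""Label rules (score -> status, ISH reading) and metric definitions."""

import numpy as np
import pytest
from sklearn.metrics import (
    balanced_accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)

from her2mil.evaluation import (
    SpotLabel,
    UnresolvedLabelError,
    balanced_accuracy,
    compute_report,
    confusion,
    ish_call,
    roc_one_vs_all,
    score_to_status,
    weighted_metrics,
)


class TestIshCall:
    @pytest.mark.parametrize("her2,cen17,expected", [
        (4.0, 2.0, 1),   # ratio exactly 2.0 -> positive
        (6.0, 5.0, 1),   # ratio 1.2 but signals reach 6.0 -> positive
        (3.0, 2.0, 0),   # fails both clauses -> negative
        (5.9, 3.0, 0),   # ratio 1.97, signals below 6
        (12.0, 2.0, 1),
    ])
    def test_reading_rule(self, her2, cen17, expected):
        assert ish_call(her2, cen17) == expected

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            ish_call(4.0, 0.0)
        with pytest.raises(ValueError):
            ish_call(0.0, 2.0)


class TestScoreToStatus:
    @pytest.mark.parametrize("score,expected", [(0, 0), (1, 0), (3, 1)])
    def test_determinate_scores(self, score, expected):
        assert score_to_status(score) == expected

    def test_score2_resolved_by_ish_counts(self):
        assert score_to_status(2, her2_signals=9.0, cen17_signals=3.0) == 1
        assert score_to_status(2, her2_signals=3.0, cen17_signals=2.5) == 0

    def test_score2_without_ish_unresolved(self):
        with pytest.raises(UnresolvedLabelError):
            score_to_status(2)

    def test_invalid_score(self):
        with pytest.raises(ValueError):
            score_to_status(4)

    def test_spotlabel_contradiction_detected(self):
        with pytest.raises(ValueError, match="contradicts"):
            SpotLabel("x", 3, her2_status=0)

    def test_spotlabel_score2_derives_from_counts(self):
        lab = SpotLabel("x", 2, her2_signals=8.0, cen17_signals=2.0)
        assert lab.her2_status == 1


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        y = [0, 0, 1, 1, 1]
        mat = confusion(y, y, [0, 1])
        np.testing.assert_array_equal(mat, [[2, 0], [0, 3]])

    def test_all_wrong_zero_diagonal(self):
        mat = confusion([0, 0, 1], [1, 1, 0], [0, 1])
        assert np.trace(mat) == 0 and mat.sum() == 3

    def test_orientation_is_predicted_by_true(self):
        # one spot with true 0 predicted 1 -> row 1 (predicted), column 0
        mat = confusion([0], [1], [0, 1])
        assert mat[1, 0] == 1

    def test_matches_transposed_sklearn_on_random_vectors(self, rng):
        y_true = rng.integers(0, 4, 50)
        y_pred = rng.integers(0, 4, 50)
        ours = confusion(y_true, y_pred, [0, 1, 2, 3])
        theirs = confusion_matrix(y_true, y_pred, labels=[0, 1, 2, 3])
        np.testing.assert_array_equal(ours, theirs.T)

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 5], [0, 0], [0, 1])


class TestScalarMetrics:
    def test_balanced_accuracy_hand_example(self):
        assert balanced_accuracy(np.array([[8, 5], [2, 5]])) == pytest.approx(0.65)

    def test_perfect_matrix(self):
        assert balanced_accuracy(np.diag([4, 9])) == 1.0
        assert weighted_metrics(np.diag([4, 9])) == pytest.approx((1.0, 1.0, 1.0))

    def test_empty_true_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.array([[2, 0], [1, 0]]))

    def test_weighted_recall_equals_overall_accuracy(self, rng):
        for _ in range(20):
            conf = rng.integers(0, 10, (3, 3)) + np.eye(3, dtype=int)
            _, recall, _ = weighted_metrics(conf)
            assert recall == pytest.approx(np.trace(conf) / conf.sum())

    def test_matches_sklearn_weighted_oracle(self, rng):
        """Expand random confusion matrices into label vectors and compare
        against scikit-learn's per-sample weighted metrics."""
        for trial in range(20):
            conf = rng.integers(0, 8, (3, 3)) + np.eye(3, dtype=int)
            y_true, y_pred = [], []
            for i in range(3):          # predicted
                for j in range(3):      # true
                    y_true += [j] * conf[i, j]
                    y_pred += [i] * conf[i, j]
            prec, rec, f1, _ = precision_recall_fscore_support(
                y_true, y_pred, average="weighted", zero_division=0)
            ba = balanced_accuracy_score(y_true, y_pred)
            got = weighted_metrics(conf)
            assert got == pytest.approx((prec, rec, f1), abs=1e-12)
            assert balanced_accuracy(conf) == pytest.approx(ba, abs=1e-12)

    def test_invariant_to_class_permutation(self, rng):
        conf = rng.integers(1, 9, (4, 4))
        perm = rng.permutation(4)
        permuted = conf[np.ix_(perm, perm)]
        assert balanced_accuracy(conf) == pytest.approx(
            balanced_accuracy(permuted))
        assert weighted_metrics(conf) == pytest.approx(
            weighted_metrics(permuted))


class TestRoc:
    def test_perfect_separation_auc_one(self):
        probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        out = roc_one_vs_all(probs, [0, 0, 1, 1])
        assert out[0]["auc"] == 1.0 and out[1]["auc"] == 1.0

    def test_inverted_scores_auc_zero(self):
        probs = np.array([[0.1, 0.9], [0.2, 0.8], [0.9, 0.1], [0.8, 0.2]])
        out = roc_one_vs_all(probs, [0, 0, 1, 1])
        assert out[0]["auc"] == 0.0

    def test_label_independent_scores_near_half(self, rng):
        n = 2000
        p1 = rng.uniform(0, 1, n)
        probs = np.column_stack([p1, 1 - p1])
        y = rng.integers(0, 2, n)
        out = roc_one_vs_all(probs, y)
        assert abs(out[0]["auc"] - 0.5) < 0.05

    def test_matches_sklearn_auc_with_ties(self, rng):
        for _ in range(10):
            n = 60
            raw = rng.integers(0, 5, (n, 3)).astype(float) + 0.5
            probs = raw / raw.sum(axis=1, keepdims=True)
            y = rng.integers(0, 3, n)
            out = roc_one_vs_all(probs, y, classes=[0, 1, 2])
            for c in range(3):
                oracle = roc_auc_score((y == c).astype(int), probs[:, c])
                assert out[c]["auc"] == pytest.approx(oracle, abs=1e-12)

    def test_absent_class_reported_missing(self):
        probs = np.array([[0.6, 0.3, 0.1], [0.2, 0.7, 0.1]])
        out = roc_one_vs_all(probs, [0, 1], classes=[0, 1, 2])
        assert out[2]["auc"] is None

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            roc_one_vs_all(np.array([[0.5, 0.2]]), [0])


def test_compute_report_bundles_everything(rng):
    y_true = rng.integers(0, 2, 40)
    y_pred = rng.integers(0, 2, 40)
    p1 = rng.uniform(0, 1, 40)
    report = compute_report(y_true, y_pred, classes=[0, 1],
                            probabilities=np.column_stack([1 - p1, p1]))
    assert report.confusion.sum() == 40
    assert 0 <= report.balanced_accuracy <= 1
    assert set(report.per_class_auc) == {0, 1}
    d = report.to_dict()
    assert d["confusion_predicted_x_true"] == report.confusion.tolist()
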