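"""Confusion bookkeeping and the five metrics, including the hand-derived
binary table and an independent reference cross-check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegfuse.metrics import ConfusionTable, compute_metrics, confusion, mcc


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self, rng):
        y = rng.integers(0, 3, size=50)
        t = confusion(y, y, 3)
        assert np.array_equal(t.matrix, np.diag(np.bincount(y, minlength=3)))
        assert (t.fp == 0).all() and (t.fn == 0).all()

    def test_hand_counted_binary_example(self):
        t = confusion([0, 0, 1, 1], [0, 1, 1, 1], 2)
        # class-0 one-vs-rest counts
        assert t.tp[0] == 1 and t.fn[0] == 1 and t.fp[0] == 0 and t.tn[0] == 2

    def test_single_sample(self):
        t = confusion([2], [1], 3)
        assert t.total == 1 and t.matrix.sum() == 1 and t.matrix[2, 1] == 1

    def test_counts_partition_total(self, rng):
        y_true = rng.integers(0, 4, size=200)
        y_pred = rng.integers(0, 4, size=200)
        t = confusion(y_true, y_pred, 4)
        np.testing.assert_array_equal(t.tp + t.fp + t.tn + t.fn, t.total)

    def test_length_mismatch_and_range_errors(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0], 2)
        with pytest.raises(ValueError):
            confusion([0, 2], [0, 1], 2)


class TestComputeMetrics:
    def test_perfect_three_class(self):
        t = confusion([0, 1, 2, 0, 1, 2], [0, 1, 2, 0, 1, 2], 3)
        r = compute_metrics(t)
        assert r.accuracy == r.precision == r.recall == r.f1 == 1.0
        assert mcc(t) == pytest.approx(1.0)

    def test_hand_derived_binary_table(self):
        """TP=50, TN=40, FP=5, FN=5: accuracy 0.90, positive-class
        precision = recall = F1 = 50/55, MCC = 1975/2475."""
        t = ConfusionTable.from_binary_counts(tp=50, tn=40, fp=5, fn=5)
        r = compute_metrics(t)
        assert r.accuracy == pytest.approx(0.90)
        pos = r.per_class[1]
        assert pos["precision"] == pytest.approx(50 / 55)
        assert pos["recall"] == pytest.approx(50 / 55)
        assert pos["f1"] == pytest.approx(50 / 55)
        assert r.mcc == pytest.approx(1975 / 2475, abs=1e-9)
        assert r.mcc == pytest.approx(0.79798, abs=1e-5)

    def test_degenerate_all_one_class_prediction(self):
        y_true = np.array([0] * 50 + [1] * 50)
        y_pred = np.zeros(100, dtype=int)
        r = compute_metrics(confusion(y_true, y_pred, 2))
        assert r.per_class[0]["recall"] == 1.0
        assert r.per_class[1]["recall"] == 0.0
        assert r.accuracy == 0.5
        assert mcc(confusion(y_true, y_pred, 2)) == 0.0  # zero-denominator rule

    def test_f1_between_precision_and_recall_per_class(self, rng):
        t = confusion(rng.integers(0, 3, 300), rng.integers(0, 3, 300), 3)
        r = compute_metrics(t)
        for stats in r.per_class.values():
            lo = min(stats["precision"], stats["recall"])
            hi = max(stats["precision"], stats["recall"])
            assert lo - 1e-12 <= stats["f1"] <= hi + 1e-12

    def test_weighted_equals_macro_on_balanced_data(self, rng):
        y_true = np.repeat(np.arange(3), 40)
        y_pred = rng.integers(0, 3, size=120)
        t = confusion(y_true, y_pred, 3)
        w = compute_metrics(t, "weighted")
        m = compute_metrics(t, "macro")
        for f in ("precision", "recall", "f1"):
            assert getattr(w, f) == pytest.approx(getattr(m, f), abs=1e-12)


class TestMCC:
    def test_multiclass_reduces_to_binary_formula(self, rng):
        """The K-class generalization evaluated on random 2x2 tables must
        equal the textbook binary formula."""
        for _ in range(50):
            m = rng.integers(0, 30, size=(2, 2))
            tn, fp, fn, tp = m.ravel()
            den = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
            expected = (tp * tn - fp * fn) / den if den > 0 else 0.0
            # route through the general K-class path by padding an empty class
            m3 = np.zeros((3, 3), dtype=int)
            m3[:2, :2] = m
            assert mcc(ConfusionTable(m3)) == pytest.approx(expected, abs=1e-9)
            assert mcc(ConfusionTable(m)) == pytest.approx(expected, abs=1e-12)

    def test_uninformative_prediction_is_zero(self):
        assert mcc(ConfusionTable([[25, 25], [25, 25]])) == 0.0


def test_agreement_with_reference_implementation(rng):
    """100 random label vectors against scikit-learn to 1e-9."""
    from sklearn.metrics import (
        accuracy_score,
        f1_score,
        matthews_corrcoef,
        precision_score,
        recall_score,
    )

    for _ in range(100):
        k = int(rng.integers(2, 5))
        n = int(rng.integers(5, 60))
        y_true = rng.integers(0, k, size=n)
        y_pred = rng.integers(0, k, size=n)
        t = confusion(y_true, y_pred, k)
        r = compute_metrics(t, "weighted")
        assert r.accuracy == pytest.approx(accuracy_score(y_true, y_pred), abs=1e-9)
        kw = dict(average="weighted", labels=np.arange(k), zero_division=0)
        assert r.precision == pytest.approx(precision_score(y_true, y_pred, **kw), abs=1e-9)
        assert r.recall == pytest.approx(recall_score(y_true, y_pred, **kw), abs=1e-9)
        assert r.f1 == pytest.approx(f1_score(y_true, y_pred, **kw), abs=1e-9)
        assert mcc(t) == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    labels=st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                    min_size=2, max_size=40),
    perm_seed=st.integers(0, 1000),
)
def test_metrics_invariant_under_class_relabeling(labels, perm_seed):
    """Applying one permutation to both truth and prediction leaves the
    weighted metrics and the MCC unchanged."""
    y_true, y_pred = (np.array(v) for v in zip(*labels))
    perm = np.random.default_rng(perm_seed).permutation(3)
    t1 = confusion(y_true, y_pred, 3)
    t2 = confusion(perm[y_true], perm[y_pred], 3)
    r1, r2 = compute_metrics(t1), compute_metrics(t2)
    for f in ("accuracy", "precision", "recall", "f1", "mcc"):
        assert getattr(r1, f) == pytest.approx(getattr(r2, f), abs=1e-12)


def test_csv_row_percent_columns():
    t = ConfusionTable.from_binary_counts(tp=50, tn=40, fp=5, fn=5)
    row = compute_metrics(t).csv_row()
    assert list(row) == ["Accuracy", "Precision", "Recall", "F1-Score", "MCC"]
    assert row["Accuracy"] == 90.0
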