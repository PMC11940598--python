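"""Classification metrics from an explicit confusion table.

Accuracy, precision, recall, F1 and the Matthews correlation
coefficient, defined binary-style per class (one-vs-rest TP/FP/TN/FN)
and aggregated over classes.  Multiclass aggregation is support-weighted
by default (on balanced data it coincides with the macro mean); the MCC
uses the K-class generalization computed from the full confusion matrix,
which reduces exactly to the familiar binary formula at K = 2.  Any
zero denominator contributes 0 to the metric concerned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ConfusionTable", "EvaluationReport", "confusion", "compute_metrics", "mcc"]

#: Column order used for CSV rows (values as percentages).
CSV_COLUMNS = ["Accuracy", "Precision", "Recall", "F1-Score", "MCC"]


@dataclass
class ConfusionTable:
    """K x K confusion matrix plus one-vs-rest per-class counts.

    ``matrix[i, j]`` counts samples of true class ``i`` predicted as
    ``j``; per-class TP/FP/TN/FN follow by treating each class in turn
    as the positive one.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError(f"matrix must be square, got shape {self.matrix.shape}")
        if (self.matrix < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def fn(self) -> np.ndarray:
        return self.matrix.sum(axis=1) - self.tp

    @property
    def fp(self) -> np.ndarray:
        return self.matrix.sum(axis=0) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.total - self.tp - self.fp - self.fn

    @property
    def support(self) -> np.ndarray:
        """True-class sample counts (row sums)."""
        return self.matrix.sum(axis=1)

    @classmethod
    def from_binary_counts(cls, tp: int, tn: int, fp: int, fn: int) -> "ConfusionTable":
        """Binary table with class 1 as the positive class."""
        return cls(np.array([[tn, fp], [fn, tp]]))


def confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> ConfusionTable:
    """Count the K x K confusion matrix of two label vectors."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 1:
        raise ValueError(
            f"y_true and y_pred must be equal-length non-empty vectors, got "
            f"{y_true.shape} and {y_pred.shape}"
        )
    for name, v in (("y_true", y_true), ("y_pred", y_pred)):
        if v.min() < 0 or v.max() >= n_classes:
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    matrix = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(matrix, (y_true, y_pred), 1)
    return ConfusionTable(matrix)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Element-wise num/den with 0 wherever den == 0."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den != 0)
    return out


def mcc(table: ConfusionTable) -> float:
    """Matthews correlation coefficient in [-1, 1].

    At K = 2 this is the textbook binary formula
    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))`` with class 1
    positive; for K > 2 the generalization from the full confusion
    matrix (sum of covariances between prediction and truth indicator
    vectors) is used, which agrees with the binary formula at K = 2.
    A zero denominator yields 0.
    """
    m = table.matrix.astype(float)
    if table.n_classes == 2:
        tn, fp, fn, tp = m[0, 0], m[0, 1], m[1, 0], m[1, 1]
        den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        return float((tp * tn - fp * fn) / den) if den > 0 else 0.0
    total = m.sum()
    correct = np.trace(m)
    pred_marg = m.sum(axis=0)
    true_marg = m.sum(axis=1)
    cov_yp = correct * total - true_marg @ pred_marg
    cov_pp = total**2 - pred_marg @ pred_marg
    cov_yy = total**2 - true_marg @ true_marg
    den = np.sqrt(cov_pp) * np.sqrt(cov_yy)
    return float(cov_yp / den) if den > 0 else 0.0


@dataclass
class EvaluationReport:
    """The five-metric record of one evaluation run."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    averaging: str = "weighted"
    per_class: dict = field(default_factory=dict)
    n_samples: int = 0

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
            "averaging": self.averaging,
            "per_class": self.per_class,
            "n_samples": self.n_samples,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    def csv_row(self) -> dict:
        """Metrics as percentages in the conventional column order."""
        vals = [self.accuracy, self.precision, self.recall, self.f1, self.mcc]
        return {c: round(100.0 * v, 2) for c, v in zip(CSV_COLUMNS, vals)}


def compute_metrics(table: ConfusionTable, averaging: str = "weighted") -> EvaluationReport:
    """Five-metric report from a confusion table.

    Per-class precision/recall/F1 use the one-vs-rest counts; aggregate
    precision/recall/F1 are the support-weighted ('weighted') or plain
    ('macro') means.  Overall accuracy is trace/total.
    """
    if averaging not in ("weighted", "macro"):
        raise ValueError(f"averaging must be 'weighted' or 'macro', got {averaging!r}")
    tp, fp, fn = table.tp, table.fp, table.fn
    precision_c = _safe_div(tp, tp + fp)
    recall_c = _safe_div(tp, tp + fn)
    f1_c = _safe_div(2 * precision_c * recall_c, precision_c + recall_c)
    support = table.support
    if averaging == "weighted":
        w = _safe_div(support, np.full_like(support, table.total))
    else:
        w = np.full(table.n_classes, 1.0 / table.n_classes)
    per_class = {
        int(k): {
            "precision": float(precision_c[k]),
            "recall": float(recall_c[k]),
            "f1": float(f1_c[k]),
            "support": int(support[k]),
        }
        for k in range(table.n_classes)
    }
    return EvaluationReport(
        accuracy=float(_safe_div(np.trace(table.matrix), table.total)),
        precision=float(precision_c @ w),
        recall=float(recall_c @ w),
        f1=float(f1_c @ w),
        mcc=mcc(table),
        averaging=averaging,
        per_class=per_class,
        n_samples=table.total,
    )
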