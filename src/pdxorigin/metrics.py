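"""Multi-class performance measures.

The central statistic is the covariance form of the multi-class Matthews
correlation coefficient (Gorodkin's R_K): with ``X`` the n x C one-hot
predicted-class indicator matrix and ``Y`` the one-hot truth matrix,

    MCC = cov(X, Y) / sqrt(cov(X, X) * cov(Y, Y)),

where cov(A, B) = sum_ij (a_ij - abar_j)(b_ij - bbar_j) with column means
abar_j.  For C = 2 it reduces to the classical binary Matthews coefficient;
it stays a balanced measure under strong class-size imbalance, which is why
it is preferred over overall accuracy for the 8-tissue cohort (largest class
roughly 3x the smallest).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "multiclass_mcc",
    "mcc_from_confusion",
    "accuracy_metrics",
    "weighted_accuracy",
    "confusion_from_predictions",
    "indicator_matrices",
    "PerformanceReport",
]


def _validate_indicators(A: np.ndarray, name: str) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {A.shape}")
    if not np.all((A == 0) | (A == 1)):
        raise ValueError(f"{name} must be a 0/1 indicator matrix")
    if not np.all(A.sum(axis=1) == 1):
        raise ValueError(f"every row of {name} must contain exactly one 1")
    return A


def multiclass_mcc(X: np.ndarray, Y: np.ndarray) -> float:
    """Multi-class Matthews correlation from one-hot indicator matrices.

    Parameters
    ----------
    X : (n, C) array
        Predicted-class indicators, one 1 per row.
    Y : (n, C) array
        True-class indicators, one 1 per row.

    Returns
    -------
    float in [-1, 1].  By convention 0.0 when either covariance term is
    zero (e.g. a constant prediction), where the ratio is undefined.
    """
    X = _validate_indicators(X, "X")
    Y = _validate_indicators(Y, "Y")
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs Y {Y.shape}")
    Xc = X - X.mean(axis=0, keepdims=True)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    cov_xy = float(np.sum(Xc * Yc))
    cov_xx = float(np.sum(Xc * Xc))
    cov_yy = float(np.sum(Yc * Yc))
    if cov_xx == 0.0 or cov_yy == 0.0:
        return 0.0
    return cov_xy / np.sqrt(cov_xx * cov_yy)


def indicator_matrices(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> tuple[np.ndarray, np.ndarray]:
    """One-hot (X_pred, Y_true) indicator matrices from integer class indices."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    n = y_true.shape[0]
    X = np.zeros((n, n_classes))
    Y = np.zeros((n, n_classes))
    X[np.arange(n), y_pred] = 1.0
    Y[np.arange(n), y_true] = 1.0
    return X, Y


def mcc_from_confusion(confusion: np.ndarray) -> float:
    """Multi-class MCC of a pooled confusion matrix (rows true, cols predicted).

    Expands the counts back into indicator rows and applies the covariance
    formula, so confusion-based and per-sample results agree exactly.
    """
    conf = np.asarray(confusion, dtype=int)
    C = conf.shape[0]
    true_idx, pred_idx = [], []
    for i in range(C):
        for j in range(C):
            true_idx.extend([i] * conf[i, j])
            pred_idx.extend([j] * conf[i, j])
    if not true_idx:
        raise ValueError("empty confusion matrix")
    X, Y = indicator_matrices(np.array(true_idx), np.array(pred_idx), C)
    return multiclass_mcc(X, Y)


def accuracy_metrics(confusion: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-class and overall accuracy from a confusion matrix.

    ACC_i = M_i / N_i with M_i the correctly predicted count (diagonal) and
    N_i the class size (row sum); overall ACC = sum_i M_i / sum_i N_i.
    """
    conf = np.asarray(confusion, dtype=float)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    row_sums = conf.sum(axis=1)
    if np.any(row_sums < 1):
        empty = np.nonzero(row_sums < 1)[0].tolist()
        raise ValueError(f"empty class rows in confusion matrix: {empty}")
    per_class = np.diag(conf) / row_sums
    overall = float(np.trace(conf) / conf.sum())
    return per_class, overall


def weighted_accuracy(confusion: np.ndarray) -> float:
    """Class-balanced accuracy: unweighted mean of per-class recalls.

    Rows with zero samples (classes absent from a held-out split) are
    excluded from the average.  Raises on an all-zero matrix.
    """
    conf = np.asarray(confusion, dtype=float)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    row_sums = conf.sum(axis=1)
    present = row_sums > 0
    if not np.any(present):
        raise ValueError("weighted accuracy undefined for an all-zero confusion matrix")
    recalls = np.diag(conf)[present] / row_sums[present]
    return float(recalls.mean())


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> np.ndarray:
    """C x C count matrix, rows true classes, columns predicted classes."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    conf = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(conf, (y_true, y_pred), 1)
    return conf


@dataclass
class PerformanceReport:
    """Confusion matrix with the derived multi-class metrics."""

    classes: list[str]
    confusion: np.ndarray
    per_class_accuracy: np.ndarray = field(init=False)
    overall_accuracy: float = field(init=False)
    mcc: float = field(init=False)

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        if self.confusion.shape != (len(self.classes), len(self.classes)):
            raise ValueError("confusion shape does not match class count")
        self.per_class_accuracy, self.overall_accuracy = accuracy_metrics(
            self.confusion
        )
        self.mcc = mcc_from_confusion(self.confusion)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "per_class_accuracy": [float(a) for a in self.per_class_accuracy],
            "overall_accuracy": float(self.overall_accuracy),
            "mcc": float(self.mcc),
        }
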