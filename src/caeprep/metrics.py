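"""Evaluation metrics: accuracy, geometric mean of recalls, ROC AUC.

Accuracy and the geometric mean are reported on a 0-100 scale; AUC on
[0, 1].  GM and AUC summarise the full confusion structure and are the
metrics of choice for imbalanced classes: GM collapses to 0 as soon as one
class is never recovered, and AUC is the probability that a random positive
outranks a random negative (Mann-Whitney form, half credit for ties),
macro-averaged one-vs-rest for more than two classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .exceptions import ShapeError


@dataclass
class ConfusionMatrix:
    """N x N counts; rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = self.counts.shape[0]
        if self.counts.ndim != 2 or self.counts.shape != (n, n):
            raise ShapeError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ShapeError("confusion matrix counts must be nonnegative")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray,
                         n_classes: int | None = None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=np.int64)
        y_pred = np.asarray(y_pred, dtype=np.int64)
        if y_true.shape != y_pred.shape:
            raise ShapeError("y_true and y_pred must have equal length")
        n = n_classes or int(max(y_true.max(), y_pred.max())) + 1
        counts = np.zeros((n, n), dtype=np.int64)
        np.add.at(counts, (y_true, y_pred), 1)
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def recalls(self) -> np.ndarray:
        row_sums = self.counts.sum(axis=1)
        if (row_sums == 0).any():
            empty = int(np.flatnonzero(row_sums == 0)[0])
            raise ValueError(f"class {empty} has no true samples; recall undefined")
        return np.diag(self.counts) / row_sums


def accuracy(cm: ConfusionMatrix) -> float:
    """Percentage of correct predictions: 100 * trace / M."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def geometric_mean(cm: ConfusionMatrix) -> float:
    """100 * (prod of per-class recalls)^(1/N); 0 if any class is missed."""
    recalls = cm.recalls
    if (recalls == 0).any():
        return 0.0
    return 100.0 * float(np.exp(np.mean(np.log(recalls))))


def _binary_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    rank_sum = float(ranks[positive].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC from per-class scores.

    Parameters
    ----------
    scores
        ``(M, N)`` matrix of class scores (e.g. predicted probabilities).
    labels
        ``(M,)`` integer labels in ``[0, N)``; every class must occur.

    Binary problems return the AUC of class 1's score; multiclass returns
    the unweighted (macro) mean of the one-vs-rest AUCs.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.ndim != 2 or scores.shape[0] != labels.shape[0]:
        raise ShapeError("scores must be (M, N) aligned with labels")
    n = scores.shape[1]
    present = np.bincount(labels, minlength=n)
    if (present == 0).any():
        missing = int(np.flatnonzero(present == 0)[0])
        raise ValueError(f"class {missing} absent from labels; AUC undefined")
    if n == 2:
        return _binary_auc(scores[:, 1], labels == 1)
    return float(np.mean([_binary_auc(scores[:, c], labels == c)
                          for c in range(n)]))


def evaluate_predictions(probabilities: np.ndarray,
                         labels: np.ndarray) -> dict:
    """All three metrics plus the confusion matrix, as a JSON-friendly dict."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    predicted = probabilities.argmax(axis=1)
    cm = ConfusionMatrix.from_predictions(
        labels, predicted, n_classes=probabilities.shape[1]
    )
    return {
        "accuracy": accuracy(cm),
        "gm": geometric_mean(cm),
        "auc": auc(probabilities, labels),
        "confusion_matrix": cm.counts.tolist(),
    }
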