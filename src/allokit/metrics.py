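"""Classification validation metrics for mode-of-action models.

Implements the validation panel used throughout the package: class recall
and precision read off a confusion matrix (sensitivity, specificity, PPV,
NPV), the binary Matthews correlation coefficient, and its three-class
extension in which the numerator is the product of correctly predicted
counts minus the product of per-class miss totals and the denominator is
the cube root of the product of all pairwise sums of correct counts and
miss totals.  The three-class recall/precision values can be rescaled
affinely so that the 1/3 random baseline maps onto the 0.5 baseline of a
binary model, making the two model families directly comparable.

Conventions: class A = allosteric small molecules, class B = non-allosteric
molecules, class C = allosteric biologicals (three-class models only).
Rows of the confusion matrix are the measured classes, columns the
predicted classes.  Any metric whose denominator is zero is reported as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "ValidationMetrics",
    "binary_metrics",
    "ternary_metrics",
    "gorodkin_mcc",
    "scale_ternary",
    "roc_curve",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count table; rows = measured class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError(f"confusion matrix must be square, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("confusion matrix counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("confusion matrix counts must be integers")
        object.__setattr__(self, "counts", arr.astype(np.int64))
        if not self.labels:
            object.__setattr__(self, "labels", tuple("ABC"[: arr.shape[0]]))

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels=None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if labels is None:
            labels = sorted(set(y_true) | set(y_pred))
        idx = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[idx[t], idx[p]] += 1
        return cls(counts, tuple(labels))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def miss_totals(self) -> np.ndarray:
        """Per-class missed predictions: AX = AB+AC, BX = BA+BC, CX = CA+CB."""
        return self.counts.sum(axis=1) - np.diag(self.counts)


@dataclass
class ValidationMetrics:
    sensitivity: float = 0.0
    specificity: float = 0.0
    ppv: float = 0.0
    npv: float = 0.0
    mcc: float = 0.0
    recall_c: float | None = None
    precision_c: float | None = None
    scaled: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "mcc": self.mcc,
        }
        if self.recall_c is not None:
            out["recall_c"] = self.recall_c
            out["precision_c"] = self.precision_c
            out.update({f"scaled_{k}": v for k, v in self.scaled.items()})
        return out


def _safe_div(num: float, den: float) -> float:
    return 0.0 if den == 0 else num / den


def binary_metrics(cm: ConfusionMatrix) -> ValidationMetrics:
    """Sensitivity, specificity, PPV, NPV and MCC of a 2x2 confusion matrix.

    MCC = (AA*BB - BA*AB) / sqrt((AA+BA)(AA+AB)(BB+BA)(BB+AB)); a zero
    denominator yields 0 by convention.
    """
    if cm.n_classes != 2:
        raise ValueError("binary_metrics requires a 2x2 confusion matrix")
    (aa, ab), (ba, bb) = cm.counts.astype(float)
    den = math.sqrt((aa + ba) * (aa + ab) * (bb + ba) * (bb + ab))
    return ValidationMetrics(
        sensitivity=_safe_div(aa, aa + ab),
        specificity=_safe_div(bb, bb + ba),
        ppv=_safe_div(aa, aa + ba),
        npv=_safe_div(bb, bb + ab),
        mcc=_safe_div(aa * bb - ba * ab, den),
    )


def scale_ternary(x: float) -> float:
    """Map a three-class proportion onto the binary scale: 1/3 -> 0.5, 1 -> 1."""
    return 0.25 + 0.75 * x


def ternary_metrics(cm: ConfusionMatrix) -> ValidationMetrics:
    """Per-class recall/precision and the three-class MCC of a 3x3 matrix.

    With diagonal counts AA, BB, CC and per-class miss totals AX, BX, CX,

        MCC3 = (AA*BB*CC - AX*BX*CX) /
               cbrt( prod over d in {AA,BB,CC}, m in {AX,BX,CX} of (d + m) )

    which reduces to the binary form (4 pairwise sums under a square root)
    for two classes and equals 1 for any strictly diagonal matrix.  Recall
    and precision are also reported rescaled to the binary range
    (1/3 -> 0.5, 1 -> 1).
    """
    if cm.n_classes != 3:
        raise ValueError("ternary_metrics requires a 3x3 confusion matrix")
    diag = [int(x) for x in np.diag(cm.counts)]
    miss = [int(x) for x in cm.miss_totals()]
    num = math.prod(diag) - math.prod(miss)
    pair_product = math.prod(d + m for d in diag for m in miss)
    # exact integer cube root where it exists (e.g. strictly diagonal
    # matrices) so the +1 anchor is hit exactly
    if pair_product > 0:
        r = round(pair_product ** (1.0 / 3.0))
        for k in (-1, 0, 1):
            if (r + k) ** 3 == pair_product:
                den = float(r + k)
                break
        else:
            den = pair_product ** (1.0 / 3.0)
    else:
        den = 0.0
    mcc = _safe_div(float(num), den)
    c = cm.counts.astype(float)

    row = c.sum(axis=1)
    col = c.sum(axis=0)
    recall = [_safe_div(c[i, i], row[i]) for i in range(3)]
    precision = [_safe_div(c[i, i], col[i]) for i in range(3)]
    return ValidationMetrics(
        sensitivity=recall[0],
        specificity=recall[1],
        ppv=precision[0],
        npv=precision[1],
        mcc=mcc,
        recall_c=recall[2],
        precision_c=precision[2],
        scaled={
            "sensitivity": scale_ternary(recall[0]),
            "specificity": scale_ternary(recall[1]),
            "ppv": scale_ternary(precision[0]),
            "npv": scale_ternary(precision[1]),
            "recall_c": scale_ternary(recall[2]),
            "precision_c": scale_ternary(precision[2]),
        },
    )


def gorodkin_mcc(cm: ConfusionMatrix) -> float:
    """Covariance-based multiclass MCC (R_K statistic); cross-check metric.

    Provided as a config-switchable alternative to the product-form
    three-class MCC; the two agree at the +1 (perfect) anchor but differ
    away from it.
    """
    c = cm.counts.astype(float)
    t = c.sum(axis=1)  # true per class
    p = c.sum(axis=0)  # predicted per class
    n = c.sum()
    num = c.trace() * n - t @ p
    den = math.sqrt(n**2 - p @ p) * math.sqrt(n**2 - t @ t)
    return _safe_div(num, den)


def roc_curve(scores, labels, positive_label=None):
    """TPR/FPR sweep and trapezoidal area under the curve.

    Parameters
    ----------
    scores : array of floats, higher = more likely positive.
    labels : array of class labels with exactly two distinct values.
    positive_label : which label counts as positive; defaults to the
        lexicographically larger one (sklearn convention).

    Returns
    -------
    (fpr, tpr, thresholds, area)
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"ROC requires exactly two classes, got {uniq.size}")
    fpr, tpr, thr = _sk_roc_curve(labels, np.asarray(scores, dtype=float),
                                  pos_label=positive_label)
    return fpr, tpr, thr, float(_sk_auc(fpr, tpr))
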