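"""Evaluation metrics for classification and segmentation.

Segmentation scores operate on binary masks: the Dice similarity
coefficient 2|y∩ŷ|/(|y|+|ŷ|), the Jaccard index (IoU)
|y∩ŷ|/(|y|+|ŷ|−|y∩ŷ|+ϵ) with a small stabiliser ϵ, and plain pixel
accuracy.  Classification reporting produces a confusion matrix (rows =
true class) with per-class precision/recall/F1 and overall accuracy in
percent (correct / total × 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

__all__ = [
    "dice_score",
    "iou_score",
    "pixel_accuracy",
    "segmentation_scores",
    "SegmentationScores",
    "classification_report",
    "ClassificationReport",
]


def _check_masks(y, yhat):
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    if y.shape != yhat.shape:
        raise ValueError(f"mask shape mismatch: {y.shape} vs {yhat.shape}")
    for name, m in (("y", y), ("yhat", yhat)):
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{name} is not binary; values {vals[:5]}")
    return y.astype(np.int64), yhat.astype(np.int64)


def dice_score(y, yhat) -> float:
    """Dice coefficient 2|y∩ŷ|/(|y|+|ŷ|); both masks empty -> 1.0.

    The empty-vs-empty case is 0/0 in the defining formula; it is fixed to
    1.0 by convention (a prediction of "nothing" for a truly empty mask is
    perfect agreement).
    """
    y, yhat = _check_masks(y, yhat)
    denom = int(y.sum() + yhat.sum())
    if denom == 0:
        return 1.0
    return 2.0 * float((y & yhat).sum()) / denom


def iou_score(y, yhat, epsilon_stab: float = 1e-7) -> float:
    """Intersection over union with stabiliser: |y∩ŷ|/(|y∪ŷ|+ϵ)."""
    y, yhat = _check_masks(y, yhat)
    inter = float((y & yhat).sum())
    union = float(y.sum() + yhat.sum()) - inter
    return inter / (union + epsilon_stab)


def pixel_accuracy(y, yhat) -> float:
    """Fraction of pixels where prediction equals ground truth."""
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    if y.shape != yhat.shape:
        raise ValueError(f"mask shape mismatch: {y.shape} vs {yhat.shape}")
    return float((y == yhat).mean())


@dataclass
class SegmentationScores:
    dice: float
    iou: float
    pixel_accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {"dice": self.dice, "iou": self.iou, "pixel_accuracy": self.pixel_accuracy}


def segmentation_scores(y, yhat, epsilon_stab: float = 1e-7) -> SegmentationScores:
    return SegmentationScores(
        dice=dice_score(y, yhat),
        iou=iou_score(y, yhat, epsilon_stab),
        pixel_accuracy=pixel_accuracy(y, yhat),
    )


@dataclass
class ClassificationReport:
    """Confusion matrix plus per-class and overall classification metrics.

    ``per_class_accuracy`` is the one-vs-rest accuracy of each class
    ((TP+TN)/total); ``overall_accuracy`` is correct/total x 100.  Both are
    reported because per-class "accuracy" tables in the field are sometimes
    one and sometimes the other.
    """

    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    per_class_accuracy: np.ndarray
    overall_accuracy: float
    num_classes: int = field(default=0)

    def as_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "precision_pct": (100 * self.precision).round(4).tolist(),
            "recall_pct": (100 * self.recall).round(4).tolist(),
            "f1_pct": (100 * self.f1).round(4).tolist(),
            "per_class_accuracy_pct": (100 * self.per_class_accuracy).round(4).tolist(),
            "overall_accuracy_pct": round(self.overall_accuracy, 4),
        }


def classification_report(truths, preds, num_classes: int) -> ClassificationReport:
    truths = np.asarray(truths, dtype=np.int64)
    preds = np.asarray(preds, dtype=np.int64)
    if truths.shape != preds.shape:
        raise ValueError("truths and preds must have equal length")
    if truths.size == 0:
        raise ValueError("empty evaluation set")
    if truths.max(initial=0) >= num_classes or preds.max(initial=0) >= num_classes:
        raise ValueError("label outside [0, num_classes)")
    labels = np.arange(num_classes)
    conf = _sk_confusion(truths, preds, labels=labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = _sk_prfs(truths, preds, labels=labels, zero_division=0)
    if np.any((conf.sum(axis=0) == 0) | (conf.sum(axis=1) == 0)):
        warnings.warn("a class has no predictions or no truths; its metrics are 0",
                      stacklevel=2)
    total = conf.sum()
    tp = np.diag(conf)
    per_class_acc = (tp + (total - conf.sum(axis=0) - conf.sum(axis=1) + tp)) / total
    overall = 100.0 * tp.sum() / total
    return ClassificationReport(
        confusion=conf,
        precision=prec,
        recall=rec,
        f1=f1,
        per_class_accuracy=per_class_acc,
        overall_accuracy=float(overall),
        num_classes=num_classes,
    )
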