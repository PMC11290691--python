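"""Segmentation and classification metrics: Dice, confusion-matrix rates, ROC/AUC."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve as sk_roc_curve


def dice(t, p) -> float:
    """Dice overlap 2|T∩P| / (|T|+|P|) between two binary rasters.

    Two empty masks agree perfectly and score 1.
    """
    t = np.asarray(t, dtype=bool)
    p = np.asarray(p, dtype=bool)
    if t.shape != p.shape:
        raise ValueError("shape mismatch")
    denom = int(t.sum()) + int(p.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((t & p).sum()) / denom


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity (recall), precision and F1 from raw counts.

    Ratios with a zero denominator are reported as None (missing), never
    silently substituted with 0.
    """
    if c.total == 0:
        raise ValueError("no observations")
    acc = (c.tp + c.tn) / c.total
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    prec = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    if prec is None or sens is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return {"accuracy": acc, "sensitivity": sens, "precision": prec, "f1": f1}


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) from a sweep over unique score thresholds, and AUC.

    Tied scores are grouped; the area is the trapezoidal integral.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = sk_roc_curve(labels, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(sk_auc(fpr, tpr))


@dataclass
class EvalReport:
    """Bundle of segmentation overlap, classification rates and ROC curve."""

    dice: float | None = None
    accuracy: float | None = None
    sensitivity: float | None = None
    precision: float | None = None
    f1: float | None = None
    roc: list = field(default_factory=list)
    auc: float | None = None
    counts: ConfusionCounts | None = None

    @classmethod
    def from_predictions(cls, y_true, y_pred, scores=None, dice_value=None) -> "EvalReport":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        c = ConfusionCounts(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )
        m = confusion_metrics(c)
        roc, auc_value = ([], None)
        if scores is not None and len(np.unique(y_true)) == 2:
            roc, auc_value = roc_auc(scores, y_true)
        return cls(dice=dice_value, roc=roc, auc=auc_value, counts=c, **m)

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "dice": self.dice,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
            "auc": self.auc,
            "roc": self.roc,
            "counts": None
            if self.counts is None
            else {"tp": self.counts.tp, "tn": self.counts.tn,
                  "fp": self.counts.fp, "fn": self.counts.fn},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
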