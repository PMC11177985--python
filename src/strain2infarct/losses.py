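"""Segmentation losses and evaluation metrics.

Losses operate on a predicted per-pixel probability map ``p`` in [0, 1] and a
binary ground-truth mask ``y``.  The soft Dice loss uses the squared
denominator ``1 - 2*sum(p*y) / (sum(p^2) + sum(y^2))`` and the IoU (Jaccard)
loss ``1 - sum(p*y) / sum(p + y - p*y)``; both carry an additive smoothing
constant so that empty masks are well defined.  Metrics are computed from the
pixel confusion counts; two empty masks are scored as a perfect match (1.0)
for both IoU and DSC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autodiff import Tensor

BCE_EPS = 1e-7
SMOOTH = 1e-6


def _check_pair(p, y):
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("ground truth mask must be binary")
    return p, y.astype(float)


def bce_loss(p, y) -> float:
    """Mean binary cross-entropy; p is clipped to [eps, 1-eps]."""
    p, y = _check_pair(p, y)
    p = np.clip(p, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def dsc_loss(p, y) -> float:
    """Soft Dice complement with squared denominator."""
    p, y = _check_pair(p, y)
    num = 2.0 * np.sum(p * y) + SMOOTH
    den = np.sum(p * p) + np.sum(y * y) + SMOOTH
    return float(1.0 - num / den)


def iou_loss(p, y) -> float:
    """Soft Jaccard complement."""
    p, y = _check_pair(p, y)
    num = np.sum(p * y) + SMOOTH
    den = np.sum(p + y - p * y) + SMOOTH
    return float(1.0 - num / den)


# -- differentiable versions used during training -----------------------------

def bce_loss_t(p: Tensor, y: np.ndarray) -> Tensor:
    y = Tensor(np.asarray(y, dtype=np.float32))
    pc = p.clip_eps(BCE_EPS)
    return -(y * pc.log() + (1.0 - y) * (1.0 - pc).log()).mean()


def dsc_loss_t(p: Tensor, y: np.ndarray) -> Tensor:
    y = Tensor(np.asarray(y, dtype=np.float32))
    num = (p * y).sum() * 2.0 + SMOOTH
    den = (p * p).sum() + (y * y).sum() + SMOOTH
    return 1.0 - num / den

def iou_loss_t(p: Tensor, y: np.ndarray) -> Tensor:
    y = Tensor(np.asarray(y, dtype=np.float32))
    num = (p * y).sum() + SMOOTH
    den = (p + y - p * y).sum() + SMOOTH
    return 1.0 - num / den


TRAINING_LOSSES = {"bce": bce_loss_t, "dsc": dsc_loss_t, "iou": iou_loss_t}
EVAL_LOSSES = {"bce": bce_loss, "dsc": dsc_loss, "iou": iou_loss}


# -- confusion-count metrics ---------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred_mask, y) -> ConfusionCounts:
    pred_mask = np.asarray(pred_mask)
    y = np.asarray(y)
    if pred_mask.shape != y.shape:
        raise ValueError("shape mismatch")
    for arr in (pred_mask, y):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("confusion inputs must be binary")
    p = pred_mask.astype(bool)
    t = y.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def iou_score(c: ConfusionCounts) -> float:
    """Jaccard index TP/(TP+FP+FN); 1.0 when both masks are empty."""
    den = c.tp + c.fp + c.fn
    if den == 0:
        return 1.0
    return c.tp / den


def dsc_score(c: ConfusionCounts) -> float:
    """Dice coefficient (F1) 2TP/(2TP+FP+FN); 1.0 when both masks are empty."""
    den = 2 * c.tp + c.fp + c.fn
    if den == 0:
        return 1.0
    return 2 * c.tp / den


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.n


def precision(c: ConfusionCounts) -> float:
    den = c.tp + c.fp
    return 1.0 if den == 0 else c.tp / den


def recall(c: ConfusionCounts) -> float:
    den = c.tp + c.fn
    return 1.0 if den == 0 else c.tp / den


METRIC_NAMES = ("accuracy", "precision", "recall", "iou", "dsc")


def metric_report(pred_mask, y) -> dict:
    """All five evaluation metrics for one predicted/true mask pair."""
    c = confusion(pred_mask, y)
    return {
        "accuracy": accuracy(c),
        "precision": precision(c),
        "recall": recall(c),
        "iou": iou_score(c),
        "dsc": dsc_score(c),
    }
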