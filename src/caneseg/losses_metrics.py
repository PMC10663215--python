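"""Focal + Dice compound loss and confusion-matrix segmentation metrics.

The material classes are heavily imbalanced (broken cane is rare, background
dominates), so training combines focal loss — cross-entropy with easy pixels
down-weighted by ``(1 - p_t)^gamma`` — with a multi-class soft Dice loss
that scores per-class overlap directly.  Evaluation accumulates a pixel
confusion matrix and derives per-class IoU, mIoU and mPA; means are
unweighted over all classes *including background* (five classes here).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .autograd import Tensor

__all__ = [
    "PROB_EPS",
    "DICE_EPS",
    "ConfusionMatrix",
    "MetricsReport",
    "focal_loss",
    "dice_loss",
    "combined_loss",
    "confusion_matrix",
    "metrics_from_confusion",
]

log = logging.getLogger(__name__)

PROB_EPS = 1e-7  # clamp for probabilities entering a log
DICE_EPS = 1e-6  # smoothing for empty-class Dice terms


def _as_tensor(probs) -> Tensor:
    return probs if isinstance(probs, Tensor) else Tensor(probs)


def _one_hot(targets: np.ndarray, num_classes: int) -> np.ndarray:
    """(N, H, W) int labels -> (N, C, H, W) float32 one-hot."""
    t = np.asarray(targets)
    if t.min() < 0 or t.max() >= num_classes:
        raise ValueError(
            f"target labels must lie in [0, {num_classes}), got range "
            f"[{t.min()}, {t.max()}]"
        )
    eye = np.eye(num_classes, dtype=np.float32)
    return np.moveaxis(eye[t], -1, 1)


def focal_loss(probs, targets: np.ndarray, alpha=0.25, gamma: float = 2.0) -> Tensor:
    """Mean focal loss -alpha_t (1 - p_t)^gamma log(p_t) over all pixels.

    ``probs`` are per-pixel class probabilities (N, C, H, W), rows summing
    to 1; ``targets`` integer labels (N, H, W).  ``alpha`` may be a scalar
    or a per-class vector indexed by the true class.  With gamma = 0 and
    alpha = 1 this is standard cross-entropy.  Probabilities are clamped at
    ``PROB_EPS`` before the log; a clamp is logged since it signals a
    saturated (confidently wrong) prediction.
    """
    if gamma < 0:
        raise ValueError(f"gamma must be non-negative, got {gamma}")
    probs = _as_tensor(probs)
    nc = probs.shape[1]
    onehot = _one_hot(targets, nc)
    p_t = (probs * Tensor(onehot)).sum(axis=1)  # (N, H, W)
    if float(p_t.data.min()) < PROB_EPS:
        log.warning("focal_loss: clamping %d probabilities below %.0e",
                    int((p_t.data < PROB_EPS).sum()), PROB_EPS)
    p_t = p_t.clip(PROB_EPS, 1.0)
    alpha_arr = np.asarray(alpha, dtype=np.float32)
    if alpha_arr.ndim == 0:
        alpha_t = Tensor(np.full(p_t.shape, float(alpha_arr), dtype=np.float32))
    else:
        if alpha_arr.size != nc:
            raise ValueError(f"per-class alpha needs {nc} entries, got {alpha_arr.size}")
        alpha_t = Tensor(alpha_arr[np.asarray(targets)])
    focal = alpha_t * (1.0 - p_t) ** gamma * p_t.log() * (-1.0)
    return focal.mean()


def dice_loss(probs, targets: np.ndarray, weights="uniform",
              literal_log: bool = False) -> Tensor:
    """Multi-class soft Dice loss.

    Default form: ``1 - sum_j 2 W_j <g_j, p_j> / (|g_j|^2 + |p_j|^2)`` with
    the class weights W_j normalized to sum to 1.  ``weights`` is
    ``"uniform"`` (1/c each), ``"reciprocal"`` (W_j proportional to 1/j by
    1-based class position), or an explicit vector.  Classes absent from
    both target and prediction contribute a smoothed neutral term.
    ``literal_log=True`` substitutes log(p) for p inside the overlap and
    norm terms (an auditable alternative reading; not recommended for
    training since log(p) is negative).
    """
    probs = _as_tensor(probs)
    nc = probs.shape[1]
    onehot = Tensor(_one_hot(targets, nc))
    if isinstance(weights, str):
        if weights == "uniform":
            w = np.full(nc, 1.0 / nc, dtype=np.float32)
        elif weights == "reciprocal":
            w = 1.0 / np.arange(1, nc + 1, dtype=np.float32)
            w /= w.sum()
        else:
            raise ValueError(f"unknown weight mode {weights!r}")
    else:
        w = np.asarray(weights, dtype=np.float32)
        if w.size != nc:
            raise ValueError(f"need {nc} class weights, got {w.size}")
        w = w / w.sum()
    p = probs.clip(PROB_EPS, 1.0).log() if literal_log else probs
    reduce_axes = tuple(i for i in range(probs.ndim) if i != 1)
    inter = (onehot * p).sum(axis=reduce_axes)  # (C,)
    norms = (onehot * onehot + p * p).sum(axis=reduce_axes)
    dice = (inter * 2.0 + DICE_EPS) / (norms + DICE_EPS)
    return 1.0 - (Tensor(w) * dice).sum()


def combined_loss(probs, targets: np.ndarray, w_focal: float = 1.0,
                  w_dice: float = 1.0, alpha=0.25, gamma: float = 2.0,
                  dice_weights="uniform") -> Tensor:
    """w_focal * focal + w_dice * dice (negative weights are rejected)."""
    if w_focal < 0 or w_dice < 0:
        raise ValueError(f"loss weights must be non-negative, got {w_focal}, {w_dice}")
    total = Tensor(0.0)
    if w_focal:
        total = total + w_focal * focal_loss(probs, targets, alpha=alpha, gamma=gamma)
    if w_dice:
        total = total + w_dice * dice_loss(probs, targets, weights=dice_weights)
    return total


# ---------------------------------------------------------------------------
# confusion matrix and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """c x c pixel counts; rows are ground truth, columns prediction."""

    counts: np.ndarray

    @classmethod
    def zeros(cls, num_classes: int) -> "ConfusionMatrix":
        return cls(np.zeros((num_classes, num_classes), dtype=np.int64))

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)

    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(predicted: np.ndarray, ground_truth: np.ndarray,
                     num_classes: int) -> ConfusionMatrix:
    """Accumulate per-pixel (gt, pred) counts; every pixel is counted."""
    pred = np.asarray(predicted).ravel()
    gt = np.asarray(ground_truth).ravel()
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {predicted.shape} vs gt {ground_truth.shape}")
    for name, arr in (("predicted", pred), ("ground_truth", gt)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(
                f"{name} labels out of range [0, {num_classes}): "
                f"[{arr.min()}, {arr.max()}]"
            )
    counts = np.bincount(gt.astype(np.int64) * num_classes + pred.astype(np.int64),
                         minlength=num_classes * num_classes)
    return ConfusionMatrix(counts.reshape(num_classes, num_classes))


@dataclass
class MetricsReport:
    """Per-class IoU plus mIoU/mPA (percent) and deployability numbers."""

    per_class_iou: dict[str, float]
    miou: float
    mpa: float
    excluded_classes: list[str] = field(default_factory=list)
    params: int | None = None
    flops: int | None = None
    inference_time_ms: float | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=float)

    def to_csv_row(self, model_name: str = "model") -> str:
        ious = ",".join(f"{v:.2f}" for v in self.per_class_iou.values())
        params = "" if self.params is None else f"{self.params / 1e6:.2f}"
        flops = "" if self.flops is None else f"{self.flops / 1e9:.2f}"
        t = "" if self.inference_time_ms is None else f"{self.inference_time_ms:.2f}"
        return f"{model_name},{ious},{self.miou:.2f},{self.mpa:.2f},{params},{flops},{t}"


def metrics_from_confusion(cm: ConfusionMatrix,
                           class_names: Sequence[str] | None = None) -> MetricsReport:
    """Per-class IoU, mIoU and mPA (percent) from a confusion matrix.

    IoU_i = P_ii / (row_i + col_i - P_ii).  mIoU and mPA are unweighted
    means over all classes present in ground truth or prediction — classes
    absent from both are excluded and flagged.  Per-class accuracy for a
    class never predicted but present in ground truth is 0, not undefined.
    """
    c = cm.num_classes
    names = list(class_names) if class_names is not None else [str(i) for i in range(c)]
    if len(names) != c:
        raise ValueError(f"need {c} class names, got {len(names)}")
    counts = cm.counts.astype(np.float64)
    gt_tot = counts.sum(axis=1)
    pred_tot = counts.sum(axis=0)
    diag = np.diag(counts)
    present = (gt_tot + pred_tot) > 0
    ious, pas = {}, []
    excluded = [names[i] for i in range(c) if not present[i]]
    for i in range(c):
        if not present[i]:
            continue
        union = gt_tot[i] + pred_tot[i] - diag[i]
        ious[names[i]] = 100.0 * diag[i] / union if union > 0 else 0.0
        if gt_tot[i] > 0:  # accuracy is undefined for classes with no gt pixels
            pas.append(100.0 * diag[i] / gt_tot[i])
    if not ious:
        raise ValueError("confusion matrix is empty")
    return MetricsReport(
        per_class_iou=ious,
        miou=float(np.mean(list(ious.values()))),
        mpa=float(np.mean(pas)),
        excluded_classes=excluded,
    )
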