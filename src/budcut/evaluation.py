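"""Quantitative evaluation: pixel positioning errors and detection metrics.

Positioning quality is judged per image by the component-wise absolute pixel
differences between a manually placed cutting point and the computed one,
their rounded Euclidean norm, and the fraction of images whose overall error
stays below a pixel threshold (15 px by default, the working tolerance of the
cutting actuator).

Detection quality uses the usual confusion-count metrics (precision, recall,
F1, Matthews correlation coefficient) plus average precision as the area
under the all-points interpolated precision-recall curve with greedy
IoU matching of predicted to ground-truth boxes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .yolo import Box

logger = logging.getLogger(__name__)

__all__ = [
    "PositioningError",
    "ConfusionCounts",
    "DetectionSet",
    "positioning_error",
    "success_rate",
    "precision",
    "recall",
    "f1_score",
    "mcc",
    "box_iou",
    "average_precision",
    "mean_average_precision",
]


def _round_half_away(v: float) -> int:
    return int(math.copysign(math.floor(abs(v) + 0.5), v))


@dataclass(frozen=True)
class PositioningError:
    """Pixel errors of one computed cutting point against the manual one."""

    e_x: float  # |X_manual − x_computed|, column direction
    e_y: float  # |Y_manual − y_computed|, row direction
    e: int  # rounded Euclidean norm of (e_x, e_y)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class DetectionSet:
    """Scored predicted boxes plus ground-truth boxes for PR/AP evaluation.

    Each prediction is (Box, score in [0,1]); class labels travel on the boxes.
    """

    predictions: list[tuple[Box, float]]
    truths: list[Box]

    def __post_init__(self) -> None:
        for _, s in self.predictions:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"scores must lie in [0,1], got {s}")


def positioning_error(manual, computed) -> PositioningError:
    """Component absolute differences and their rounded Euclidean norm.

    ``manual`` and ``computed`` are (x, y) pairs or objects with x/y fields.
    The overall error ``e`` rounds half away from zero to integer pixels.
    """
    mx, my = (manual.x, manual.y) if hasattr(manual, "x") else (manual[0], manual[1])
    cx, cy = (computed.x, computed.y) if hasattr(computed, "x") else (computed[0], computed[1])
    e_x = abs(mx - cx)
    e_y = abs(my - cy)
    return PositioningError(e_x=e_x, e_y=e_y, e=_round_half_away(math.hypot(e_x, e_y)))


def success_rate(
    errors: list[PositioningError], threshold: float = 15
) -> tuple[int, int]:
    """Count and integer percentage of errors strictly below ``threshold``."""
    if not errors:
        raise ValueError("success_rate needs at least one error record")
    count = sum(1 for r in errors if r.e < threshold)
    percent = _round_half_away(100.0 * count / len(errors))
    return count, percent


def precision(c: ConfusionCounts) -> float:
    """Tp / (Tp + Fp) as a percentage; NaN (with a warning) if no positives predicted."""
    if c.tp + c.fp == 0:
        logger.warning("precision undefined: no predicted positives")
        return float("nan")
    return 100.0 * c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    """Tp / (Tp + Fn) as a percentage; NaN (with a warning) if no actual positives."""
    if c.tp + c.fn == 0:
        logger.warning("recall undefined: no actual positives")
        return float("nan")
    return 100.0 * c.tp / (c.tp + c.fn)


def f1_score(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall, as a percentage."""
    p, r = precision(c), recall(c)
    if math.isnan(p) or math.isnan(r):
        return float("nan")
    if p + r == 0:
        logger.warning("F1 undefined: precision and recall both zero")
        return float("nan")
    return 2.0 * p * r / (p + r)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [−1, 1]; 0 when a denominator factor is 0."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        logger.info("MCC denominator has a zero factor; returning 0 by convention")
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def _corners(b: Box) -> tuple[float, float, float, float]:
    # boxes without a center are treated as corner-aligned at the origin
    cx = b.x if b.x is not None else b.w / 2.0
    cy = b.y if b.y is not None else b.h / 2.0
    return cx - b.w / 2.0, cy - b.h / 2.0, cx + b.w / 2.0, cy + b.h / 2.0


def box_iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two axis-aligned boxes."""
    ax0, ay0, ax1, ay1 = _corners(a)
    bx0, by0, bx1, by1 = _corners(b)
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def _match_predictions(
    preds: list[tuple[Box, float]], truths: list[Box], iou_threshold: float
) -> np.ndarray:
    """Greedy one-to-one matching by descending score; returns tp flags per pred."""
    order = sorted(range(len(preds)), key=lambda i: -preds[i][1])
    used = [False] * len(truths)
    tp = np.zeros(len(preds), dtype=bool)
    for i in order:
        box, _ = preds[i]
        best, best_iou = -1, iou_threshold
        for j, t in enumerate(truths):
            if used[j] or t.label != box.label:
                continue
            iou = box_iou(box, t)
            if iou >= best_iou:
                best, best_iou = j, iou
        if best >= 0:
            used[best] = True
            tp[i] = True
    return tp[np.asarray(order)]  # in descending-score order


def _ap_from_flags(tp_sorted: np.ndarray, n_truth: int) -> float:
    tp_cum = np.cumsum(tp_sorted)
    fp_cum = np.cumsum(~tp_sorted)
    rec = tp_cum / n_truth
    prec = tp_cum / (tp_cum + fp_cum)
    # all-points interpolation: precision envelope from the right
    prec_env = np.maximum.accumulate(prec[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(rec, prec_env):
        ap += (r - prev_r) * p
        prev_r = r
    return 100.0 * ap


def average_precision(d: DetectionSet, iou_threshold: float = 0.5, label=None) -> float:
    """AP (%) for one class: area under the interpolated PR step curve.

    Predictions are sorted by descending score and greedily matched one-to-one
    to ground truths at the given IoU threshold; ``label=None`` evaluates the
    whole set as a single class (labels still must agree box-to-box).
    """
    truths = [t for t in d.truths if label is None or t.label == label]
    if not truths:
        logger.warning("average precision undefined: no ground-truth boxes")
        return float("nan")
    preds = [(b, s) for b, s in d.predictions if label is None or b.label == label]
    if not preds:
        return 0.0
    tp_sorted = _match_predictions(preds, truths, iou_threshold)
    return _ap_from_flags(tp_sorted, len(truths))


def mean_average_precision(d: DetectionSet, iou_threshold: float = 0.5) -> float:
    """Mean of per-class AP over the classes present in the ground truth."""
    labels = sorted({t.label for t in d.truths}, key=lambda x: (x is None, x))
    if not labels:
        logger.warning("mAP undefined: no ground-truth boxes")
        return float("nan")
    return float(
        np.mean([average_precision(d, iou_threshold, label=lab) for lab in labels])
    )
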