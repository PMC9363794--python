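"""Segmentation and localization metrics.

Per-class one-vs-rest confusion counts over all pixels feed IoU and pixel
accuracy; MIoU/MPA are unweighted means over all k+1 classes including
background.  Center errors (DO for the disc, DM for the macula) are plain
Euclidean pixel distances between true and predicted centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "SegMetrics",
    "confusion_counts",
    "iou_pa",
    "center_error",
    "summarize",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest pixel counts per class.

    ``tp[c] + fp[c] + fn[c] + tn[c]`` equals the total pixel count for every
    class ``c``; ``sum(tp)`` equals the number of correctly classified pixels
    because the classes partition the image.
    """

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def num_classes(self) -> int:
        return len(self.tp)

    @property
    def total_pixels(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


@dataclass(frozen=True)
class SegMetrics:
    """Per-class IoU and PA with their unweighted means (MIoU, MPA).

    ``undefined_classes`` lists classes absent from both masks, whose IoU is
    defined as 1.0 ("nothing to find, nothing found").
    """

    iou: np.ndarray
    pa: np.ndarray
    miou: float
    mpa: float
    undefined_classes: tuple = field(default=())


def confusion_counts(predicted, truth, num_classes: int = 3) -> ConfusionCounts:
    """Per-class TP/FP/FN/TN over all pixels of a predicted/truth mask pair."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape} vs truth {truth.shape}"
        )
    total = predicted.size
    tp = np.empty(num_classes, dtype=np.int64)
    fp = np.empty(num_classes, dtype=np.int64)
    fn = np.empty(num_classes, dtype=np.int64)
    for c in range(num_classes):
        p = predicted == c
        t = truth == c
        tp[c] = np.count_nonzero(p & t)
        fp[c] = np.count_nonzero(p & ~t)
        fn[c] = np.count_nonzero(~p & t)
    tn = total - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def iou_pa(counts: ConfusionCounts) -> SegMetrics:
    """IoU = TP/(TP+FP+FN) and PA = (TP+TN)/total per class, plus MIoU/MPA.

    A class absent from both masks (TP+FP+FN = 0) gets IoU 1.0 and is
    reported in ``undefined_classes``.
    """
    tp = counts.tp.astype(float)
    fp = counts.fp.astype(float)
    fn = counts.fn.astype(float)
    tn = counts.tn.astype(float)
    union = tp + fp + fn
    undefined = tuple(int(c) for c in np.nonzero(union == 0)[0])
    iou = np.where(union > 0, tp / np.where(union > 0, union, 1.0), 1.0)
    pa = (tp + tn) / (tp + fp + fn + tn)
    return SegMetrics(
        iou=iou,
        pa=pa,
        miou=float(iou.mean()),
        mpa=float(pa.mean()),
        undefined_classes=undefined,
    )


def center_error(truth, predicted) -> float:
    """Euclidean distance in pixels between a true and a predicted center."""
    x1, y1 = float(truth[0]), float(truth[1])
    x2, y2 = float(predicted[0]), float(predicted[1])
    if not all(math.isfinite(v) for v in (x1, y1, x2, y2)):
        raise ValueError("center coordinates must be finite")
    return math.hypot(x2 - x1, y2 - y1)


def summarize(values):
    """(min, max, arithmetic mean) of a non-empty list of per-image numbers."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("summarize requires a non-empty list of values")
    return float(values.min()), float(values.max()), float(values.mean())
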