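"""Detection and classification evaluation statistics.

Confusion-matrix metrics (accuracy, precision, recall), mean average
precision over per-class APs, box intersection-over-union, all-point
interpolated AP from scored detections, and the paired t-test comparing
two sets of per-image IoU values:

    t = mean(d) / sqrt( sum((d_i - mean(d))^2) / (N (N - 1)) ),  d_i = X_i - Y_i

with a two-sided p-value from Student's t distribution on N - 1 degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import Box, ParameterError


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary-classification counts."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ParameterError(f"{name} must be a non-negative integer, got {v}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class Metrics:
    """Accuracy / precision / recall as fractions; ``None`` marks an
    undefined value (zero denominator), never a silent zero."""

    accuracy: float
    precision: Optional[float]
    recall: Optional[float]


def percent(value: Optional[float]) -> str:
    """Render a fraction as a percentage with 2 decimals, half away from zero."""
    if value is None:
        return "undefined"
    q = (Decimal(repr(value)) * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return f"{q}%"


def confusion_metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, precision and recall from a confusion matrix.

    accuracy = (TP+TN)/total, precision = TP/(TP+FP), recall = TP/(TP+FN);
    a zero denominator yields ``None`` for that metric.
    """
    if cm.total < 1:
        raise ParameterError("confusion matrix is all zero")
    accuracy = (cm.TP + cm.TN) / cm.total
    precision = cm.TP / (cm.TP + cm.FP) if cm.TP + cm.FP > 0 else None
    recall = cm.TP / (cm.TP + cm.FN) if cm.TP + cm.FN > 0 else None
    return Metrics(accuracy, precision, recall)


def mean_average_precision(aps: Sequence[float]) -> float:
    """Arithmetic mean of per-class average-precision values."""
    aps = list(aps)
    if not aps:
        raise ParameterError("AP list is empty")
    if any(not (0.0 <= a <= 1.0) for a in aps):
        raise ParameterError("AP values must lie in [0, 1]")
    return float(np.mean(aps))


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two half-open pixel boxes."""
    ix = max(0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def ap_from_detections(
    detections: Sequence[tuple[Box, float]],
    ground_truth: Sequence[Box],
    iou_threshold: float = 0.5,
) -> float:
    """All-point interpolated average precision for one class.

    Detections are sorted by descending score and greedily matched
    one-to-one to the unmatched ground-truth box of highest IoU, counting a
    true positive when that IoU reaches ``iou_threshold``. AP is the area
    under the precision envelope of the resulting precision-recall curve.
    """
    if not ground_truth:
        raise ParameterError("no ground-truth boxes")
    if any(not np.isfinite(s) for _, s in detections):
        raise ParameterError("detection scores must be finite")
    order = sorted(range(len(detections)), key=lambda i: -detections[i][1])
    matched = [False] * len(ground_truth)
    tp = np.zeros(len(detections))
    for rank, i in enumerate(order):
        box, _ = detections[i]
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(ground_truth):
            if matched[j]:
                continue
            v = iou(box, gt)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            tp[rank] = 1.0
    if len(detections) == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, len(detections) + 1)
    recall = cum_tp / len(ground_truth)
    # precision envelope (running max from the right), then sum of
    # recall increments weighted by envelope precision
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for p, r in zip(env, recall):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


@dataclass(frozen=True)
class PairedSamples:
    """Two equal-length sequences of per-image IoU values to compare."""

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.X, dtype=np.float64)
        y = np.asarray(self.Y, dtype=np.float64)
        if x.ndim != 1 or x.shape != y.shape:
            raise ParameterError("X and Y must be 1-D sequences of equal length")
        if x.size < 2:
            raise ParameterError("need at least 2 paired samples")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ParameterError("paired samples must be finite")
        object.__setattr__(self, "X", x)
        object.__setattr__(self, "Y", y)

    @property
    def differences(self) -> np.ndarray:
        return self.X - self.Y


def paired_t_test(samples: PairedSamples) -> tuple[float, float]:
    """Paired t statistic on the IoU differences and its two-sided p-value.

    Raises for zero-variance differences (the statistic is undefined there,
    not infinite).
    """
    d = samples.differences
    n = d.size
    d_bar = d.mean()
    ss = float(np.sum((d - d_bar) ** 2))
    if ss == 0.0:
        raise ParameterError("differences have zero variance; t statistic undefined")
    t = d_bar / np.sqrt(ss / (n * (n - 1)))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return float(t), p
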