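"""Per-pixel confusion-count segmentation metrics.

Film (label 1) is the positive class.  The IOU reported here is the mean of
the film-class and background-class Jaccard indices,

    IOU = 1/2 * ( TP / (TP + FP + FN)  +  TN / (TN + FN + FP) ),

and "MIOU" over a test set is, by default, the arithmetic mean of this
per-image IOU; a pooled variant (IOU of the summed confusion counts) is
always available alongside.

Zero-denominator conventions: a class absent from both prediction and truth
contributes a vacuously perfect term (1.0); precision is 1 when nothing was
predicted positive and nothing was missed (TP+FP = 0 and FN = 0), else 0
when TP+FP = 0, and recall is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rfilm.dataio import BinaryMask

__all__ = ["ConfusionCounts", "MetricPanel", "confusion", "panel", "miou_over_set", "metrics_table"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricPanel:
    """Segmentation metrics as fractions in [0, 1]."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    iou: float

    def as_percent(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.__dict__.items()}


def confusion(pred: BinaryMask | np.ndarray, truth: BinaryMask | np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies of a predicted vs. ground-truth binary mask."""
    p = pred.labels if isinstance(pred, BinaryMask) else np.asarray(pred)
    t = truth.labels if isinstance(truth, BinaryMask) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    p = p.astype(bool)
    t = t.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def _ratio(num: int, den: int, vacuous: bool) -> float:
    if den == 0:
        return 1.0 if vacuous else 0.0
    return num / den


def panel(counts: ConfusionCounts) -> MetricPanel:
    """Full metric panel from confusion counts."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("cannot compute metrics over zero pixels")
    accuracy = (tp + tn) / counts.total
    precision = _ratio(tp, tp + fp, vacuous=(fn == 0))
    recall = _ratio(tp, tp + fn, vacuous=(fp == 0))
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    iou_film = _ratio(tp, tp + fp + fn, vacuous=True)
    iou_bg = _ratio(tn, tn + fn + fp, vacuous=True)
    return MetricPanel(accuracy, precision, recall, f1, 0.5 * (iou_film + iou_bg))


def miou_over_set(
    pairs: list[tuple[BinaryMask | np.ndarray, BinaryMask | np.ndarray]],
    mode: str = "per_image_mean",
) -> float:
    """Aggregate mean IOU over (prediction, truth) mask pairs.

    ``per_image_mean`` averages the per-image IOU; ``pooled`` computes IOU
    on the element-wise summed confusion counts.
    """
    if not pairs:
        raise ValueError("empty pair list")
    if mode == "per_image_mean":
        return float(np.mean([panel(confusion(p, t)).iou for p, t in pairs]))
    if mode == "pooled":
        total = ConfusionCounts(0, 0, 0, 0)
        for p, t in pairs:
            total = total + confusion(p, t)
        return panel(total).iou
    raise ValueError(f"unknown mode {mode!r}")


def metrics_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-image/aggregate metric rows into a DataFrame in percent."""
    df = pd.DataFrame(rows)
    metric_cols = [c for c in df.columns if c in ("accuracy", "precision", "recall", "f1", "iou", "miou_per_image", "miou_pooled")]
    df[metric_cols] = (100.0 * df[metric_cols]).round(2)
    return df
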