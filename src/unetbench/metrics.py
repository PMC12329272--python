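"""Pixelwise segmentation agreement: confusion counts, Jaccard (IoU), Dice.

IoU is TP / (TP + FN + FP); Dice is 2 TP / ((TP + FN) + (TP + FP)). The two
are linked by Dice = 2 IoU / (1 + IoU), so Dice >= IoU always, with equality
only at 0 and 1 — a useful sanity check on any reported table. When both
masks are empty the 0/0 ratio is defined as 1.0 (perfect agreement on
absence) and a warning is emitted.

Dataset-level aggregation is reported both ways: micro (pool the pixel
counts across images, then apply the formula) and macro (average the
per-image values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "iou",
    "dice",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies for a binary prediction against a binary truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (values in {{0, 1}})")
    return arr.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies; both arrays must be binary and same-shaped."""
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def iou(counts: ConfusionCounts) -> float:
    """Jaccard index TP / (TP + FN + FP); 1.0 when both masks are empty."""
    denom = counts.tp + counts.fn + counts.fp
    if denom == 0:
        warnings.warn("IoU of two empty masks is undefined; returning 1.0",
                      stacklevel=2)
        return 1.0
    return counts.tp / denom


def dice(counts: ConfusionCounts) -> float:
    """Dice coefficient 2 TP / ((TP + FN) + (TP + FP)); 1.0 when both empty."""
    denom = 2 * counts.tp + counts.fn + counts.fp
    if denom == 0:
        warnings.warn("Dice of two empty masks is undefined; returning 1.0",
                      stacklevel=2)
        return 1.0
    return 2 * counts.tp / denom


@dataclass
class MetricReport:
    """Per-image metrics plus micro (pooled) and macro (mean) aggregates."""

    per_image: list[tuple[str, float, float]]  # (identifier, iou, dice)
    micro_iou: float
    micro_dice: float
    macro_iou: float
    macro_dice: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_image, columns=["identifier", "iou", "dice"])


def evaluate_dataset(pairs: list[tuple[np.ndarray, np.ndarray, str]]) -> MetricReport:
    """Evaluate (pred, truth, identifier) triples into a :class:`MetricReport`."""
    if not pairs:
        raise ValueError("evaluate_dataset needs at least one (pred, truth, id) triple")
    per_image = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for pred, truth, identifier in pairs:
        counts = confusion_counts(pred, truth)
        per_image.append((identifier, iou(counts), dice(counts)))
        pooled = pooled + counts
    ious = np.array([r[1] for r in per_image])
    dices = np.array([r[2] for r in per_image])
    return MetricReport(
        per_image=per_image,
        micro_iou=iou(pooled),
        micro_dice=dice(pooled),
        macro_iou=float(ious.mean()),
        macro_dice=float(dices.mean()),
    )
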