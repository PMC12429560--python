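"""Segmentation evaluation: confusion counts, IoU, Dice, precision, recall,
pixel accuracy, and cross-entropy.

Two averaging modes are provided. ``pooled`` sums the confusion counts over
images before forming ratios, so the algebraic identities
``dice = 2*iou/(1+iou)`` and ``dice = harmonic_mean(precision, recall)`` hold
exactly. ``macro`` averages per-image scores, which is the default reporting
mode; macro averages do not satisfy those identities in general.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .types import LabelMap, STRIOSOME


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass
class SegmentationScore:
    iou: float
    dice: float
    precision: float
    recall: float
    accuracy: float
    averaging_mode: str = "pooled"


def _as_striosome_mask(m) -> np.ndarray:
    if isinstance(m, LabelMap):
        return m.labels == STRIOSOME
    a = np.asarray(m)
    if a.dtype != bool:
        a = a.astype(bool)
    return a


def confusion(pred, truth, evaluation_region=None) -> ConfusionCounts:
    """Count striosome-vs-rest agreement inside ``evaluation_region``.

    ``pred`` and ``truth`` may be LabelMaps or boolean striosome masks. When
    ``evaluation_region`` is None and ``truth`` is a LabelMap, evaluation is
    restricted to striatal tissue (background, fibers and vessels excluded);
    for plain boolean masks the whole frame is evaluated. An empty evaluation
    region yields all-zero counts.
    """
    p = _as_striosome_mask(pred)
    t = _as_striosome_mask(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if evaluation_region is None:
        region = truth.striatal if isinstance(truth, LabelMap) else np.ones(t.shape, bool)
    else:
        region = np.asarray(evaluation_region, dtype=bool)
        if region.shape != t.shape:
            raise ValueError("evaluation_region shape mismatch")
    p = p[region]
    t = t[region]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(p.size - tp - fp - fn)
    return ConfusionCounts(tp, fp, fn, tn)


def score(counts: ConfusionCounts, averaging_mode: str = "pooled") -> SegmentationScore:
    """Overlap metrics from confusion counts.

    Zero-denominator convention: when both masks are empty (tp+fp+fn == 0)
    every overlap metric is 1.0; any other zero denominator scores 0.0.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    if tp + fp + fn == 0:
        iou = dice = precision = recall = 1.0
    else:
        iou = tp / (tp + fp + fn)
        dice = 2 * tp / (2 * tp + fp + fn)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = (tp + tn) / counts.total if counts.total else 1.0
    return SegmentationScore(iou, dice, precision, recall, accuracy, averaging_mode)


def pooled_score(counts: Iterable[ConfusionCounts]) -> SegmentationScore:
    total = ConfusionCounts()
    for c in counts:
        total = total + c
    return score(total, averaging_mode="pooled")


def macro_score(counts: Sequence[ConfusionCounts]) -> SegmentationScore:
    """Per-image scores averaged with equal weight (the default report mode)."""
    if not counts:
        raise ValueError("macro_score requires at least one image")
    per = [score(c) for c in counts]
    return SegmentationScore(
        iou=float(np.mean([s.iou for s in per])),
        dice=float(np.mean([s.dice for s in per])),
        precision=float(np.mean([s.precision for s in per])),
        recall=float(np.mean([s.recall for s in per])),
        accuracy=float(np.mean([s.accuracy for s in per])),
        averaging_mode="macro",
    )


def cross_entropy(prob_striosome: np.ndarray, truth, eps: float = 1e-7) -> float:
    """Mean pixel-wise binary cross-entropy of a striosome probability map."""
    t = _as_striosome_mask(truth).astype(np.float64)
    p = np.clip(np.asarray(prob_striosome, dtype=np.float64), eps, 1.0 - eps)
    return float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))


def scores_frame(per_image: dict[str, ConfusionCounts]):
    """Tidy per-image + aggregate score table (one row per image and mode)."""
    import pandas as pd

    rows = []
    for image_id, c in per_image.items():
        s = score(c)
        rows.append({"image": image_id, "mode": "per_image", **_score_row(s)})
    rows.append({"image": "__all__", "mode": "macro",
                 **_score_row(macro_score(list(per_image.values())))})
    rows.append({"image": "__all__", "mode": "pooled",
                 **_score_row(pooled_score(per_image.values()))})
    return pd.DataFrame(rows)


def _score_row(s: SegmentationScore) -> dict:
    return {"iou": s.iou, "dice": s.dice, "precision": s.precision,
            "recall": s.recall, "accuracy": s.accuracy}
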