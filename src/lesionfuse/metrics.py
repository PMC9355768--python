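"""Pixel-overlap evaluation metrics for binary segmentation.

All scores derive from the per-pixel confusion counts between a predicted
mask and the ground truth:

    Dice = 2TP / (2TP + FP + FN)        Jaccard = TP / (TP + FP + FN)
    Acc  = (TP + TN) / total            Sens = TP / (TP + FN)
    Spec = TN / (TN + FP)

plus the challenge-style thresholded Jaccard, which zeroes any per-image
Jaccard below a threshold (0.65 by convention) before averaging.  When a
score's denominator is empty because the relevant class is absent from both
masks, the score is defined as 1 (perfect agreement on absence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts", "confusion_counts", "dice", "jaccard", "accuracy",
    "sensitivity", "specificity", "thresholded_jaccard", "evaluate_masks",
    "aggregate_reports",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP / FP / FN / TN pixel tallies for one comparison."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally pixel agreement between two binary masks of equal shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dice(counts: ConfusionCounts) -> float:
    denom = 2 * counts.tp + counts.fp + counts.fn
    return 1.0 if denom == 0 else 2 * counts.tp / denom


def jaccard(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fp + counts.fn
    return 1.0 if denom == 0 else counts.tp / denom


def accuracy(counts: ConfusionCounts) -> float:
    return 1.0 if counts.total == 0 else (counts.tp + counts.tn) / counts.total


def sensitivity(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fn
    return 1.0 if denom == 0 else counts.tp / denom


def specificity(counts: ConfusionCounts) -> float:
    denom = counts.tn + counts.fp
    return 1.0 if denom == 0 else counts.tn / denom


def thresholded_jaccard(per_image_jaccards, threshold: float = 0.65) -> float:
    """Mean of per-image Jaccards with scores below ``threshold`` zeroed.

    The scoring rule of the ISIC 2018 lesion-boundary challenge.
    """
    scores = np.asarray(list(per_image_jaccards), dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one per-image Jaccard score")
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("Jaccard scores must lie in [0, 1]")
    return float(np.where(scores >= threshold, scores, 0.0).mean())


_METRICS = {
    "dice": dice,
    "jaccard": jaccard,
    "accuracy": accuracy,
    "sensitivity": sensitivity,
    "specificity": specificity,
}


def evaluate_masks(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """All five overlap metrics for one predicted/true mask pair."""
    counts = confusion_counts(pred, truth)
    return {name: fn(counts) for name, fn in _METRICS.items()}


def aggregate_reports(pairs_of_masks) -> dict[str, dict[str, float]]:
    """Per-image-mean and pooled-count metrics over (pred, truth) pairs.

    Returns ``{"per_image": {...}, "pooled": {...}}``; per_image additionally
    carries the thresholded Jaccard.
    """
    all_counts = [confusion_counts(p, t) for p, t in pairs_of_masks]
    if not all_counts:
        raise ValueError("no mask pairs to evaluate")
    per_image = {
        name: float(np.mean([fn(c) for c in all_counts]))
        for name, fn in _METRICS.items()
    }
    per_image["thresholded_jaccard"] = thresholded_jaccard(
        [jaccard(c) for c in all_counts])
    pooled_counts = all_counts[0]
    for c in all_counts[1:]:
        pooled_counts = pooled_counts + c
    pooled = {name: fn(pooled_counts) for name, fn in _METRICS.items()}
    return {"per_image": per_image, "pooled": pooled}
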