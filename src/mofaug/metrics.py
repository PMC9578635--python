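"""Pixelwise segmentation metrics and the train/test split utility.

Metrics are the standard overlap statistics on binary masks —
precision, recall, Dice similarity coefficient and volumetric overlap
error:

    P    = TP / (TP + FP)
    R    = TP / (TP + FN)
    Dice = 2 TP / (2 TP + FP + FN)
    VOE  = 1 - TP / (TP + FP + FN)

An undefined ratio (zero denominator) is reported as NaN rather than
raised.  The split utility shuffles item indices with a seeded generator
and cuts at ``round(train_fraction * n)``, the rule that reproduces an
8:2 split of 1186 items as (949, 237) and of 201 items as (161, 40).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "SegmentationScores",
    "SplitSpec",
    "confusion_counts",
    "precision_recall_dice_voe",
    "split_dataset",
    "kfold_split",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a binary segmentation versus ground truth.

    True negatives are not tracked; none of the overlap metrics here
    use them.
    """

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fp < 0 or self.fn < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass(frozen=True)
class SegmentationScores:
    precision: float
    recall: float
    dice: float
    voe: float

    def to_json(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "dice": self.dice,
            "voe": self.voe,
        }


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split parameters: default 8:2, shuffled by seed."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise TP/FP/FN between congruent binary masks."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, truth {truth.shape}")
    p = pred > 0
    t = truth > 0
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def precision_recall_dice_voe(c: ConfusionCounts) -> SegmentationScores:
    """Precision, recall, Dice and VOE from confusion counts.

    Undefined ratios (zero denominators, e.g. an all-zero count triple)
    come back as NaN markers, not exceptions.
    """
    return SegmentationScores(
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=_ratio(c.tp, c.tp + c.fn),
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        voe=1.0 - _ratio(c.tp, c.tp + c.fp + c.fn)
        if (c.tp + c.fp + c.fn) > 0
        else math.nan,
    )


def split_dataset(
    n_items: int, spec: SplitSpec = SplitSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled, disjoint, exhaustive train/test index split.

    ``|train| = round(train_fraction * n_items)`` to the nearest
    integer (half away from zero); the remainder is the test set.
    """
    if n_items < 2:
        raise ValueError("need at least 2 items to split")
    n_train = int(math.floor(spec.train_fraction * n_items + 0.5))
    perm = np.random.default_rng(spec.seed).permutation(n_items)
    return perm[:n_train].copy(), perm[n_train:].copy()


def kfold_split(
    n_items: int, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k disjoint (train, test) folds; each item is tested exactly once."""
    if n_items < k or k < 2:
        raise ValueError("need n_items >= k >= 2")
    perm = np.random.default_rng(seed).permutation(n_items)
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        test = folds[i]
        train = np.concatenate([folds[j] for j in range(k) if j != i])
        out.append((train, test))
    return out
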