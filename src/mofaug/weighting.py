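"""Median-frequency class balancing and the weighted cross-entropy loss.

Even after oversampling, background pixels outnumber lesion pixels by an
order of magnitude or more.  Median-frequency balancing counters this in
the loss: with per-class corpus pixel frequencies ``F_c = N_c / T``, the
class weight is

    W_c = median(F_c) / F_c,

so the rarer class always receives the strictly larger weight, and
``W_c * N_c`` — the weighted pixel mass — is equalised across the two
classes.  The weights feed a pixelwise weighted cross-entropy where each
pixel's term is scaled by its *target* class's weight.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .types import ArrayOrSlice

__all__ = [
    "class_pixel_counts",
    "class_frequencies",
    "class_weights",
    "weighted_cross_entropy",
    "weights_report",
]

#: default clip for log() arguments in the loss
DEFAULT_EPS = 1e-7


def class_pixel_counts(labels: Iterable[np.ndarray]) -> np.ndarray:
    """Tally (N_background, N_lesion) pixel counts over a label corpus."""
    counts = np.zeros(2, dtype=np.int64)
    for label in labels:
        arr = np.asarray(label)
        lesions = int(np.count_nonzero(arr))
        counts[1] += lesions
        counts[0] += arr.size - lesions
    return counts


def class_frequencies(counts: Sequence[int]) -> np.ndarray:
    """Per-class pixel frequency F_c = N_c / T over the corpus."""
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("pixel counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("corpus contains no pixels (T = 0)")
    return counts / total


def class_weights(freq: Sequence[float]) -> np.ndarray:
    """Median-frequency weights W_c = median(F_c) / F_c.

    For two classes the median is the mean of the two frequencies, so a
    balanced corpus (0.5, 0.5) yields unit weights.  A class with zero
    frequency is absent from the corpus and has no defined weight.
    """
    freq = np.asarray(freq, dtype=float)
    if (freq <= 0).any():
        raise ValueError(
            "every class must be present in the corpus (all F_c > 0)"
        )
    return np.median(freq) / freq


def weighted_cross_entropy(
    pred: ArrayOrSlice,
    target: np.ndarray,
    weights: Sequence[float],
    eps: float = DEFAULT_EPS,
) -> float:
    """Pixelwise weighted binary cross-entropy.

        WCE = -(1/n) * sum_i W_{c(i)} [T_i log P_i + (1 - T_i) log(1 - P_i)]

    ``pred`` holds predicted lesion probabilities in [0, 1] (clipped to
    [eps, 1 - eps] before the logs); ``target`` is the binary ground
    truth; ``W_{c(i)}`` is the weight of pixel i's target class; ``n``
    is the number of summed pixels, so the loss scale is independent of
    image resolution.
    """
    if eps <= 0 or eps >= 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    from .types import ImageSlice

    p = np.asarray(
        pred.pixels if isinstance(pred, ImageSlice) else pred, dtype=float
    )
    t = np.asarray(target)
    if p.shape != t.shape:
        raise ValueError(f"pred {p.shape} and target {t.shape} must be congruent")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    w = np.asarray(weights, dtype=float)
    if w.shape != (2,):
        raise ValueError("weights must be a length-2 (background, lesion) array")

    t_bin = (t > 0).astype(float)
    p = np.clip(p, eps, 1.0 - eps)
    pixel_w = np.where(t_bin > 0, w[1], w[0])
    terms = pixel_w * (t_bin * np.log(p) + (1.0 - t_bin) * np.log(1.0 - p))
    return float(-terms.mean())


def weights_report(counts: Sequence[int]) -> dict:
    """JSON-ready report: per class N_c, F_c, W_c plus the weighted
    pixel masses W_c * N_c (equal across classes by construction)."""
    counts = np.asarray(counts, dtype=np.int64)
    freq = class_frequencies(counts)
    weights = class_weights(freq)
    names = ("background", "lesion")
    return {
        name: {
            "N_c": int(counts[i]),
            "F_c": float(freq[i]),
            "W_c": float(weights[i]),
            "weighted_mass": float(weights[i] * counts[i]),
        }
        for i, name in enumerate(names)
    }
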