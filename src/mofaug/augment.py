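"""Copy-paste lesion oversampling and multiple-oversampling fusion (MOF).

Small lesions (pulmonary nodules, liver tumours) occupy a few percent of
the pixels of a CT slice at most, so segmentation networks trained on
such slices see an extreme background:lesion imbalance.  The operators
in this module attack the imbalance at the data level by pasting extra
copies of real lesions into the training images:

* :func:`oversample` — plain within-image random oversampling: copies of
  the image's own lesions are pasted, untransformed, at random admissible
  positions.
* :func:`mof_augment` — multiple-oversampling fusion: each paste draws a
  lesion from a bank built over the whole training set and applies a
  random rotation (theta ~ U(0, pi)), rescale (omega ~ U(0.5, 2.0)) and
  mirror before placement.

Every placement must satisfy the same constraint system
(:func:`check_placement`): the pasted bounding box keeps a margin from
the image border (default 5 px), the footprint may not overlap existing
lesions, and the lesion must lie inside the organ region.  Pasting is a
hard replacement of intensities on footprint pixels only; everything
outside accepted footprints is left bitwise unchanged.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .types import (
    ArrayOrSlice,
    ImageSlice,
    LesionPatch,
    Placement,
    PlacementConstraints,
    TransformRanges,
    as_pixels,
)

__all__ = [
    "extract_lesions",
    "build_lesion_bank",
    "rotate",
    "mirror",
    "enlarge",
    "check_placement",
    "PlacementDecision",
    "PlacementRecord",
    "AugmentationResult",
    "oversample",
    "mof_augment",
]

#: 8-connectivity structuring element for component labelling and the
#: separation dilation.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)

#: Placement draws attempted per patch before the patch is skipped.
DEFAULT_RETRY_BUDGET = 100


# ---------------------------------------------------------------------------
# lesion extraction

def extract_lesions(image: ArrayOrSlice, label: np.ndarray) -> list[LesionPatch]:
    """Cut one :class:`LesionPatch` per 8-connected lesion component.

    Each patch carries the intensities over the component's bounding
    box, the component's binary footprint, and the bounding box in
    source-image coordinates.  An all-background label yields an empty
    list.
    """
    pixels = as_pixels(image)
    label = np.asarray(label)
    if label.shape != pixels.shape:
        raise ValueError(
            f"label {label.shape} not congruent with image {pixels.shape}"
        )
    labelled, n = ndimage.label(label > 0, structure=_STRUCTURE_8)
    patches: list[LesionPatch] = []
    for comp, sl in enumerate(ndimage.find_objects(labelled), start=1):
        if sl is None:  # pragma: no cover - find_objects gap
            continue
        # bbox may graze a neighbouring component; keep only this one
        footprint = labelled[sl] == comp
        patches.append(
            LesionPatch(
                pixels=pixels[sl].copy(),
                footprint=footprint.copy(),
                source_bbox=(
                    sl[0].start,
                    sl[1].start,
                    sl[0].stop - sl[0].start,
                    sl[1].stop - sl[1].start,
                ),
            )
        )
    return patches


def build_lesion_bank(
    pairs: Sequence[tuple[ArrayOrSlice, np.ndarray]]
) -> list[LesionPatch]:
    """Pool the lesion patches of a whole dataset of (image, label) pairs."""
    bank: list[LesionPatch] = []
    for image, label in pairs:
        bank.extend(extract_lesions(image, label))
    return bank


# ---------------------------------------------------------------------------
# affine transforms

def rotate(patch: LesionPatch, theta: float) -> LesionPatch:
    """Rotate a patch by ``theta`` radians about its centre.

    The canvas expands so the full rotated footprint is contained, then
    is trimmed back to the footprint's bounding box.  Intensities are
    interpolated bilinearly, the footprint with nearest neighbour so it
    stays binary.  ``theta = 0`` is the exact identity.
    """
    if not math.isfinite(theta):
        raise ValueError("theta must be finite")
    if theta % (2 * math.pi) == 0:
        return patch.copy()
    angle_deg = math.degrees(theta)
    pixels = ndimage.rotate(
        patch.pixels, angle_deg, reshape=True, order=1, mode="constant", cval=0.0
    )
    footprint = ndimage.rotate(
        patch.footprint.astype(np.uint8), angle_deg, reshape=True, order=0,
        mode="constant", cval=0,
    ).astype(bool)
    if not footprint.any():
        # pathological sub-pixel footprint: keep the canvas centre pixel
        footprint = np.zeros_like(footprint)
        footprint[footprint.shape[0] // 2, footprint.shape[1] // 2] = True
        centre = patch.pixels[patch.footprint].mean()
        pixels = pixels.copy()
        pixels[footprint] = centre
    return _trim_to_footprint(LesionPatch(pixels, footprint, patch.source_bbox))


def mirror(patch: LesionPatch, tau: Literal["horizontal", "vertical"]) -> LesionPatch:
    """Mirror a patch: ``"horizontal"`` reverses columns (j' = N - 1 - j),
    ``"vertical"`` reverses rows.  An involution; shape is preserved."""
    if tau == "horizontal":
        axis = 1
    elif tau == "vertical":
        axis = 0
    else:
        raise ValueError(f"invalid mirror axis {tau!r}")
    return LesionPatch(
        np.flip(patch.pixels, axis=axis).copy(),
        np.flip(patch.footprint, axis=axis).copy(),
        patch.source_bbox,
    )


def enlarge(patch: LesionPatch, omega: float) -> LesionPatch:
    """Rescale a patch by factor ``omega`` in (0.5, 2.0].

    Output dimensions are ``round(omega * dims)`` with a minimum of 1.
    Intensities are interpolated bilinearly (the new pixels are filled
    by interpolation); the footprint uses nearest neighbour.
    ``omega = 1`` is the exact identity.
    """
    if not (0.5 <= omega <= 2.0):
        raise ValueError(f"omega {omega} outside the supported range [0.5, 2.0]")
    h, w = patch.shape
    new_h = max(1, int(round(omega * h)))
    new_w = max(1, int(round(omega * w)))
    if (new_h, new_w) == (h, w):
        return patch.copy()
    from skimage.transform import resize

    pixels = resize(
        patch.pixels, (new_h, new_w), order=1, mode="edge",
        anti_aliasing=omega < 1.0, preserve_range=True,
    )
    footprint = resize(
        patch.footprint.astype(float), (new_h, new_w), order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    ) > 0.5
    if not footprint.any():
        footprint[new_h // 2, new_w // 2] = True
    return LesionPatch(pixels, footprint, patch.source_bbox)


def _trim_to_footprint(patch: LesionPatch) -> LesionPatch:
    """Crop a patch to the bounding box of its footprint."""
    rows = np.flatnonzero(patch.footprint.any(axis=1))
    cols = np.flatnonzero(patch.footprint.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    return LesionPatch(patch.pixels[sl].copy(), patch.footprint[sl].copy(),
                       patch.source_bbox)


# ---------------------------------------------------------------------------
# placement

@dataclass(frozen=True)
class PlacementDecision:
    """Outcome of a placement check; ``reason`` is set on rejection."""

    accepted: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.accepted


def check_placement(
    placement: Placement,
    patch: LesionPatch,
    organ: np.ndarray,
    existing_lesions: np.ndarray,
    constraints: PlacementConstraints = PlacementConstraints(),
) -> PlacementDecision:
    """Accept or reject a candidate paste position.

    Checks, in order:

    1. the pasted bounding box lies within the image and at least
       ``border_margin`` pixels from every edge (reject: ``"margin"``);
    2. organ containment — ``full_footprint``: every footprint pixel
       inside the organ; ``anchor_only``: the anchor pixel inside the
       organ (reject: ``"containment"``);
    3. if ``require_no_overlap``, the footprint (padded by
       ``min_separation`` pixels) intersects no existing lesion pixel
       (reject: ``"overlap"``).
    """
    organ = np.asarray(organ, dtype=bool)
    existing = np.asarray(existing_lesions)
    if organ.shape != existing.shape:
        raise ValueError("organ and lesion masks must be congruent")
    height, width = organ.shape
    r0, c0, r1, c1 = placement.bbox
    if (r1 - r0, c1 - c0) != patch.shape:
        raise ValueError("placement shape does not match patch shape")

    m = constraints.border_margin
    if r0 < m or c0 < m or r1 > height - m or c1 > width - m:
        return PlacementDecision(False, "margin")

    if constraints.containment_mode == "full_footprint":
        if not organ[r0:r1, c0:c1][patch.footprint].all():
            return PlacementDecision(False, "containment")
    else:  # anchor_only
        if not organ[r0, c0]:
            return PlacementDecision(False, "containment")

    if constraints.require_no_overlap:
        sep = constraints.min_separation
        rr0, cc0 = max(0, r0 - sep), max(0, c0 - sep)
        rr1, cc1 = min(height, r1 + sep), min(width, c1 + sep)
        region = existing[rr0:rr1, cc0:cc1] > 0
        if region.any():
            fp = np.zeros((rr1 - rr0, cc1 - cc0), dtype=bool)
            fp[r0 - rr0 : r0 - rr0 + patch.shape[0],
               c0 - cc0 : c0 - cc0 + patch.shape[1]] = patch.footprint
            if sep:
                fp = ndimage.binary_dilation(fp, _STRUCTURE_8, iterations=sep)
            if (fp & region).any():
                return PlacementDecision(False, "overlap")

    return PlacementDecision(True)


# ---------------------------------------------------------------------------
# oversampling drivers

@dataclass(frozen=True)
class PlacementRecord:
    """One accepted paste: which patch went where, with which transform."""

    patch_index: int
    anchor: tuple[int, int]
    bbox: tuple[int, int, int, int]
    theta: float | None = None
    omega: float | None = None
    tau: str | None = None

    def to_json(self) -> dict:
        return {
            "patch_index": self.patch_index,
            "anchor": list(self.anchor),
            "bbox": list(self.bbox),
            "theta": self.theta,
            "omega": self.omega,
            "tau": self.tau,
        }


@dataclass
class AugmentationResult:
    """Augmented image + label plus a log of what happened.

    ``placements`` lists the accepted pastes in order; ``rejections``
    counts rejected placement draws by reason; ``requested`` is the
    sampling ratio m that was asked for (``len(placements)`` may be
    smaller when retry budgets were exhausted).
    """

    image: ImageSlice
    label: np.ndarray
    placements: list[PlacementRecord] = field(default_factory=list)
    rejections: Counter = field(default_factory=Counter)
    requested: int = 0

    @property
    def accepted(self) -> int:
        return len(self.placements)

    @property
    def exhausted(self) -> bool:
        return self.accepted < self.requested

    def to_json(self) -> dict:
        return {
            "requested": self.requested,
            "accepted": self.accepted,
            "placements": [p.to_json() for p in self.placements],
            "rejections": dict(self.rejections),
        }


def _paste(
    image: np.ndarray, label: np.ndarray, patch: LesionPatch, anchor: tuple[int, int]
) -> None:
    r0, c0 = anchor
    h, w = patch.shape
    view = image[r0 : r0 + h, c0 : c0 + w]
    view[patch.footprint] = patch.pixels[patch.footprint]
    label[r0 : r0 + h, c0 : c0 + w][patch.footprint] = 1


def _place_patch(
    patch: LesionPatch,
    record_args: dict,
    image: np.ndarray,
    label: np.ndarray,
    organ: np.ndarray,
    rng: np.random.Generator,
    constraints: PlacementConstraints,
    result: AugmentationResult,
    retry_budget: int,
) -> bool:
    """Draw anchors until one is accepted or the budget runs out."""
    height, width = image.shape
    h, w = patch.shape
    if h > height or w > width:
        result.rejections["too_large"] += 1
        return False
    for _ in range(retry_budget):
        anchor = (int(rng.integers(0, height)), int(rng.integers(0, width)))
        placement = Placement(anchor=anchor, shape=(h, w))
        if placement.bbox[2] > height or placement.bbox[3] > width:
            result.rejections["margin"] += 1
            continue
        decision = check_placement(placement, patch, organ, label, constraints)
        if decision.accepted:
            _paste(image, label, patch, anchor)
            result.placements.append(
                PlacementRecord(anchor=anchor, bbox=placement.bbox, **record_args)
            )
            return True
        result.rejections[decision.reason] += 1
    return False


def oversample(
    image: ArrayOrSlice,
    label: np.ndarray,
    organ: np.ndarray,
    m: int,
    rng: np.random.Generator,
    constraints: PlacementConstraints = PlacementConstraints(),
    retry_budget: int = DEFAULT_RETRY_BUDGET,
) -> AugmentationResult:
    """Plain within-image random oversampling.

    Pastes ``m`` untransformed copies of lesions drawn uniformly from
    the image's own lesion components at random accepted placements.
    Raises if the image contains no lesion.  Newly pasted lesions count
    as existing for subsequent overlap checks.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    pixels = as_pixels(image).copy()
    out_label = (np.asarray(label) > 0).astype(np.uint8)
    organ = np.asarray(organ, dtype=bool)
    if out_label.shape != pixels.shape or organ.shape != pixels.shape:
        raise ValueError("image, label and organ must be congruent")

    patches = extract_lesions(pixels, out_label)
    if not patches:
        raise ValueError("image contains no lesion to oversample")

    units = image.units if isinstance(image, ImageSlice) else "HU"
    result = AugmentationResult(
        image=ImageSlice(pixels, units=units), label=out_label, requested=m
    )
    for _ in range(m):
        idx = int(rng.integers(0, len(patches)))
        _place_patch(
            patches[idx], {"patch_index": idx}, pixels, out_label, organ,
            rng, constraints, result, retry_budget,
        )
    return result


def mof_augment(
    target_image: ArrayOrSlice,
    target_label: np.ndarray,
    organ: np.ndarray,
    lesion_bank: Sequence[LesionPatch],
    m: int,
    rng: np.random.Generator,
    constraints: PlacementConstraints = PlacementConstraints(),
    transform_ranges: TransformRanges = TransformRanges(),
    retry_budget: int = DEFAULT_RETRY_BUDGET,
) -> AugmentationResult:
    """Multiple-oversampling fusion augmentation of one target image.

    For each of the ``m`` pastes: draw a patch uniformly from
    ``lesion_bank``, rotate it by theta ~ Uniform(theta_range), rescale
    by omega ~ Uniform(omega_range), mirror about a uniformly chosen
    axis, then draw placements until :func:`check_placement` accepts or
    ``retry_budget`` draws are spent.  The random draw order per paste
    is fixed as (patch index, theta, omega, tau, placement draws) so a
    given seed reproduces the output bit for bit.

    The target's existing lesions are kept; the number of images is
    unchanged — only the lesion count and pixel fraction grow.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if not lesion_bank:
        raise ValueError("lesion bank is empty")
    pixels = as_pixels(target_image).copy()
    out_label = (np.asarray(target_label) > 0).astype(np.uint8)
    organ = np.asarray(organ, dtype=bool)
    if out_label.shape != pixels.shape or organ.shape != pixels.shape:
        raise ValueError("image, label and organ must be congruent")

    units = target_image.units if isinstance(target_image, ImageSlice) else "HU"
    result = AugmentationResult(
        image=ImageSlice(pixels, units=units), label=out_label, requested=m
    )
    for _ in range(m):
        idx = int(rng.integers(0, len(lesion_bank)))
        theta = float(rng.uniform(*transform_ranges.theta_range))
        omega = float(rng.uniform(*transform_ranges.omega_range))
        tau = "horizontal" if rng.integers(0, 2) == 0 else "vertical"
        do_mirror = (
            transform_ranges.mirror_probability >= 1.0
            or rng.random() < transform_ranges.mirror_probability
        )
        patch = enlarge(rotate(lesion_bank[idx], theta), omega)
        if do_mirror:
            patch = mirror(patch, tau)
        _place_patch(
            patch,
            {"patch_index": idx, "theta": theta, "omega": omega,
             "tau": tau if do_mirror else None},
            pixels, out_label, organ, rng, constraints, result, retry_budget,
        )
    return result
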