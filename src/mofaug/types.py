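"""Core value types shared across the package.

Conventions used everywhere in :mod:`mofaug`:

* pixel coordinates are 0-based ``(row, col)`` with the origin at the
  top-left of the image;
* intensity images are 2D ``float`` arrays, either in Hounsfield units
  (HU) or normalized to ``[0, 1]``;
* label masks are 2D integer arrays with ``0 = background`` and
  ``1 = lesion``; organ masks are 2D boolean arrays marking the
  admissible anatomical region (lung parenchyma, liver).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Union

import numpy as np

__all__ = [
    "HU_REFERENCE",
    "LUNG_WINDOW",
    "LIVER_WINDOW",
    "WindowSpec",
    "ImageSlice",
    "LesionPatch",
    "TransformRanges",
    "PlacementConstraints",
    "Placement",
    "as_pixels",
]

#: HU values of typical objects and organs on the CT attenuation scale
#: (water = 0, air = -1000).  Ranges are ``(low, high)`` tuples, open
#: bounds are encoded with +/- inf.
HU_REFERENCE: dict[str, tuple[float, float]] = {
    "bone": (400.0, math.inf),
    "blood": (7.0, 32.0),
    "liver": (40.0, 70.0),
    "water": (-5.0, 5.0),
    "air": (-1000.0, -1000.0),
}


@dataclass(frozen=True)
class WindowSpec:
    """A CT intensity window ``[lower, upper]`` in Hounsfield units.

    Windowing clips intensities to the interval and rescales it linearly
    to ``[0, 1]``, suppressing tissues outside the range of interest
    (bone, air).
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("window bounds must be finite")
        if not self.lower < self.upper:
            raise ValueError(
                f"degenerate window: lower ({self.lower}) must be < upper ({self.upper})"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


#: Default window for lung tissue.
LUNG_WINDOW = WindowSpec(-1000, 250)
#: Default window for liver tissue.
LIVER_WINDOW = WindowSpec(-100, 250)


@dataclass
class ImageSlice:
    """A 2D grayscale slice with its intensity units.

    ``units`` is ``"HU"`` for raw CT attenuation values or
    ``"normalized"`` for window-rescaled intensities in ``[0, 1]``.
    """

    pixels: np.ndarray
    units: Literal["HU", "normalized"] = "HU"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D slice, got ndim={self.pixels.ndim}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def copy(self) -> "ImageSlice":
        return replace(self, pixels=self.pixels.copy())


ArrayOrSlice = Union[np.ndarray, ImageSlice]


def as_pixels(image: ArrayOrSlice) -> np.ndarray:
    """Return the raw 2D pixel array of ``image`` (unwrapping ImageSlice)."""
    arr = image.pixels if isinstance(image, ImageSlice) else np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D image, got ndim={arr.ndim}")
    return arr


@dataclass
class LesionPatch:
    """One connected lesion component cut out of a source image.

    The patch is the unit of copy-paste augmentation: ``pixels`` carries
    the intensities over the component's bounding box, ``footprint``
    marks which of those pixels actually belong to the lesion, and
    ``source_bbox`` records ``(row0, col0, height, width)`` in source
    image coordinates.
    """

    pixels: np.ndarray
    footprint: np.ndarray
    source_bbox: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.footprint = np.asarray(self.footprint, dtype=bool)
        if self.pixels.shape != self.footprint.shape:
            raise ValueError(
                f"pixels {self.pixels.shape} and footprint "
                f"{self.footprint.shape} must be congruent"
            )
        if self.pixels.ndim != 2:
            raise ValueError("patch must be 2D")
        if not self.footprint.any():
            raise ValueError("footprint must contain at least one pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def area(self) -> int:
        """Number of lesion pixels in the footprint."""
        return int(self.footprint.sum())

    def copy(self) -> "LesionPatch":
        return LesionPatch(self.pixels.copy(), self.footprint.copy(), self.source_bbox)


@dataclass(frozen=True)
class TransformRanges:
    """Sampling ranges for the per-patch affine transform.

    Each pasted patch is rotated by ``theta ~ Uniform(theta_range)``,
    rescaled by ``omega ~ Uniform(omega_range)`` and mirrored about a
    uniformly chosen axis.  Defaults are rotation over ``(0, pi)`` and
    scale over ``(0.5, 2.0)``.
    """

    theta_range: tuple[float, float] = (0.0, math.pi)
    omega_range: tuple[float, float] = (0.5, 2.0)
    #: probability that the mirror step runs; the algorithm always
    #: mirrors, so the default is 1.0.
    mirror_probability: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mirror_probability <= 1.0:
            raise ValueError("mirror_probability must lie in [0, 1]")
        for name, (lo, hi) in (
            ("theta_range", self.theta_range),
            ("omega_range", self.omega_range),
        ):
            if not lo < hi:
                raise ValueError(f"{name} must be an increasing interval")


@dataclass(frozen=True)
class PlacementConstraints:
    """Rules a candidate paste position must satisfy.

    border_margin
        Minimum distance (pixels) between the pasted bounding box and
        every image edge; default 5.
    require_no_overlap
        Reject placements whose footprint touches an existing lesion.
    containment_mode
        ``"full_footprint"`` requires every footprint pixel to lie in
        the organ region; ``"anchor_only"`` only requires the top-left
        anchor to lie in the organ.
    min_separation
        Clearance (pixels) kept between a pasted footprint and existing
        lesions when checking overlap; 1 keeps distinct lesions
        8-disconnected so component counts stay additive, 0 allows
        touching.
    """

    border_margin: int = 5
    require_no_overlap: bool = True
    containment_mode: Literal["full_footprint", "anchor_only"] = "full_footprint"
    min_separation: int = 1

    def __post_init__(self) -> None:
        if self.border_margin < 0:
            raise ValueError("border_margin must be >= 0")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.containment_mode not in ("full_footprint", "anchor_only"):
            raise ValueError(f"unknown containment_mode {self.containment_mode!r}")


@dataclass(frozen=True)
class Placement:
    """A candidate paste position: ``anchor`` is the (row, col) of the
    patch's top-left corner; ``bbox`` is ``(row0, col0, row1, col1)``
    with exclusive end indices."""

    anchor: tuple[int, int]
    shape: tuple[int, int]

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        r0, c0 = self.anchor
        h, w = self.shape
        return (r0, c0, r0 + h, c0 + w)
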