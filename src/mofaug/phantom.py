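"""Synthetic CT-like phantoms with the small-lesion imbalance structure.

Each phantom is a single 2D slice in Hounsfield units: an elliptical
"organ" (soft-tissue HU, liver-like 40-70 by default) over an air
background (-1000 HU), containing a few small high-contrast disc
"lesions".  The geometry reproduces the class-imbalance regime the
augmentation method targets — lesions of radius 3-20 px in a 512 px
frame give background:lesion pixel ratios in the ~98:2 to ~89:11 range.

Lesion discs are placed by the same constraint system the augmentation
operators use: fully inside the organ, at least 5 px from the image
border, and non-overlapping (with 1 px clearance so components stay
separable).  Generation is deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .types import ImageSlice

__all__ = ["PhantomSpec", "PhantomError", "generate_phantom", "generate_corpus"]


class PhantomError(RuntimeError):
    """Raised when the requested lesions cannot be placed; carries the
    number of lesions that were placed before giving up."""

    def __init__(self, message: str, achieved: int):
        super().__init__(message)
        self.achieved = achieved


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    ``organ_center``/``organ_semiaxes`` default to a centred ellipse
    with semi-axes 0.38 and 0.32 of the image size.  HU defaults follow
    the CT attenuation scale: air background (-1000), liver-like organ
    (40-70), lesions offset +60 HU above the organ.
    """

    image_size: int = 512
    organ_center: tuple[float, float] | None = None
    organ_semiaxes: tuple[float, float] | None = None
    n_lesions: int = 3
    lesion_radius_range: tuple[float, float] = (3.0, 20.0)
    background_hu: float = -1000.0
    organ_hu: tuple[float, float] = (40.0, 70.0)
    lesion_hu_offset: float = 60.0
    noise_sd: float = 5.0
    border_margin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        lo, hi = self.lesion_radius_range
        if lo < 1 or hi < lo:
            raise ValueError("lesion radii must satisfy 1 <= lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def resolved_organ(self) -> tuple[tuple[float, float], tuple[float, float]]:
        s = self.image_size
        centre = self.organ_center or (s / 2.0, s / 2.0)
        axes = self.organ_semiaxes or (0.38 * s, 0.32 * s)
        return centre, axes


#: placement draws per lesion before generation fails
_LESION_RETRIES = 500


def _ellipse_mask(
    shape: tuple[int, int], centre: tuple[float, float], axes: tuple[float, float]
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - centre[0]) / axes[0]) ** 2 + ((cc - centre[1]) / axes[1]) ** 2 <= 1.0


def generate_phantom(
    spec: PhantomSpec = PhantomSpec(),
) -> tuple[ImageSlice, np.ndarray, np.ndarray]:
    """Generate one (image, organ mask, lesion label) triplet.

    Deterministic for a given spec (the seed is part of the spec).
    Raises :class:`PhantomError` when the requested number of lesions
    cannot be placed without violating the constraints.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    shape = (size, size)
    centre, axes = spec.resolved_organ()

    organ = _ellipse_mask(shape, centre, axes)
    lo, hi = spec.organ_hu
    image = np.full(shape, spec.background_hu, dtype=float)
    image[organ] = rng.uniform(lo, hi, size=int(organ.sum()))
    if spec.noise_sd > 0:
        image[organ] += rng.normal(0.0, spec.noise_sd, size=int(organ.sum()))
        image[organ] = np.clip(image[organ], lo, hi)

    label = np.zeros(shape, dtype=np.uint8)
    placed: list[tuple[float, float, float]] = []  # (row, col, radius)
    margin = spec.border_margin
    rr, cc = np.mgrid[0:size, 0:size]

    for i in range(spec.n_lesions):
        ok = False
        for _ in range(_LESION_RETRIES):
            radius = float(rng.uniform(*spec.lesion_radius_range))
            row = float(rng.uniform(0, size))
            col = float(rng.uniform(0, size))
            # keep the full disc >= margin px from the borders
            if not (
                margin + radius <= row <= size - 1 - margin - radius
                and margin + radius <= col <= size - 1 - margin - radius
            ):
                continue
            # full containment in the organ ellipse
            disc = (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
            if not organ[disc].all():
                continue
            # >= 1 px clearance from every existing lesion
            if any(
                np.hypot(row - r0, col - c0) <= radius + rad0 + 2.0
                for r0, c0, rad0 in placed
            ):
                continue
            lesion_hu = (
                rng.uniform(lo, hi) + spec.lesion_hu_offset
                + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
            )
            lesion_hu = float(
                np.clip(lesion_hu, lo + spec.lesion_hu_offset, hi + spec.lesion_hu_offset)
            )
            image[disc] = lesion_hu
            label[disc] = 1
            placed.append((row, col, radius))
            ok = True
            break
        if not ok:
            raise PhantomError(
                f"could not place lesion {i + 1} of {spec.n_lesions} "
                f"after {_LESION_RETRIES} draws",
                achieved=len(placed),
            )

    return ImageSlice(image, units="HU"), organ, label


def generate_corpus(
    n_images: int,
    out_dir: str | Path,
    spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    fmt: str = "png",
) -> dict:
    """Write ``n_images`` phantom triplets plus a JSON manifest.

    Per-image seeds are derived from the master ``seed``; the manifest
    records every parameter so the corpus is reproducible from it
    alone.  Returns the manifest dict.
    """
    from . import io as mio

    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    child_seeds = np.random.SeedSequence(seed).generate_state(n_images) % (2**31)
    entries = []
    for i in range(n_images):
        item_spec = replace(spec, seed=int(child_seeds[i]))
        image, organ, label = generate_phantom(item_spec)
        stem = f"phantom_{i:04d}"
        paths = {
            "image": f"{stem}_image.{fmt}",
            "organ": f"{stem}_organ.{fmt}",
            "label": f"{stem}_label.{fmt}",
        }
        mio.write_slice(out_dir / paths["image"], image)
        mio.write_mask(out_dir / paths["organ"], organ)
        mio.write_mask(out_dir / paths["label"], label)
        entries.append(
            {
                "index": i,
                "seed": int(child_seeds[i]),
                "n_lesions": int(spec.n_lesions),
                "lesion_pixels": int(label.sum()),
                **paths,
            }
        )

    manifest = {
        "kind": "mofaug-phantom-corpus",
        "n_images": n_images,
        "seed": int(seed),
        "format": fmt,
        "spec": {
            "image_size": spec.image_size,
            "n_lesions": spec.n_lesions,
            "lesion_radius_range": list(spec.lesion_radius_range),
            "background_hu": spec.background_hu,
            "organ_hu": list(spec.organ_hu),
            "lesion_hu_offset": spec.lesion_hu_offset,
            "noise_sd": spec.noise_sd,
            "border_margin": spec.border_margin,
        },
        "items": entries,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
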