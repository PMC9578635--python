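"""HU windowing and organ-centred cropping of raw CT slices.

The preprocessing chain turns a raw Hounsfield-unit slice plus its organ
mask into a clean, normalized, organ-centred square input:

1. clip intensities to a tissue window and rescale linearly to [0, 1]
   (:func:`window_and_normalize`);
2. crop the smallest axis-aligned square that contains the organ's
   bounding box and resize it to a fixed side, default 512
   (:func:`crop_to_organ`).

Masks always travel through the identical geometric transform with
nearest-neighbour resampling so they stay binary.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .types import ArrayOrSlice, ImageSlice, WindowSpec, as_pixels

__all__ = ["window_and_normalize", "crop_to_organ", "preprocess_slice"]


def window_and_normalize(image: ArrayOrSlice, window: WindowSpec) -> ImageSlice:
    """Clip ``image`` to ``window`` and rescale linearly to [0, 1].

    ``window.lower`` maps to 0 and ``window.upper`` to 1; values outside
    the window saturate.  The mapping is monotone and idempotent on data
    already windowed to the same interval.

    Parameters
    ----------
    image
        2D slice in Hounsfield units.
    window
        The HU interval to keep, e.g. ``LUNG_WINDOW`` (-1000, 250).

    Returns
    -------
    ImageSlice
        A normalized slice with every pixel in [0, 1].
    """
    pixels = as_pixels(image)
    if isinstance(image, ImageSlice) and image.units != "HU":
        raise ValueError("window_and_normalize expects a slice in HU units")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("image contains non-finite pixels")
    clipped = np.clip(pixels, window.lower, window.upper)
    out = (clipped - window.lower) / window.width
    return ImageSlice(out, units="normalized")


def _organ_bbox(organ: np.ndarray) -> tuple[int, int, int, int]:
    """Inclusive-exclusive bounding box (r0, c0, r1, c1) of a binary mask."""
    rows = np.flatnonzero(organ.any(axis=1))
    cols = np.flatnonzero(organ.any(axis=0))
    return rows[0], cols[0], rows[-1] + 1, cols[-1] + 1


def _square_window(
    r0: int, c0: int, r1: int, c1: int, height: int, width: int
) -> tuple[int, int, int, int, int]:
    """Centre the smallest square over the bbox, clamped to image bounds.

    Returns (row0, col0, side, pad_before_r, pad_before_c); pads are the
    symmetric padding needed on each axis when the side exceeds the
    image extent.
    """
    side = max(r1 - r0, c1 - c0)

    def _axis(lo: int, hi: int, extent: int) -> tuple[int, int]:
        centre = (lo + hi) / 2.0
        start = int(round(centre - side / 2.0))
        if side <= extent:
            start = min(max(start, 0), extent - side)
            return start, 0
        pad = (side - extent + 1) // 2
        return -pad, pad

    row0, pad_r = _axis(r0, r1, height)
    col0, pad_c = _axis(c0, c1, width)
    return row0, col0, side, pad_r, pad_c


def crop_to_organ(
    image: ArrayOrSlice,
    organ: np.ndarray,
    out_size: int = 512,
) -> tuple[ImageSlice, np.ndarray]:
    """Crop the smallest external square around the organ and resize.

    The square contains the organ's bounding box; when it would exceed
    the image bounds it is clamped and the missing rows/columns are
    padded symmetrically with the image minimum.  Intensities are
    resampled bilinearly, the organ mask with nearest neighbour so it
    stays binary.

    Returns
    -------
    (ImageSlice, ndarray)
        The ``out_size`` x ``out_size`` crop and the congruent organ mask.
    """
    pixels = as_pixels(image)
    organ = np.asarray(organ, dtype=bool)
    if organ.shape != pixels.shape:
        raise ValueError(
            f"organ mask {organ.shape} not congruent with image {pixels.shape}"
        )
    if not organ.any():
        raise ValueError("organ mask is empty")
    if out_size < 1:
        raise ValueError("out_size must be >= 1")

    height, width = pixels.shape
    r0, c0, r1, c1 = _organ_bbox(organ)
    row0, col0, side, pad_r, pad_c = _square_window(r0, c0, r1, c1, height, width)

    fill = float(pixels.min())
    if pad_r or pad_c:
        pixels = np.pad(
            pixels, ((pad_r, side), (pad_c, side)), mode="constant", constant_values=fill
        )
        organ = np.pad(
            organ, ((pad_r, side), (pad_c, side)), mode="constant", constant_values=False
        )
        row0 += pad_r
        col0 += pad_c

    crop = pixels[row0 : row0 + side, col0 : col0 + side]
    crop_mask = organ[row0 : row0 + side, col0 : col0 + side]

    out = resize(
        crop, (out_size, out_size), order=1, mode="edge",
        anti_aliasing=side > out_size, preserve_range=True,
    )
    out_mask = resize(
        crop_mask.astype(float), (out_size, out_size), order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    ) > 0.5

    units = image.units if isinstance(image, ImageSlice) else "HU"
    return ImageSlice(out, units=units), out_mask


def preprocess_slice(
    image: ArrayOrSlice,
    organ: np.ndarray,
    window: WindowSpec,
    out_size: int = 512,
    label: np.ndarray | None = None,
) -> tuple[ImageSlice, np.ndarray, np.ndarray | None]:
    """Full preprocessing: window -> organ-centred square crop -> resize.

    The crop is computed once from the organ mask and applied to the
    image, the organ mask, and (if given) the lesion label mask, so all
    three stay co-registered.  The label mask is resampled with nearest
    neighbour.
    """
    normalized = window_and_normalize(image, window)
    pixels = normalized.pixels
    organ_arr = np.asarray(organ, dtype=bool)
    if not organ_arr.any():
        raise ValueError("organ mask is empty")
    if organ_arr.shape != pixels.shape:
        raise ValueError("organ mask not congruent with image")

    height, width = pixels.shape
    r0, c0, r1, c1 = _organ_bbox(organ_arr)
    row0, col0, side, pad_r, pad_c = _square_window(r0, c0, r1, c1, height, width)

    def _crop_resize(arr: np.ndarray, order: int, fill: float) -> np.ndarray:
        if pad_r or pad_c:
            arr = np.pad(
                arr.astype(float), ((pad_r, side), (pad_c, side)),
                mode="constant", constant_values=fill,
            )
        else:
            arr = arr.astype(float)
        rr = row0 + pad_r
        cc = col0 + pad_c
        sub = arr[rr : rr + side, cc : cc + side]
        return resize(
            sub, (out_size, out_size), order=order, mode="edge",
            anti_aliasing=(order > 0 and side > out_size), preserve_range=True,
        )

    out_img = ImageSlice(_crop_resize(pixels, 1, float(pixels.min())), units="normalized")
    out_organ = _crop_resize(organ_arr, 0, 0.0) > 0.5
    out_label = None
    if label is not None:
        label_arr = np.asarray(label)
        if label_arr.shape != (height, width):
            raise ValueError("label mask not congruent with image")
        out_label = (_crop_resize(label_arr > 0, 0, 0.0) > 0.5).astype(np.uint8)
    return out_img, out_organ, out_label
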