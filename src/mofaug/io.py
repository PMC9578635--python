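"""Reading and writing slices and masks in the common CT dialects.

Supported formats, dispatched on file extension:

* ``.nii`` / ``.nii.gz`` — NIfTI via nibabel (float32 slices, uint8
  masks);
* ``.mhd`` / ``.mha`` — MetaImage via SimpleITK (the LUNA16 dialect);
* ``.tif`` / ``.tiff`` — 32-bit float TIFF via tifffile, HU values
  stored verbatim;
* ``.png`` — 16-bit unsigned PNG via imageio.  PNG cannot hold negative
  HU values, so slices are stored with a fixed +1024 offset (the common
  CT convention, air -1000 -> 24); normalized slices are stored scaled
  by 65535.  Masks are 8-bit with 0/255.

A slice extractor pulls a single z-plane out of a 3D volume so 3D
NIfTI/MetaImage datasets can feed the 2D pipeline.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .types import ImageSlice

__all__ = [
    "read_slice",
    "write_slice",
    "read_mask",
    "write_mask",
    "extract_slice",
]

#: additive offset used to store HU in unsigned 16-bit PNG
PNG_HU_OFFSET = 1024


def _fmt(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    suffix = path.suffix.lower()
    if suffix in (".mhd", ".mha"):
        return "meta"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix == ".png":
        return "png"
    raise ValueError(f"unsupported file format: {path.name}")


def write_slice(path: str | Path, image: ImageSlice) -> None:
    """Write a 2D slice; the on-disk encoding depends on the extension."""
    path = Path(path)
    fmt = _fmt(path)
    pixels = image.pixels
    if fmt == "nifti":
        import nibabel as nib

        nib.save(nib.Nifti1Image(pixels.astype(np.float32), affine=np.eye(4)), path)
    elif fmt == "meta":
        import SimpleITK as sitk

        sitk.WriteImage(sitk.GetImageFromArray(pixels.astype(np.float32)), str(path))
    elif fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, pixels.astype(np.float32))
    else:  # png, 16-bit
        import imageio.v3 as iio

        if image.units == "normalized":
            data = np.clip(pixels, 0.0, 1.0) * 65535.0
        else:
            data = pixels + PNG_HU_OFFSET
        data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
        iio.imwrite(path, data)


def read_slice(path: str | Path, units: str = "HU") -> ImageSlice:
    """Read a 2D slice; ``units`` declares how to interpret the values
    (it selects the inverse PNG encoding and is recorded on the result)."""
    path = Path(path)
    fmt = _fmt(path)
    if fmt == "nifti":
        import nibabel as nib

        pixels = np.asanyarray(nib.load(path).dataobj).astype(float)
    elif fmt == "meta":
        import SimpleITK as sitk

        pixels = sitk.GetArrayFromImage(sitk.ReadImage(str(path))).astype(float)
    elif fmt == "tiff":
        import tifffile

        pixels = tifffile.imread(path).astype(float)
    else:
        import imageio.v3 as iio

        raw = iio.imread(path).astype(float)
        pixels = raw / 65535.0 if units == "normalized" else raw - PNG_HU_OFFSET
    pixels = np.squeeze(pixels)
    if pixels.ndim != 2:
        raise ValueError(f"{path.name} does not hold a single 2D slice")
    return ImageSlice(pixels, units=units)  # type: ignore[arg-type]


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask (organ region or lesion label) as 0/1."""
    path = Path(path)
    fmt = _fmt(path)
    data = (np.asarray(mask) > 0).astype(np.uint8)
    if fmt == "nifti":
        import nibabel as nib

        nib.save(nib.Nifti1Image(data, affine=np.eye(4)), path)
    elif fmt == "meta":
        import SimpleITK as sitk

        sitk.WriteImage(sitk.GetImageFromArray(data), str(path))
    elif fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data * np.uint8(255))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask; any nonzero value counts as foreground."""
    path = Path(path)
    fmt = _fmt(path)
    if fmt == "nifti":
        import nibabel as nib

        data = np.asanyarray(nib.load(path).dataobj)
    elif fmt == "meta":
        import SimpleITK as sitk

        data = sitk.GetArrayFromImage(sitk.ReadImage(str(path)))
    elif fmt == "tiff":
        import tifffile

        data = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        data = iio.imread(path)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ValueError(f"{path.name} does not hold a single 2D mask")
    return (data > 0).astype(np.uint8)


def extract_slice(volume_path: str | Path, z: int, units: str = "HU") -> ImageSlice:
    """Pull the z-th axial plane from a 3D NIfTI or MetaImage volume."""
    path = Path(volume_path)
    fmt = _fmt(path)
    if fmt == "nifti":
        import nibabel as nib

        vol = np.asanyarray(nib.load(path).dataobj).astype(float)
        if vol.ndim != 3:
            raise ValueError(f"{path.name} is not a 3D volume")
        # nibabel axes are (x, y, z)
        plane = vol[:, :, z]
    elif fmt == "meta":
        import SimpleITK as sitk

        vol = sitk.GetArrayFromImage(sitk.ReadImage(str(path))).astype(float)
        if vol.ndim != 3:
            raise ValueError(f"{path.name} is not a 3D volume")
        # SimpleITK arrays are (z, y, x)
        plane = vol[z]
    else:
        raise ValueError("slice extraction needs a 3D NIfTI or MetaImage volume")
    return ImageSlice(plane, units=units)  # type: ignore[arg-type]
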