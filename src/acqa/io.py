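"""Reading and writing image lattices.

MetaImage (``.mha``/``.mhd``) and NIfTI (``.nii``/``.nii.gz``) go through
SimpleITK; DICOM CT series are read with SimpleITK's series reader, which
applies RescaleSlope/RescaleIntercept so voxel values come back in HU.
Masks are stored as 8-bit 0/1 label images.

SimpleITK orders spacing/origin as (x, y, z); our lattices are (z, y, x),
so metadata tuples are reversed at the boundary.
"""

from __future__ import annotations

import os

import numpy as np
import SimpleITK as sitk

from .grids import DoseGrid, ImageGrid, StructureMask

__all__ = ["write_image", "read_image", "read_mask", "read_dose", "read_dicom_series"]

_EXTENSIONS = (".mha", ".mhd", ".nii", ".nii.gz")


def _check_extension(path: str) -> None:
    low = str(path).lower()
    if not low.endswith(_EXTENSIONS):
        raise ValueError(
            f"unsupported image extension for {path!r}; expected one of {_EXTENSIONS}"
        )


def _to_sitk(obj) -> sitk.Image:
    if isinstance(obj, StructureMask):
        arr = obj.values.astype(np.uint8)
    elif isinstance(obj, DoseGrid):
        arr = obj.values.astype(np.float64)
    else:
        arr = np.asarray(obj.values)
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.int16)
        else:
            arr = arr.astype(np.float64)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(reversed(obj.spacing)))
    img.SetOrigin(tuple(reversed(obj.origin)))
    return img


def write_image(obj, path: str) -> None:
    """Write an ImageGrid / StructureMask / DoseGrid to .mha or NIfTI."""
    _check_extension(path)
    sitk.WriteImage(_to_sitk(obj), str(path), useCompression=False)


def _from_sitk(img: sitk.Image):
    arr = sitk.GetArrayFromImage(img)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return arr, spacing, origin


def read_image(path: str) -> ImageGrid:
    """Read an HU image; DICOM directories go through read_dicom_series."""
    if os.path.isdir(path):
        return read_dicom_series(path)
    _check_extension(path)
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return ImageGrid(values=arr, spacing=spacing, origin=origin)


def read_mask(path: str, label: str = "") -> StructureMask:
    _check_extension(path)
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return StructureMask(values=arr > 0, spacing=spacing, origin=origin, label=label)


def read_dose(path: str) -> DoseGrid:
    _check_extension(path)
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return DoseGrid(values=arr, spacing=spacing, origin=origin)


def read_dicom_series(directory: str) -> ImageGrid:
    """Read a DICOM CT series directory as one HU volume.

    Slice geometry (pixel spacing, inter-slice distance) must be uniform
    across the series; SimpleITK applies the rescale slope/intercept so the
    returned values are Hounsfield units.
    """
    reader = sitk.ImageSeriesReader()
    file_names = reader.GetGDCMSeriesFileNames(str(directory))
    if not file_names:
        raise ValueError(f"no DICOM series found in {directory!r}")
    reader.SetFileNames(file_names)
    img = reader.Execute()
    arr, spacing, origin = _from_sitk(img)
    return ImageGrid(values=arr, spacing=spacing, origin=origin)
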