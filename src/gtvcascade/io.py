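"""Reading and writing volumes and masks.

NIfTI (``.nii`` / ``.nii.gz``) is the working format for volumes, masks and
score maps; DICOM series directories are supported read-only for CT input.
Geometry is kept deliberately simple: spacing and origin are honoured,
direction cosines beyond axis-aligned grids are not (planning CT exported for
this pipeline is axis-aligned).
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import BinaryMask, ImageVolume

__all__ = ["read_volume", "read_mask", "write_volume"]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        # channels stored as the 4th NIfTI dimension -> channel-first
        data = np.moveaxis(data, -1, 0)
    elif data.ndim != 3:
        raise ValueError(f"non-3D input: {path} has {data.ndim} dimensions")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return data, spacing, origin


def _read_dicom_series(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(path))
    if not files:
        raise ValueError(f"no DICOM series found in {path}")
    reader.SetFileNames(files)
    img = reader.Execute()
    # SimpleITK arrays come back (z, y, x); restore in-plane-first layout
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0)).astype(np.float32)
    spacing = tuple(float(s) for s in img.GetSpacing())
    origin = tuple(float(o) for o in img.GetOrigin())
    return data, spacing, origin


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    Returns an :class:`ImageVolume` with spacing/origin taken from the file
    header, in-plane axes first and the slice axis last.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        data, spacing, origin = _read_dicom_series(path)
    else:
        data, spacing, origin = _read_nifti(path)
    return ImageVolume(np.ascontiguousarray(data, dtype=np.float32), spacing, origin)


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a binary mask (ground truth or prediction) from NIfTI."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data, spacing, origin = _read_nifti(path)
    if data.ndim == 4:
        if data.shape[0] != 1:
            raise ValueError("masks must be single-channel")
        data = data[0]
    return BinaryMask(np.rint(data).astype(np.uint8), spacing, origin)


def write_volume(v: ImageVolume | BinaryMask, path: str | os.PathLike) -> None:
    """Write a volume or mask as NIfTI; spacing/origin go into the header."""
    path = Path(path)
    if isinstance(v, BinaryMask):
        data = v.data.astype(np.uint8)
    elif isinstance(v, ImageVolume):
        if not np.isfinite(v.data).all():
            raise ValueError("refusing to write non-finite values")
        data = v.first_channel if v.channels == 1 else np.moveaxis(v.data, 0, -1)
        data = np.asarray(data, dtype=np.float32)
    else:
        raise TypeError(f"cannot write object of type {type(v).__name__}")
    img = nib.Nifti1Image(data, _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing + (1.0,) * (data.ndim - 3))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
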