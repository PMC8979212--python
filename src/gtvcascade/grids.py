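"""Volumetric data containers.

Axial CT volumes are held channel-first as ``(C, nx, ny, nz)`` arrays with the
in-plane axes first and the cranio-caudal (slice) axis last, so a clinical
"512 x 512" axial matrix maps to the first two array axes.  Voxel indexing is
0-based and every crop in the package uses half-open intervals
``[start, start + size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ImageVolume", "BinaryMask"]


def _validate_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive numbers, got {spacing!r}")
    return spacing


@dataclass
class ImageVolume:
    """A 3D scalar grid (HU or normalized intensity) with physical geometry.

    Parameters
    ----------
    data:
        ``(C, nx, ny, nz)`` float array; ``C`` is 1 (plain CT) or 2 (plain CT
        plus a co-registered contrast-enhanced channel on the same grid).
    spacing:
        ``(sx, sy, sz)`` voxel size in mm, strictly positive.
    origin:
        Physical coordinates of voxel ``(0, 0, 0)``.
    meta:
        Free-form provenance (crop offsets, original grid shape, ...);
        carried along by the pipeline, never interpreted by the containers.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"volume data must be 3D or (C, x, y, z), got ndim={self.data.ndim}")
        if self.data.shape[0] not in (1, 2):
            raise ValueError(f"expected 1 or 2 channels, got {self.data.shape[0]}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")
        self.spacing = _validate_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial grid shape (nx, ny, nz)."""
        return self.data.shape[1:]

    @property
    def first_channel(self) -> np.ndarray:
        """The plain-CT channel as a bare (nx, ny, nz) array."""
        return self.data[0]

    def with_data(self, data: np.ndarray, spacing=None) -> "ImageVolume":
        return ImageVolume(
            data,
            spacing=self.spacing if spacing is None else spacing,
            origin=self.origin,
            meta=dict(self.meta),
        )


@dataclass
class BinaryMask:
    """A {0,1} grid aligned to an :class:`ImageVolume` grid.

    Used for body masks, ground-truth tumor delineations ``G`` and automatic
    delineations ``A``; values other than 0/1 are rejected.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={arr.ndim}")
        values = np.unique(arr)
        if not np.isin(values, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0, 1}}, found {values[:5]!r}")
        self.data = arr.astype(np.uint8)
        self.spacing = _validate_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def same_grid_as(self, other) -> bool:
        return self.shape == tuple(other.shape) and np.allclose(self.spacing, other.spacing)
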