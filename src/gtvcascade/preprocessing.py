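"""CT preprocessing: bed removal, body mask, neck localization, cropping,
resampling and foreground-based intensity normalization.

The pipeline order is: extract the body mask (Hough line removal of the bed
rails, HU thresholding, morphological closing, largest component, hole
filling) -> locate the neck as the minimum of the smoothed per-slice body
area profile -> crop to the volume above the neck, tightened in-plane to the
body bounding box -> resample to the target spacing (third-order spline for
intensities, nearest-neighbour for masks) -> z-score with a single global
foreground mean/std pooled over the training cohort's body voxels.
Cropping precedes resampling; the crop provenance (offsets, original grid)
is recorded on the outputs so predictions can be restored to the original
512 x 512 x N canvas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import probabilistic_hough_line

from .grids import BinaryMask, ImageVolume

__all__ = [
    "ForegroundStats", "EmptyBodyError", "NoNeckError",
    "extract_body_mask", "find_neck_index", "crop_above_neck",
    "resample", "compute_foreground_stats", "normalize", "preprocess_case",
]


class EmptyBodyError(ValueError):
    """No above-threshold voxels: the volume contains no body."""


class NoNeckError(ValueError):
    """The per-slice area profile has no interior minimum."""


@dataclass(frozen=True)
class ForegroundStats:
    """Global intensity statistics over body voxels, per channel."""

    mean: tuple[float, ...]
    std: tuple[float, ...]
    n_voxels: int

    def __post_init__(self):
        if any(s <= 0 for s in self.std):
            raise ValueError("degenerate std: foreground intensities are constant")

    def to_dict(self) -> dict:
        return {"mean": list(self.mean), "std": list(self.std), "n_voxels": self.n_voxels}

    @classmethod
    def from_dict(cls, d: dict) -> "ForegroundStats":
        return cls(tuple(d["mean"]), tuple(d["std"]), int(d["n_voxels"]))


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    g = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (g[0] ** 2 + g[1] ** 2 + g[2] ** 2) <= r**2


def _detect_bed_lines(fg: np.ndarray, min_len_frac: float = 0.4) -> np.ndarray:
    """Erasure mask for straight high-intensity rails.

    Runs probabilistic Hough line detection on per-slice axial edge maps
    (subsampled slices; rails are coherent along the slice axis) and keeps
    lines longer than ``min_len_frac`` of the field of view that lie outside
    the largest connected component.
    """
    nx, ny, nz = fg.shape
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        body_label = int(np.argmax(sizes)) + 1
    else:
        body_label = 1
    non_body = fg & (labels != body_label) if n > 1 else np.zeros_like(fg)

    erase2d = np.zeros((nx, ny), dtype=bool)
    min_len = min_len_frac * min(nx, ny)
    step = max(1, nz // 8)
    for k in range(0, nz, step):
        sl = non_body[:, :, k]
        if not sl.any():
            continue
        lines = probabilistic_hough_line(sl, threshold=10,
                                         line_length=int(min_len), line_gap=3)
        for (c0, r0), (c1, r1) in lines:  # skimage returns (col, row) pairs
            length = np.hypot(r1 - r0, c1 - c0)
            if length < min_len:
                continue
            npts = int(length) * 2 + 1
            rr = np.clip(np.round(np.linspace(r0, r1, npts)).astype(int), 0, nx - 1)
            cc = np.clip(np.round(np.linspace(c0, c1, npts)).astype(int), 0, ny - 1)
            erase2d[rr, cc] = True
    if erase2d.any():
        erase2d = ndimage.binary_dilation(erase2d, iterations=2)
    return erase2d[:, :, None] & non_body


def extract_body_mask(v: ImageVolume, hu_threshold: float = -300.0,
                      closing_radius: int = 3) -> BinaryMask:
    """Body mask from the plain-CT channel.

    Bed rails detected as straight lines are erased first; the remaining
    above-threshold voxels are morphologically closed, the largest connected
    component is kept and its holes are filled.
    """
    fg = v.first_channel > hu_threshold
    if not fg.any():
        raise EmptyBodyError("empty body: no voxels above the HU threshold")
    fg = fg & ~_detect_bed_lines(fg)
    r = int(closing_radius)
    padded = np.pad(fg, r, mode="edge")  # keep closing neutral at the borders
    fg = ndimage.binary_closing(padded, structure=_ball(r))[r:-r, r:-r, r:-r]
    labels, n = ndimage.label(fg)
    if n == 0:
        raise EmptyBodyError("empty body after morphology")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    fg = ndimage.binary_fill_holes(fg)
    mask = BinaryMask(fg.astype(np.uint8), v.spacing, v.origin, meta=dict(v.meta))
    mask.meta["role"] = "body"
    return mask


def _smoothed_area_profile(m: BinaryMask, window: int = 5) -> np.ndarray:
    area = m.data.sum(axis=(0, 1)).astype(float)
    kernel = np.ones(window) / window
    return np.convolve(area, kernel, mode="same")


def find_neck_index(m: BinaryMask, smooth_window: int = 5) -> int:
    """Slice index of the neck: the interior minimum of the smoothed
    per-slice body area along the cranio-caudal axis.

    The search runs strictly between the shoulder-driven area maximum on the
    caudal side and the head apex (the top 10% of occupied slices is
    excluded, where the profile necessarily collapses).
    """
    area = m.data.sum(axis=(0, 1)).astype(float)
    occupied = np.nonzero(area > 0)[0]
    if occupied.size < 3:
        raise NoNeckError("mask must be nonempty on at least 3 slices")
    first, apex = int(occupied[0]), int(occupied[-1])
    profile = _smoothed_area_profile(m, smooth_window)

    upper = apex - max(1, round(0.10 * (apex - first + 1)))
    caudal_end = first + max(1, (apex - first) // 2)
    shoulder_idx = first + int(np.argmax(profile[first:caudal_end + 1]))
    lo, hi = shoulder_idx + 1, upper
    if hi <= lo:
        raise NoNeckError("no neck found: search window is empty")

    seg = profile[lo:hi + 1]
    neck = lo + int(np.argmin(seg))
    cranial_max = profile[neck:hi + 1].max()
    tol = 1e-9 + 0.02 * profile[shoulder_idx]
    if profile[neck] > profile[shoulder_idx] - tol or profile[neck] > cranial_max - tol:
        raise NoNeckError("no neck found: area profile has no interior minimum")
    return neck


def crop_above_neck(v: ImageVolume, m: BinaryMask, neck_index: int
                    ) -> tuple[ImageVolume, BinaryMask]:
    """Keep slices from the neck to the head apex, tightened in-plane to the
    body bounding box; crop provenance goes into ``meta``."""
    nz = v.shape[2]
    if not 0 <= neck_index < nz:
        raise ValueError(f"neck_index {neck_index} outside [0, {nz})")
    sub = m.data[:, :, neck_index:]
    occupied = np.nonzero(sub.sum(axis=(0, 1)))[0]
    if occupied.size == 0:
        raise ValueError("no body voxels above the neck")
    apex = neck_index + int(occupied[-1])
    region = m.data[:, :, neck_index:apex + 1]
    x_idx = np.nonzero(region.any(axis=(1, 2)))[0]
    y_idx = np.nonzero(region.any(axis=(0, 2)))[0]
    x0, x1 = int(x_idx[0]), int(x_idx[-1]) + 1
    y0, y1 = int(y_idx[0]), int(y_idx[-1]) + 1

    prov = {
        "crop_offset": (x0, y0, neck_index),
        "cropped_shape": (x1 - x0, y1 - y0, apex + 1 - neck_index),
        "original_shape": tuple(v.shape),
        "original_spacing": tuple(v.spacing),
    }
    vol = ImageVolume(v.data[:, x0:x1, y0:y1, neck_index:apex + 1].copy(),
                      v.spacing, v.origin, meta={**v.meta, **prov})
    mask = BinaryMask(m.data[x0:x1, y0:y1, neck_index:apex + 1].copy(),
                      m.spacing, m.origin, meta={**m.meta, **prov})
    return vol, mask


def resample(v: ImageVolume | BinaryMask,
             target_spacing: Sequence[float]) -> ImageVolume | BinaryMask:
    """Resample to ``target_spacing`` (mm): third-order spline for intensity
    volumes, nearest-neighbour for masks; output spacing is exactly the
    target and the physical extent is preserved to within one voxel."""
    target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    zoom = tuple(s / t for s, t in zip(v.spacing, target))
    if np.allclose(zoom, 1.0, rtol=0, atol=1e-12):
        out = v.__class__(v.data.copy(), target, v.origin, meta=dict(v.meta))
        return out
    if isinstance(v, BinaryMask):
        data = ndimage.zoom(v.data, zoom, order=0, mode="nearest", grid_mode=True)
        return BinaryMask(data, target, v.origin, meta=dict(v.meta))
    chans = [ndimage.zoom(v.data[c], zoom, order=3, mode="nearest", grid_mode=True)
             for c in range(v.channels)]
    return ImageVolume(np.stack(chans).astype(np.float32), target, v.origin,
                       meta=dict(v.meta))


def compute_foreground_stats(volumes: Iterable[ImageVolume],
                             masks: Iterable[BinaryMask]) -> ForegroundStats:
    """Pooled per-channel mean/std over the body voxels of all volumes.

    One global pair for the whole training cohort, not per-case statistics;
    frozen at training time and reused verbatim at inference.
    """
    sums = None
    sqsums = None
    n = 0
    n_channels = None
    for vol, mask in zip(volumes, masks):
        if tuple(mask.shape) != tuple(vol.shape):
            raise ValueError("volume/mask grid mismatch")
        sel = mask.data.astype(bool)
        k = int(sel.sum())
        if k == 0:
            continue
        vals = vol.data[:, sel].astype(np.float64)
        if sums is None:
            n_channels = vol.channels
            sums = np.zeros(n_channels)
            sqsums = np.zeros(n_channels)
        sums += vals.sum(axis=1)
        sqsums += (vals**2).sum(axis=1)
        n += k
    if n == 0:
        raise EmptyBodyError("zero foreground voxels across the cohort")
    mean = sums / n
    var = sqsums / n - mean**2
    std = np.sqrt(np.maximum(var, 0.0))
    return ForegroundStats(tuple(mean.tolist()), tuple(std.tolist()), n)


def normalize(v: ImageVolume, stats: ForegroundStats) -> ImageVolume:
    """Voxelwise ``(x - mean) / std`` per channel."""
    if len(stats.mean) != v.channels:
        raise ValueError("stats channel count does not match volume")
    mean = np.asarray(stats.mean, dtype=np.float64)[:, None, None, None]
    std = np.asarray(stats.std, dtype=np.float64)[:, None, None, None]
    data = ((v.data - mean) / std).astype(np.float32)
    out = ImageVolume(data, v.spacing, v.origin, meta=dict(v.meta))
    out.meta["normalized"] = True
    return out


def preprocess_case(v: ImageVolume, target_spacing: Sequence[float],
                    hu_threshold: float = -300.0,
                    gt: BinaryMask | None = None,
                    ) -> tuple[ImageVolume, BinaryMask, BinaryMask | None]:
    """Body mask -> neck crop -> resample, without normalization.

    Returns ``(cropped+resampled volume, body mask, resampled gt or None)``;
    normalization is applied separately once cohort statistics exist.
    """
    body = extract_body_mask(v, hu_threshold)
    neck = find_neck_index(body)
    vol_c, body_c = crop_above_neck(v, body, neck)
    gt_c = None
    if gt is not None:
        prov = {k: vol_c.meta[k] for k in ("crop_offset", "original_shape", "original_spacing")}
        x0, y0, z0 = prov["crop_offset"]
        nx, ny, nz = vol_c.shape
        gt_c = BinaryMask(gt.data[x0:x0 + nx, y0:y0 + ny, z0:z0 + nz].copy(),
                          gt.spacing, gt.origin, meta={**gt.meta, **prov})
        gt_c = resample(gt_c, target_spacing)
    vol_r = resample(vol_c, target_spacing)
    body_r = resample(body_c, target_spacing)
    return vol_r, body_r, gt_c
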