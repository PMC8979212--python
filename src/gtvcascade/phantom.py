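"""Seeded synthetic head-and-neck CT phantoms with ground-truth tumors.

Each phantom emulates the features of a planning CT that the pipeline's
assumptions rest on: air background around -1000 HU; a body (soft tissue
around 0 HU) built from a shoulder slab, a waisted neck cylinder whose
narrowest slice is the configured neck position, and a head modelled as a
sphere in physical mm (an ellipsoid in voxels on the anisotropic grid); a
treatment bed rendered as two straight high-intensity rails posterior to the
body; and a soft-edged ellipsoidal tumor inside the head whose per-case size
draw mimics stage-like spread and whose low boundary contrast is the
segmentation difficulty.  Additive Gaussian noise tops the composite.

The tumor intensity profile is monotone in the normalized ellipsoid radius
(a logistic ramp), so the ground truth -- the ellipsoid interior -- is
exactly the super-level set above half-contrast; boundary softness controls
how quickly contrast decays across that surface, not where it sits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .grids import BinaryMask, ImageVolume

__all__ = ["PhantomSpec", "PhantomCase", "generate_case", "generate_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of one synthetic case family.

    Lengths with the ``_mm`` suffix are physical; everything else is voxels
    of the configured grid.  Defaults describe the full clinical grid
    (512 x 512 axial matrix, ~130 slices at 3 mm); :meth:`desk` yields a
    proportionally reduced grid for CPU-scale experiments.
    """

    grid_size: tuple[int, int, int] = (512, 512, 130)
    spacing: tuple[float, float, float] = (0.9, 0.9, 3.0)
    # body geometry (voxels)
    head_center_xy: tuple[int, int] = (256, 256)
    head_radius_mm: float = 90.0
    head_center_z: int = 85
    neck_radius_mm: float = 40.0
    neck_slice: int = 45
    neck_flare: float = 0.02          # voxel radius gain per squared slice offset
    shoulder_top: int = 30            # slab occupies slices [0, shoulder_top)
    shoulder_halfaxes: tuple[int, int] = (230, 130)
    # bed
    bed: bool = True
    bed_rows: tuple[int, int] = (440, 456)
    bed_thickness: int = 2
    bed_span: tuple[float, float] = (0.15, 0.85)  # x extent as FOV fraction
    bed_hu: float = 800.0
    # tumor
    tumor_semiaxes_mm: tuple[tuple[float, float], ...] = ((4.0, 19.0), (4.0, 19.0), (9.0, 27.0))
    tumor_center_jitter: tuple[int, int, int] = (40, 40, 12)
    tumor_contrast_hu: float = 120.0
    ce_contrast_factor: float = 1.5
    boundary_softness: float = 0.08   # logistic width in normalized radius
    # intensity
    tissue_hu: float = 0.0
    air_hu: float = -1000.0
    noise_sigma_hu: float = 20.0
    channels: int = 1

    def __post_init__(self):
        nx, ny, nz = self.grid_size
        if self.neck_radius_mm >= self.head_radius_mm:
            raise ValueError("neck radius must be smaller than head radius")
        if not (self.shoulder_top <= self.neck_slice < self.head_center_z < nz):
            raise ValueError("need shoulder_top <= neck_slice < head_center_z < nz")
        if self.tumor_contrast_hu <= 0:
            raise ValueError("tumor contrast must be positive")
        if self.channels not in (1, 2):
            raise ValueError("channels must be 1 or 2")

    @classmethod
    def desk(cls, channels: int = 1, spacing: tuple[float, float, float] = (0.952, 0.952, 3.0),
             **overrides) -> "PhantomSpec":
        """A 128 x 128 x 64 phantom preserving the full grid's proportions."""
        kw = dict(
            grid_size=(128, 128, 64), spacing=spacing,
            head_center_xy=(64, 64), head_radius_mm=38.0, head_center_z=40,
            neck_radius_mm=15.0, neck_slice=20, neck_flare=0.03,
            shoulder_top=12, shoulder_halfaxes=(56, 34),
            bed_rows=(108, 116), bed_thickness=2,
            tumor_semiaxes_mm=((6.0, 16.0), (5.0, 12.0), (7.5, 18.0)),
            tumor_center_jitter=(12, 12, 5),
            channels=channels,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PhantomCase:
    """A rendered phantom: volume + ground truth + exact truth record."""

    volume: ImageVolume
    gt: BinaryMask
    truth: dict[str, Any] = field(default_factory=dict)
    case_id: str = "case"


def _body_mask(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.grid_size
    sx, sy, sz = spec.spacing
    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(nz)[None, None, :]
    cx, cy = spec.head_center_xy

    rhx, rhz = spec.head_radius_mm / sx, spec.head_radius_mm / sz
    head = (((x - cx) / rhx) ** 2 + ((y - cy) / rhx) ** 2
            + ((z - spec.head_center_z) / rhz) ** 2) <= 1.0

    rneck = spec.neck_radius_mm / sx + spec.neck_flare * (z - spec.neck_slice) ** 2
    in_neck_z = (z >= max(spec.shoulder_top - 1, 0)) & (z <= spec.head_center_z)
    neck = in_neck_z & ((x - cx) ** 2 + (y - cy) ** 2 <= rneck**2)

    ax, ay = spec.shoulder_halfaxes
    shoulder = (z < spec.shoulder_top) & (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0)

    return head | neck | shoulder


def _bed_mask(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.grid_size
    bed = np.zeros(spec.grid_size, dtype=bool)
    if not spec.bed:
        return bed
    x0, x1 = (int(round(f * nx)) for f in spec.bed_span)
    for row in spec.bed_rows:
        bed[x0:x1, row:row + spec.bed_thickness, :] = True
    return bed


def _tumor_fields(spec: PhantomSpec, center: np.ndarray,
                  semiaxes_vox: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(soft intensity profile in [0,1], hard interior mask)."""
    nx, ny, nz = spec.grid_size
    lo = np.maximum(np.floor(center - 2 * semiaxes_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center + 2 * semiaxes_vox).astype(int) + 1, spec.grid_size)
    soft = np.zeros(spec.grid_size, dtype=np.float32)
    hard = np.zeros(spec.grid_size, dtype=bool)
    xs = [np.arange(lo[i], hi[i]) for i in range(3)]
    rho = np.sqrt(
        ((xs[0][:, None, None] - center[0]) / semiaxes_vox[0]) ** 2
        + ((xs[1][None, :, None] - center[1]) / semiaxes_vox[1]) ** 2
        + ((xs[2][None, None, :] - center[2]) / semiaxes_vox[2]) ** 2
    )
    region = tuple(slice(lo[i], hi[i]) for i in range(3))
    soft[region] = 1.0 / (1.0 + np.exp(np.clip((rho - 1.0) / spec.boundary_softness, -60, 60)))
    hard[region] = rho < 1.0
    return soft, hard


def _head_rho(spec: PhantomSpec, p: np.ndarray) -> float:
    sx, _, sz = spec.spacing
    cx, cy = spec.head_center_xy
    rhx, rhz = spec.head_radius_mm / sx, spec.head_radius_mm / sz
    return float(np.sqrt(((p[0] - cx) / rhx) ** 2 + ((p[1] - cy) / rhx) ** 2
                         + ((p[2] - spec.head_center_z) / rhz) ** 2))


def _draw_tumor(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    sx, sy, sz = spec.spacing
    cx, cy = spec.head_center_xy
    base = np.array([cx, cy, spec.head_center_z], dtype=float)
    jit = np.asarray(spec.tumor_center_jitter, dtype=float)
    for _ in range(100):
        semi_mm = np.array([rng.uniform(lo, hi) for lo, hi in spec.tumor_semiaxes_mm])
        semi_vox = semi_mm / np.array([sx, sy, sz])
        center = base + rng.uniform(-1, 1, 3) * jit
        # sample the tumor surface and require it inside the head with margin
        th = np.linspace(0, np.pi, 7)[1:-1]
        ph = np.linspace(0, 2 * np.pi, 9)[:-1]
        tt, pp = np.meshgrid(th, ph, indexing="ij")
        pts = np.stack([
            center[0] + semi_vox[0] * np.sin(tt) * np.cos(pp),
            center[1] + semi_vox[1] * np.sin(tt) * np.sin(pp),
            center[2] + semi_vox[2] * np.cos(tt),
        ], axis=-1).reshape(-1, 3)
        poles = np.array([center + [0, 0, semi_vox[2]], center - [0, 0, semi_vox[2]]])
        pts = np.vstack([pts, poles])
        if max(_head_rho(spec, p) for p in pts) <= 0.95:
            return center, semi_vox
    raise RuntimeError("could not place tumor inside body after 100 attempts")


def generate_case(spec: PhantomSpec, seed: int, case_id: str = "case") -> PhantomCase:
    """Render one phantom; bit-deterministic for fixed ``(spec, seed)``."""
    rng = np.random.default_rng(seed)
    body = _body_mask(spec)
    bed = _bed_mask(spec)
    if (body & bed).any():
        raise ValueError("bed rails intersect the body; adjust bed_rows")
    center, semi_vox = _draw_tumor(spec, rng)
    soft, hard = _tumor_fields(spec, center, semi_vox)

    base = np.where(body, spec.tissue_hu, spec.air_hu).astype(np.float32)
    base[bed] = spec.bed_hu
    channels = []
    for c in range(spec.channels):
        contrast = spec.tumor_contrast_hu * (spec.ce_contrast_factor if c == 1 else 1.0)
        img = base + contrast * soft
        if spec.noise_sigma_hu > 0:
            img = img + rng.normal(0.0, spec.noise_sigma_hu, spec.grid_size).astype(np.float32)
        channels.append(img.astype(np.float32))

    volume = ImageVolume(np.stack(channels), spec.spacing)
    gt = BinaryMask(hard.astype(np.uint8), spec.spacing)
    if gt.n_foreground == 0:
        raise RuntimeError("rendered tumor is empty; semi-axes too small for the grid")
    truth = {
        "tumor_center": center.tolist(),
        "tumor_semiaxes_vox": semi_vox.tolist(),
        "neck_slice": spec.neck_slice,
        "body": body,
        "bed": bed,
        "seed": int(seed),
    }
    return PhantomCase(volume=volume, gt=gt, truth=truth, case_id=case_id)


def generate_cohort(spec: PhantomSpec, n: int, seed: int) -> list[PhantomCase]:
    """``n`` cases with independently drawn tumors; per-case seeds derive
    from the master seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [generate_case(spec, int(s), case_id=f"case{i:03d}")
            for i, s in enumerate(case_seeds)]
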