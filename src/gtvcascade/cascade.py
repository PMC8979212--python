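"""Coarse-to-fine two-stage segmentation: patch sampling, sliding-window
inference, tumor-centroid localization, fine-stage ROI cropping, score
assembly, thresholding and restoration to the original grid.

Stage 1 tiles the preprocessed volume with overlapping windows and averages
the per-window scores into a coarse map S1.  The tumor centroid is located
from S1, a fixed-size ROI is cropped around it and scored by the stage-2
network into S2.  The final score is S = w*S1 + (1-w)*S2 inside the ROI and
S1 outside; voxels with S >= threshold (inclusive) are foreground, and the
binary result is restored to the original uncropped CT canvas.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .grids import BinaryMask, ImageVolume
from .network import SegNetwork, load_network, save_network
from .preprocessing import ForegroundStats, normalize, preprocess_case

__all__ = ["ROIBox", "ScoreMap", "CascadeModel", "window_origins",
           "sample_patch_stage1", "sample_patch_stage2", "sliding_window_infer",
           "locate_center", "assemble", "binarize_and_restore", "predict_case"]


@dataclass(frozen=True)
class ROIBox:
    """Fixed-size crop identified by its integer centre, half-open bounds."""

    center: tuple[int, int, int]
    size: tuple[int, int, int]

    @property
    def start(self) -> tuple[int, int, int]:
        return tuple(int(c) - s // 2 for c, s in zip(self.center, self.size))

    @property
    def end(self) -> tuple[int, int, int]:
        return tuple(st + s for st, s in zip(self.start, self.size))


@dataclass
class ScoreMap:
    """Per-voxel probabilities in [0, 1] on the preprocessed grid."""

    data: np.ndarray
    provenance: str = "stage1"  # stage1 | stage2 | assembled
    roi: ROIBox | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("score values must lie in [0, 1]")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x) + 0.5).astype(int)


def _crop_padded(data: np.ndarray, start, size, pad_value: float) -> np.ndarray:
    """Half-open crop of the spatial axes of (C, X, Y, Z) data, padding with
    ``pad_value`` where the box leaves the grid."""
    out = np.full((data.shape[0], *size), pad_value, dtype=data.dtype)
    src = []
    dst = []
    for ax in range(3):
        s0 = start[ax]
        s1 = s0 + size[ax]
        c0, c1 = max(s0, 0), min(s1, data.shape[ax + 1])
        if c0 >= c1:
            return out
        src.append(slice(c0, c1))
        dst.append(slice(c0 - s0, c1 - s0))
    out[(slice(None), *dst)] = data[(slice(None), *src)]
    return out


def window_origins(extent: int, patch: int, stride: int) -> list[int]:
    """Sliding-window origins along one axis: a regular stride grid with the
    final window clamped to the border so every voxel is covered."""
    if extent <= patch:
        return [0]
    origins = list(range(0, extent - patch + 1, stride))
    if origins[-1] != extent - patch:
        origins.append(extent - patch)
    return origins


def sample_patch_stage1(v: ImageVolume, gt: BinaryMask,
                        patch_size: tuple[int, int, int],
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random patch/label crop for coarse-stage training."""
    if tuple(gt.shape) != tuple(v.shape):
        raise ValueError("gt grid does not match volume grid")
    pad_value = float(v.data.min())
    origin = []
    for ax in range(3):
        hi = v.shape[ax] - patch_size[ax]
        origin.append(int(rng.integers(0, hi + 1)) if hi > 0 else (hi if hi < 0 else 0))
    # negative origin centres an undersized volume inside the padded patch
    origin = [o if o >= 0 else o // 2 for o in origin]
    patch = _crop_padded(v.data, origin, patch_size, pad_value)
    label = _crop_padded(gt.data[None].astype(np.float32), origin, patch_size, 0.0)[0]
    return patch, label


def gt_centroid(gt: BinaryMask) -> tuple[int, int, int]:
    idx = np.argwhere(gt.data > 0)
    if idx.size == 0:
        raise ValueError("no GTV in case")
    return tuple(_round_half_up(idx.mean(axis=0)).tolist())


def sample_patch_stage2(v: ImageVolume, gt: BinaryMask,
                        patch_size: tuple[int, int, int],
                        jitter: tuple[int, int, int],
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Fine-stage crop centred on the ground-truth centroid plus an integer
    jitter drawn uniformly from the configured range per axis."""
    if tuple(gt.shape) != tuple(v.shape):
        raise ValueError("gt grid does not match volume grid")
    center = np.array(gt_centroid(gt))
    off = np.array([int(rng.integers(-j, j + 1)) if j > 0 else 0 for j in jitter])
    box = ROIBox(tuple((center + off).tolist()), tuple(patch_size))
    pad_value = float(v.data.min())
    patch = _crop_padded(v.data, box.start, box.size, pad_value)
    label = _crop_padded(gt.data[None].astype(np.float32), box.start, box.size, 0.0)[0]
    return patch, label


def sliding_window_infer(net: SegNetwork, v: ImageVolume,
                         patch_size: tuple[int, int, int],
                         stride: tuple[int, int, int]) -> ScoreMap:
    """Coarse score map S1 on the full grid.

    Windows tile the volume at the configured stride with the final window
    clamped to each border; overlapping predictions are averaged with equal
    weights.  Volumes smaller than a window are padded for the forward pass
    and cropped back.
    """
    shape = v.shape
    pad_value = float(v.data.min())
    padded = tuple(max(s, p) for s, p in zip(shape, patch_size))
    data = v.data
    if padded != tuple(shape):
        data = _crop_padded(v.data, (0, 0, 0), padded, pad_value)
    acc = np.zeros(padded, dtype=np.float64)
    cnt = np.zeros(padded, dtype=np.int32)
    for ox in window_origins(padded[0], patch_size[0], stride[0]):
        for oy in window_origins(padded[1], patch_size[1], stride[1]):
            for oz in window_origins(padded[2], patch_size[2], stride[2]):
                sl = (slice(ox, ox + patch_size[0]), slice(oy, oy + patch_size[1]),
                      slice(oz, oz + patch_size[2]))
                scores = net.forward(data[(slice(None), *sl)])[0]
                acc[sl] += scores
                cnt[sl] += 1
    s1 = (acc / cnt)[: shape[0], : shape[1], : shape[2]]
    return ScoreMap(s1.astype(np.float32), provenance="stage1")


def locate_center(s1: ScoreMap, threshold: float = 0.5) -> tuple[int, int, int]:
    """Centroid of the largest connected component of S1 >= threshold."""
    fg = s1.data >= threshold
    if not fg.any():
        raise ValueError("no coarse detection: no score reaches the threshold")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    idx = np.argwhere(fg)
    return tuple(_round_half_up(idx.mean(axis=0)).tolist())


def stage2_infer(net: SegNetwork, v: ImageVolume, roi: ROIBox) -> ScoreMap:
    pad_value = float(v.data.min())
    patch = _crop_padded(v.data, roi.start, roi.size, pad_value)
    scores = net.forward(patch)[0]
    return ScoreMap(scores, provenance="stage2", roi=roi)


def assemble(s1: ScoreMap, s2: ScoreMap, roi: ROIBox, weight: float) -> ScoreMap:
    """S = w*S1 + (1-w)*S2 inside the ROI; S1 elsewhere."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError("assembly weight must be in [0, 1]")
    shape = s1.data.shape
    out = s1.data.copy()
    grid_sl, patch_sl = [], []
    for ax in range(3):
        g0, g1 = max(roi.start[ax], 0), min(roi.end[ax], shape[ax])
        if g0 >= g1:
            raise ValueError("ROI lies outside the score grid")
        grid_sl.append(slice(g0, g1))
        patch_sl.append(slice(g0 - roi.start[ax], g1 - roi.start[ax]))
    out[tuple(grid_sl)] = (weight * s1.data[tuple(grid_sl)]
                           + (1.0 - weight) * s2.data[tuple(patch_sl)])
    return ScoreMap(out, provenance="assembled", roi=roi)


def _resize_nearest(data: np.ndarray, out_shape: tuple[int, int, int]) -> np.ndarray:
    idx = []
    for ax in range(3):
        n_in, n_out = data.shape[ax], out_shape[ax]
        src = np.minimum(((np.arange(n_out) + 0.5) * n_in / n_out).astype(int), n_in - 1)
        idx.append(src)
    return data[np.ix_(*idx)]


def binarize_and_restore(s: ScoreMap, threshold: float,
                         meta: dict) -> BinaryMask:
    """Threshold S (inclusive: S == threshold is foreground), undo the
    resampling with nearest-neighbour resizing, and place the mask back on
    the original uncropped canvas at the recorded crop offset."""
    for key in ("crop_offset", "cropped_shape", "original_shape", "original_spacing"):
        if key not in meta:
            raise ValueError(f"missing crop provenance: {key!r}")
    binary = (s.data >= threshold).astype(np.uint8)
    restored = _resize_nearest(binary, tuple(meta["cropped_shape"]))
    canvas = np.zeros(tuple(meta["original_shape"]), dtype=np.uint8)
    x0, y0, z0 = meta["crop_offset"]
    nx, ny, nz = restored.shape
    canvas[x0:x0 + nx, y0:y0 + ny, z0:z0 + nz] = restored
    return BinaryMask(canvas, tuple(meta["original_spacing"]))


@dataclass
class CascadeModel:
    """Both trained stage networks plus the frozen cohort statistics."""

    stage1: SegNetwork
    stage2: SegNetwork
    stats: ForegroundStats
    config: PipelineConfig
    log: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_network(self.stage1, directory / "stage1.npz")
        save_network(self.stage2, directory / "stage2.npz")
        payload = {"stats": self.stats.to_dict(), "config": self.config.to_dict(),
                   "log": self.log}
        (directory / "model.json").write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "CascadeModel":
        from .config import load_config

        directory = Path(directory)
        payload = json.loads((directory / "model.json").read_text())
        cfg = load_config(overrides=payload["config"])
        return cls(stage1=load_network(directory / "stage1.npz"),
                   stage2=load_network(directory / "stage2.npz"),
                   stats=ForegroundStats.from_dict(payload["stats"]),
                   config=cfg, log=payload.get("log", {}))


def predict_case(model: CascadeModel, raw: ImageVolume) -> BinaryMask:
    """Full pipeline on a raw CT: preprocess -> S1 -> centroid -> ROI -> S2
    -> assemble -> threshold -> restore.  Deterministic given the model.

    A case with no coarse detection yields an empty mask with
    ``meta['warning'] = 'no coarse detection'`` rather than an exception, so
    cohort evaluation completes.
    """
    cfg = model.config
    vol, body, _ = preprocess_case(raw, cfg.target_spacing, cfg.hu_threshold)
    vol = normalize(vol, model.stats)
    s1 = sliding_window_infer(model.stage1, vol, cfg.stage1_patch, cfg.stage1_stride)
    try:
        center = locate_center(s1)
    except ValueError:
        warnings.warn("no coarse detection; returning an empty mask")
        empty = BinaryMask(np.zeros(tuple(vol.meta["original_shape"]), dtype=np.uint8),
                           tuple(vol.meta["original_spacing"]))
        empty.meta["warning"] = "no coarse detection"
        return empty
    roi = ROIBox(center, cfg.stage2_patch)
    s2 = stage2_infer(model.stage2, vol, roi)
    s = assemble(s1, s2, roi, cfg.assembly_weight)
    return binarize_and_restore(s, cfg.final_threshold, vol.meta)
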