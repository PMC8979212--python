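"""Validated pipeline configuration with the published defaults.

Every number that steers the pipeline lives here: the resampling target
spacing (0.952, 0.952, 3.0) mm, the coarse-stage sliding window 128x128x64
with stride 64x64x32, the fine-stage crop 96x64x32 with +-3 voxel centre
jitter, the assembly weight w = 0.5, the final threshold 0.6, and the
training recipe (SGD momentum 0.99, poly learning-rate decay with exponent
0.9 from 0.01 over 120 epochs, batch size 1 with gradient accumulation over
2 samples, fine-tuning at 0.001 over 60 epochs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .network import NetworkSpec

__all__ = ["AugmentSpec", "TrainSpec", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class AugmentSpec:
    """Random augmentation parameters; each transform fires with probability
    ``gate_p`` independently."""

    scale_range: tuple[float, float] = (0.7, 1.3)
    elastic_alpha: float = 34.0
    elastic_sigma: float = 10.0
    rotation_deg: tuple[float, float] = (-10.0, 10.0)
    noise_gaussian_sigma_max: float = 0.1
    noise_uniform_limit: float = 0.1
    flip: bool = True
    gate_p: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.gate_p <= 1.0:
            raise ValueError("gate_p must be in [0, 1]")
        if self.scale_range[0] <= 0 or self.scale_range[0] > self.scale_range[1]:
            raise ValueError(f"bad scale_range {self.scale_range}")


@dataclass(frozen=True)
class TrainSpec:
    lr_ini: float = 0.01
    epochs: int = 120
    poly_exponent: float = 0.9
    momentum: float = 0.99
    batch_size: int = 1
    accumulation: int = 2
    patches_per_case: int = 2
    finetune_lr_ini: float = 0.001
    finetune_epochs: int = 60
    finetune_train_fraction: float = 0.7
    folds: int = 5
    dice_eps: float = 1e-5
    augment: AugmentSpec = field(default_factory=AugmentSpec)
    seed: int = 0

    def __post_init__(self):
        if self.lr_ini <= 0 or self.finetune_lr_ini <= 0:
            raise ValueError("learning rates must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.accumulation < 1:
            raise ValueError("accumulation must be >= 1")
        if not 0 < self.finetune_train_fraction < 1:
            raise ValueError("finetune_train_fraction must be in (0, 1)")


def _check_divisible(patch: tuple[int, int, int], divisor: int, name: str) -> None:
    if any(p % divisor for p in patch):
        raise ValueError(
            f"{name} {patch} must be divisible by 2^(levels-1) = {divisor}")


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration; defaults reproduce the published recipe."""

    target_spacing: tuple[float, float, float] = (0.952, 0.952, 3.0)
    stage1_patch: tuple[int, int, int] = (128, 128, 64)
    stage1_stride: tuple[int, int, int] = (64, 64, 32)
    stage2_patch: tuple[int, int, int] = (96, 64, 32)
    jitter_range: tuple[int, int, int] = (3, 3, 3)
    assembly_weight: float = 0.5
    final_threshold: float = 0.6
    hu_threshold: float = -300.0
    in_channels: int = 1
    stage1_network: NetworkSpec = None  # filled in __post_init__
    stage2_network: NetworkSpec = None
    train: TrainSpec = field(default_factory=TrainSpec)
    seed: int = 0

    def __post_init__(self):
        if self.stage1_network is None:
            object.__setattr__(self, "stage1_network",
                               NetworkSpec.for_stage(1, in_channels=self.in_channels))
        if self.stage2_network is None:
            object.__setattr__(self, "stage2_network",
                               NetworkSpec.for_stage(2, in_channels=self.in_channels))
        if not 0.0 <= self.assembly_weight <= 1.0:
            raise ValueError(f"assembly_weight must be in [0, 1], got {self.assembly_weight}")
        if not 0.0 < self.final_threshold < 1.0:
            raise ValueError(f"final_threshold must be in (0, 1), got {self.final_threshold}")
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")
        if any(j < 0 for j in self.jitter_range):
            raise ValueError("jitter_range must be non-negative")
        _check_divisible(self.stage1_patch, self.stage1_network.divisor, "stage1_patch")
        _check_divisible(self.stage2_patch, self.stage2_network.divisor, "stage2_patch")

    @classmethod
    def tiny(cls, in_channels: int = 1, seed: int = 0, **train_overrides) -> "PipelineConfig":
        """Desk-scale configuration: 3 levels, base width 8, patches
        64x64x32 (stride 32x32x16) and 48x32x16; same recipe otherwise."""
        train = TrainSpec(seed=seed, **train_overrides)
        return cls(
            stage1_patch=(64, 64, 32), stage1_stride=(32, 32, 16),
            stage2_patch=(48, 32, 16), in_channels=in_channels,
            stage1_network=NetworkSpec.for_stage(1, in_channels=in_channels,
                                                 levels=3, base_features=8),
            stage2_network=NetworkSpec.for_stage(2, in_channels=in_channels,
                                                 levels=3, base_features=8),
            train=train, seed=seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage1_network"] = self.stage1_network.to_dict()
        d["stage2_network"] = self.stage2_network.to_dict()
        return d


_TUPLE_FIELDS = {"target_spacing", "stage1_patch", "stage1_stride", "stage2_patch",
                 "jitter_range", "scale_range", "rotation_deg", "dilation_rates"}


def _tuplify(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, dict):
            out[k] = _tuplify(v)
        elif k in _TUPLE_FIELDS and isinstance(v, (list, tuple)):
            out[k] = tuple(v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON document.

    Absent fields take the published defaults; an empty (or missing) document
    yields the full default configuration.  Unknown or invalid fields raise a
    ``ValueError`` naming the field.
    """
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("config document must be a mapping")
            doc.update(loaded)
    if overrides:
        doc.update(overrides)
    doc = _tuplify(doc)

    def build(cls, data: dict, name: str):
        valid = set(cls.__dataclass_fields__)
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown {name} field(s): {sorted(unknown)}")
        try:
            return cls(**data)
        except (TypeError, ValueError) as e:
            raise ValueError(f"invalid {name} configuration: {e}") from e

    kwargs = dict(doc)
    for key, cls in (("stage1_network", NetworkSpec), ("stage2_network", NetworkSpec)):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = build(cls, kwargs[key], key)
    if "train" in kwargs and isinstance(kwargs["train"], dict):
        tkw = dict(kwargs["train"])
        if "augment" in tkw and isinstance(tkw["augment"], dict):
            tkw["augment"] = build(AugmentSpec, tkw["augment"], "augment")
        kwargs["train"] = build(TrainSpec, tkw, "train")
    return build(PipelineConfig, kwargs, "pipeline")
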