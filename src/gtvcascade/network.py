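"""Stage-specific 3D Res-UNet architectures with multiscale dilated skips.

Both stages share one encoder-decoder skeleton: per resolution level a
Conv-block (strided past the first level, so it doubles as the downsampler)
followed by a Res-block; a Res-block bottleneck at the deepest resolution;
and a mirrored decoder whose levels upsample by transposed convolution,
concatenate the skip feature and apply a Conv-block + Res-block.  Every skip
connection routes through an ASPP-family block, enlarging the field of view
with parallel dilated convolutions.

With ``levels`` resolution levels this yields ``levels + 1`` encoder
Res-blocks, ``levels`` decoder Res-blocks (the deepest decoder level merges
without upsampling) and ``levels`` ASPP blocks — at the default ``levels=5``:
11 Res-blocks and 5 ASPP blocks.  Feature widths follow
``min(base * 2^level, cap)``.

Stage differences: stage 1 (whole-volume windows) uses the plain ASPP variant
with large dilation rates; stage 2 (small tumor-centred crops) uses the
ASPP_v3+ variant with small rates, an image-pooling path and dropout, plus a
dropout layer at the encoder end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import (ASPPBlock, Conv3d, ConvBlock, ConvTranspose3d, Dropout,
                 InstanceNorm3d, Parameter, ResBlock, kaiming_normal_init)

__all__ = ["NetworkSpec", "SegNetwork", "build_network", "initialize",
           "save_network", "load_network"]

_STAGE_DEFAULTS = {
    1: dict(feature_cap=512, aspp_variant="aspp", dilation_rates=(6, 12, 18), dropout_p=0.0),
    2: dict(feature_cap=1024, aspp_variant="aspp_v3p", dilation_rates=(1, 2, 4), dropout_p=0.3),
}


@dataclass(frozen=True)
class NetworkSpec:
    """Hyperparameters fixing one stage network's construction."""

    stage: int = 1
    levels: int = 5
    base_features: int = 32
    feature_cap: int = 512
    aspp_variant: str = "aspp"
    dilation_rates: tuple[int, ...] = (6, 12, 18)
    dropout_p: float = 0.0
    in_channels: int = 1
    negative_slope: float = 0.01

    def __post_init__(self):
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")
        if self.levels < 2:
            raise ValueError("need at least 2 resolution levels")
        if self.feature_cap < self.base_features:
            raise ValueError("feature cap below base width")
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")

    @classmethod
    def for_stage(cls, stage: int, in_channels: int = 1, levels: int = 5,
                  base_features: int = 32, **overrides) -> "NetworkSpec":
        kw = dict(_STAGE_DEFAULTS[stage])
        kw.update(overrides)
        return cls(stage=stage, levels=levels, base_features=base_features,
                   in_channels=in_channels, **kw)

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(min(self.base_features * 2**i, self.feature_cap)
                     for i in range(self.levels))

    @property
    def divisor(self) -> int:
        """Patch sizes must be divisible by 2^(levels-1)."""
        return 2 ** (self.levels - 1)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["dilation_rates"] = list(self.dilation_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        d["dilation_rates"] = tuple(d["dilation_rates"])
        return cls(**d)


def _level_rates(rates: tuple[int, ...], level: int) -> tuple[int, ...]:
    # deeper skips see coarser grids; halve the dilation per level, floor 1
    return tuple(max(1, r // 2**level) for r in rates)


class SegNetwork:
    """A built stage network: input patch (C, X, Y, Z) -> scores in (0, 1)."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        w = spec.widths
        L = spec.levels
        ns = spec.negative_slope

        self.enc_conv = [ConvBlock(spec.in_channels, w[0], stride=1, negative_slope=ns)]
        self.enc_res = [ResBlock(w[0], ns)]
        for lev in range(1, L):
            self.enc_conv.append(ConvBlock(w[lev - 1], w[lev], stride=2, negative_slope=ns))
            self.enc_res.append(ResBlock(w[lev], ns))
        self.bottleneck = ResBlock(w[L - 1], ns)
        self.enc_dropout = Dropout(spec.dropout_p) if (spec.stage == 2 and spec.dropout_p > 0) else None

        self.aspp = [ASPPBlock(w[lev], _level_rates(spec.dilation_rates, lev),
                               spec.aspp_variant, spec.dropout_p, ns)
                     for lev in range(L)]

        self.up = [ConvTranspose3d(w[lev + 1], w[lev]) for lev in range(L - 1)]
        self.dec_conv = [ConvBlock(2 * w[lev], w[lev], stride=1, negative_slope=ns)
                         for lev in range(L)]
        self.dec_res = [ResBlock(w[lev], ns) for lev in range(L)]
        self.head = Conv3d(w[0], 1, k=1)

    # ---- structural accessors -------------------------------------------------

    def blocks(self):
        out = []
        out.extend(self.enc_conv)
        out.extend(self.enc_res)
        out.append(self.bottleneck)
        out.extend(self.aspp)
        out.extend(self.dec_conv)
        out.extend(self.dec_res)
        return out

    def block_inventory(self) -> dict[str, int]:
        inv = {"res": 0, "aspp": 0, "conv": 0}
        for b in self.blocks():
            inv[b.kind] += 1
        return {"res_blocks": inv["res"], "aspp_blocks": inv["aspp"],
                "conv_blocks": inv["conv"], "upsample_blocks": len(self.up)}

    def layers(self) -> list:
        """All primitive layers in a fixed construction order."""
        out: list = []
        L = self.spec.levels
        for lev in range(L):
            out.extend(self.enc_conv[lev].layers())
            out.extend(self.enc_res[lev].layers())
        out.extend(self.bottleneck.layers())
        if self.enc_dropout is not None:
            out.append(self.enc_dropout)
        for a in self.aspp:
            out.extend(a.layers())
        for u in self.up:
            out.append(u)
        for lev in range(L):
            out.extend(self.dec_conv[lev].layers())
            out.extend(self.dec_res[lev].layers())
        out.append(self.head)
        return out

    def parameters(self) -> list[tuple[str, Parameter]]:
        out = []
        for i, lay in enumerate(self.layers()):
            for name, p in lay.parameters():
                out.append((f"layer{i:03d}.{type(lay).__name__}.{name}", p))
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for _, p in self.parameters())

    def zero_grad(self) -> None:
        for _, p in self.parameters():
            p.zero_grad()

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for lay in self.layers():
            if isinstance(lay, Dropout):
                lay.rng = rng

    # ---- forward / backward ---------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[np.newaxis]
        if x.ndim != 4 or x.shape[0] != self.spec.in_channels:
            raise ValueError(f"expected ({self.spec.in_channels}, X, Y, Z) input, got {x.shape}")
        d = self.spec.divisor
        if any(s % d for s in x.shape[1:]):
            raise ValueError(f"spatial shape {x.shape[1:]} not divisible by {d}")
        return x

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._check_input(x)
        L = self.spec.levels
        skips = []
        h = x
        for lev in range(L):
            h = self.enc_conv[lev].forward(h, train)
            h = self.enc_res[lev].forward(h, train)
            skips.append(h)
        h = self.bottleneck.forward(h, train)
        if self.enc_dropout is not None:
            h = self.enc_dropout.forward(h, train)
        skips = [self.aspp[lev].forward(s, train) for lev, s in enumerate(skips)]
        for lev in range(L - 1, -1, -1):
            if lev < L - 1:
                h = self.up[lev].forward(h, train)
            h = np.concatenate([skips[lev], h], axis=0)
            h = self.dec_conv[lev].forward(h, train)
            h = self.dec_res[lev].forward(h, train)
        return self.head.forward(h, train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Score patch in (0, 1) with the same spatial shape as the input."""
        z = self.forward_logits(x, train)
        return _sigmoid(z)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dlogits."""
        L = self.spec.levels
        w = self.spec.widths
        dy = self.head.backward(dlogits)
        dskips = [None] * L
        for lev in range(L):
            dy = self.dec_res[lev].backward(dy)
            dy = self.dec_conv[lev].backward(dy)
            dskips[lev] = dy[: w[lev]]
            dy = np.ascontiguousarray(dy[w[lev]:])
            if lev < L - 1:
                dy = self.up[lev].backward(dy)
        denc = [self.aspp[lev].backward(dskips[lev]) for lev in range(L)]
        if self.enc_dropout is not None:
            dy = self.enc_dropout.backward(dy)
        dy = self.bottleneck.backward(dy)
        for lev in range(L - 1, -1, -1):
            dy = dy + denc[lev]
            dy = self.enc_res[lev].backward(dy)
            dy = self.enc_conv[lev].backward(dy)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build_network(spec: NetworkSpec) -> SegNetwork:
    """Construct (un-initialized) the stage network described by ``spec``."""
    return SegNetwork(spec)


def initialize(net: SegNetwork, scheme: str = "kaiming_normal",
               seed: int = 0) -> SegNetwork:
    """Draw all convolution weights (kaiming-normal, leaky-ReLU gain); zero
    biases; unit norm scales.  Reproducible under ``seed``."""
    if scheme != "kaiming_normal":
        raise ValueError(f"unknown initialization scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    slope = net.spec.negative_slope
    for lay in net.layers():
        if isinstance(lay, (Conv3d, ConvTranspose3d)):
            lay.weight.data = kaiming_normal_init(lay.weight.data.shape, lay.fan_in,
                                                  rng, slope)
            lay.bias.data[...] = 0.0
        elif isinstance(lay, InstanceNorm3d):
            lay.gamma.data[...] = 1.0
            lay.beta.data[...] = 0.0
    return net


def save_network(net: SegNetwork, path: str | Path) -> None:
    """Checkpoint = spec JSON sidecar + named parameter arrays (npz)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {name: p.data for name, p in net.parameters()}
    np.savez(str(path), **arrays)
    path.with_suffix(".json").write_text(json.dumps(net.spec.to_dict(), indent=1))


def load_network(path: str | Path) -> SegNetwork:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    spec = NetworkSpec.from_dict(json.loads(path.with_suffix(".json").read_text()))
    net = SegNetwork(spec)
    with np.load(str(path)) as zf:
        for name, p in net.parameters():
            p.data = np.ascontiguousarray(zf[name])
            p.grad = np.zeros_like(p.data)
    return net
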