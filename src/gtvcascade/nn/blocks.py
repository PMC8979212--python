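"""Composite building blocks: Conv-block, Res-block and the ASPP family.

A Conv-block is convolution -> instance norm -> leaky ReLU (strided when it
doubles as a downsampler).  The Res-block uses pre-activation ordering with an
identity shortcut.  The ASPP blocks fuse parallel dilated convolutions at
several rates on each skip connection; the "v3p" variant adds an
image-pooling path and dropout for the small fine-stage patches.
"""

from __future__ import annotations

import numpy as np

from .core import (DTYPE, Conv3d, Dropout, GlobalAvgPool, InstanceNorm3d,
                   Layer, LeakyReLU)

__all__ = ["ConvBlock", "ResBlock", "ASPPBlock"]


class _Chain:
    """Sequential container with explicit backward."""

    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class ConvBlock:
    kind = "conv"

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1, k: int = 3,
                 negative_slope: float = 0.01):
        self.conv = Conv3d(in_ch, out_ch, k=k, stride=stride)
        self.chain = _Chain(self.conv, InstanceNorm3d(out_ch), LeakyReLU(negative_slope))

    def layers(self):
        return list(self.chain.layers)

    def forward(self, x, train=False):
        return self.chain.forward(x, train)

    def backward(self, dy):
        return self.chain.backward(dy)


class ResBlock:
    """Pre-activation residual unit: x + conv(act(norm(conv(act(norm(x)))))).

    Channel count is preserved, so the shortcut is a pure identity.
    """

    kind = "res"

    def __init__(self, ch: int, negative_slope: float = 0.01):
        self.branch = _Chain(
            InstanceNorm3d(ch), LeakyReLU(negative_slope), Conv3d(ch, ch, k=3),
            InstanceNorm3d(ch), LeakyReLU(negative_slope), Conv3d(ch, ch, k=3),
        )

    def layers(self):
        return list(self.branch.layers)

    def forward(self, x, train=False):
        return x + self.branch.forward(x, train)

    def backward(self, dy):
        return dy + self.branch.backward(dy)


class ASPPBlock:
    """Atrous spatial pyramid pooling on a skip connection.

    Parallel paths: a 1x1x1 convolution plus one 3x3x3 dilated convolution per
    rate; the ``v3p`` variant appends a global image-pooling path.  Path
    outputs are concatenated and merged by a 1x1x1 convolution.  ``v3p``
    finishes with dropout.  Every path keeps the block's channel width.
    """

    kind = "aspp"

    def __init__(self, ch: int, rates: tuple[int, ...], variant: str = "aspp",
                 dropout_p: float = 0.0, negative_slope: float = 0.01):
        if variant not in ("aspp", "aspp_v3p"):
            raise ValueError(f"unknown ASPP variant {variant!r}")
        self.variant = variant
        self.rates = tuple(int(r) for r in rates)
        self.paths: list[_Chain] = [
            _Chain(Conv3d(ch, ch, k=1), InstanceNorm3d(ch), LeakyReLU(negative_slope))
        ]
        for r in self.rates:
            self.paths.append(_Chain(Conv3d(ch, ch, k=3, dilation=r),
                                     InstanceNorm3d(ch), LeakyReLU(negative_slope)))
        self.pool_path = None
        if variant == "aspp_v3p":
            self.pool_path = _Chain(GlobalAvgPool(), Conv3d(ch, ch, k=1),
                                    LeakyReLU(negative_slope))
        n_paths = len(self.paths) + (1 if self.pool_path else 0)
        self.merge = _Chain(Conv3d(n_paths * ch, ch, k=1), InstanceNorm3d(ch),
                            LeakyReLU(negative_slope))
        self.dropout = Dropout(dropout_p) if (variant == "aspp_v3p" and dropout_p > 0) else None
        self.ch = ch
        self._spatial = None

    def layers(self):
        out = []
        for p in self.paths:
            out.extend(p.layers)
        if self.pool_path is not None:
            out.extend(self.pool_path.layers)
        out.extend(self.merge.layers)
        if self.dropout is not None:
            out.append(self.dropout)
        return out

    def forward(self, x, train=False):
        self._spatial = x.shape[1:]
        outs = [p.forward(x, train) for p in self.paths]
        if self.pool_path is not None:
            pooled = self.pool_path.forward(x, train)  # (C,1,1,1)
            outs.append(np.broadcast_to(pooled, (self.ch, *self._spatial)).astype(DTYPE))
        y = self.merge.forward(np.concatenate(outs, axis=0), train)
        if self.dropout is not None:
            y = self.dropout.forward(y, train)
        return y

    def backward(self, dy):
        if self.dropout is not None:
            dy = self.dropout.backward(dy)
        dcat = self.merge.backward(dy)
        ch = self.ch
        dx = None
        for i, p in enumerate(self.paths):
            d = p.backward(dcat[i * ch:(i + 1) * ch])
            dx = d if dx is None else dx + d
        if self.pool_path is not None:
            i = len(self.paths)
            dpool = dcat[i * ch:(i + 1) * ch].sum(axis=(1, 2, 3), keepdims=True)
            dx = dx + self.pool_path.backward(dpool.astype(DTYPE))
        return dx
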