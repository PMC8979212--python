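"""Minimal 3D neural-network layers on numpy with explicit backpropagation.

All tensors are channel-first without a batch axis: ``(C, X, Y, Z)`` in
float32 (training here runs at batch size 1 with gradient accumulation, so a
batch axis would be dead weight).  Each layer caches what its backward pass
needs during ``forward`` and releases it after ``backward``; convolution
column matrices are recomputed in backward rather than cached, trading a
second im2col pass for a much smaller peak memory footprint.

Convolutions are evaluated as GEMMs on column matrices built from 27 (or
``k^3``) strided slices of the zero-padded input, which supports stride and
dilation uniformly and keeps all heavy arithmetic inside BLAS.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv3d",
    "ConvTranspose3d",
    "InstanceNorm3d",
    "LeakyReLU",
    "Dropout",
    "GlobalAvgPool",
    "kaiming_normal_init",
    "leaky_relu_gain",
]

DTYPE = np.float32


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base class: subclasses implement forward(x, train) and backward(dy)."""

    def parameters(self) -> list[tuple[str, Parameter]]:
        out = []
        for name in sorted(vars(self)):
            val = getattr(self, name)
            if isinstance(val, Parameter):
                out.append((name, val))
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def leaky_relu_gain(negative_slope: float) -> float:
    return float(np.sqrt(2.0 / (1.0 + negative_slope**2)))


def kaiming_normal_init(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator,
                        negative_slope: float = 0.01) -> np.ndarray:
    """He/kaiming-normal weights for leaky-ReLU layers: std = gain / sqrt(fan_in)."""
    std = leaky_relu_gain(negative_slope) / np.sqrt(fan_in)
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


def _out_size(n: int, k: int, stride: int, pad: int, dilation: int) -> int:
    eff = dilation * (k - 1) + 1
    return (n + 2 * pad - eff) // stride + 1


def _im2col(xp: np.ndarray, k: int, stride: tuple[int, int, int],
            dilation: tuple[int, int, int], out_shape: tuple[int, int, int]) -> np.ndarray:
    """Column matrix (C*k^3, ox*oy*oz) from a padded (C, X, Y, Z) array."""
    c = xp.shape[0]
    ox, oy, oz = out_shape
    sx, sy, sz = stride
    dx, dy, dz = dilation
    cols = np.empty((c, k * k * k, ox, oy, oz), dtype=DTYPE)
    for t, (a, b, cc) in enumerate(product(range(k), repeat=3)):
        cols[:, t] = xp[:,
                        a * dx: a * dx + sx * (ox - 1) + 1: sx,
                        b * dy: b * dy + sy * (oy - 1) + 1: sy,
                        cc * dz: cc * dz + sz * (oz - 1) + 1: sz]
    return cols.reshape(c * k * k * k, ox * oy * oz)


def _col2im(dcols: np.ndarray, xp_shape: tuple[int, ...], k: int,
            stride: tuple[int, int, int], dilation: tuple[int, int, int],
            out_shape: tuple[int, int, int]) -> np.ndarray:
    """Scatter-add the column gradient back onto the padded input grid."""
    c = xp_shape[0]
    ox, oy, oz = out_shape
    sx, sy, sz = stride
    dx, dy, dz = dilation
    dxp = np.zeros(xp_shape, dtype=DTYPE)
    dcols = dcols.reshape(c, k * k * k, ox, oy, oz)
    for t, (a, b, cc) in enumerate(product(range(k), repeat=3)):
        dxp[:,
            a * dx: a * dx + sx * (ox - 1) + 1: sx,
            b * dy: b * dy + sy * (oy - 1) + 1: sy,
            cc * dz: cc * dz + sz * (oz - 1) + 1: sz] += dcols[:, t]
    return dxp


class Conv3d(Layer):
    """3D convolution with isotropic kernel, per-axis stride and dilation.

    Padding is chosen so that at stride 1 the spatial shape is preserved
    (``pad = dilation * (k - 1) // 2``); at stride 2 with k=3 the shape
    halves exactly for even inputs.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int = 3,
                 stride: int | tuple[int, int, int] = 1,
                 dilation: int | tuple[int, int, int] = 1):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.stride = (stride,) * 3 if np.isscalar(stride) else tuple(stride)
        self.dilation = (dilation,) * 3 if np.isscalar(dilation) else tuple(dilation)
        self.pad = tuple(d * (k - 1) // 2 for d in self.dilation)
        self.fan_in = in_ch * k**3
        self.weight = Parameter(np.zeros((out_ch, in_ch, k, k, k)))
        self.bias = Parameter(np.zeros(out_ch))
        self._cache = None

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.pad
        if max(p) == 0:
            return x
        return np.pad(x, ((0, 0), (p[0], p[0]), (p[1], p[1]), (p[2], p[2])))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, d, p = self.k, self.stride, self.dilation, self.pad
        oshape = tuple(_out_size(n, k, s[i], p[i], d[i]) for i, n in enumerate(x.shape[1:]))
        if min(oshape) < 1:
            raise ValueError(f"input {x.shape[1:]} too small for kernel {k} dilation {d}")
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if k == 1 and s == (1, 1, 1):
            cols = x.reshape(self.in_ch, -1)  # 1x1x1 conv: plain channel mixing
        else:
            cols = _im2col(self._pad(x), k, s, d, oshape)
        wm = self.weight.data.reshape(self.out_ch, -1)
        y = (wm @ cols) + self.bias.data[:, None]
        # during training the column matrix is kept for the weight-gradient
        # GEMM; in evaluation it is dropped to keep inference memory flat
        self._cache = (x.shape, cols if train else x, oshape, train)
        return np.ascontiguousarray(y.reshape(self.out_ch, *oshape))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cached, oshape, had_cols = self._cache
        self._cache = None
        k, s, d, p = self.k, self.stride, self.dilation, self.pad
        pointwise = k == 1 and s == (1, 1, 1)
        if had_cols:
            cols = cached
        elif pointwise:
            cols = cached.reshape(self.in_ch, -1)
        else:
            cols = _im2col(self._pad(cached), k, s, d, oshape)
        dym = dy.reshape(self.out_ch, -1)
        self.weight.grad += (dym @ cols.T).reshape(self.weight.data.shape)
        self.bias.grad += dym.sum(axis=1)
        del cols
        dcols = self.weight.data.reshape(self.out_ch, -1).T @ dym
        if pointwise:
            return dcols.reshape(self.in_ch, *x_shape[1:])
        xp_shape = (x_shape[0], x_shape[1] + 2 * p[0], x_shape[2] + 2 * p[1],
                    x_shape[3] + 2 * p[2])
        dxp = _col2im(dcols, xp_shape, k, s, d, oshape)
        if max(p) > 0:
            dxp = dxp[:, p[0]: p[0] + x_shape[1], p[1]: p[1] + x_shape[2], p[2]: p[2] + x_shape[3]]
        return dxp


class ConvTranspose3d(Layer):
    """Stride-2, kernel-2 transposed convolution: exact 2x spatial upsampling.

    Each input voxel maps linearly onto a disjoint 2x2x2 output block, so the
    operation is one GEMM plus an axis shuffle in both directions.
    """

    def __init__(self, in_ch: int, out_ch: int):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.fan_in = in_ch  # one input voxel feeds each output voxel
        self.weight = Parameter(np.zeros((in_ch, out_ch * 8)))
        self.bias = Parameter(np.zeros(out_ch))
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c, nx, ny, nz = x.shape
        xm = x.reshape(c, -1)
        y = self.weight.data.T @ xm  # (out*8, N)
        y = y.reshape(self.out_ch, 2, 2, 2, nx, ny, nz)
        y = y.transpose(0, 4, 1, 5, 2, 6, 3).reshape(self.out_ch, 2 * nx, 2 * ny, 2 * nz)
        y += self.bias.data[:, None, None, None]
        self._cache = (x, (nx, ny, nz))
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, (nx, ny, nz) = self._cache
        self._cache = None
        self.bias.grad += dy.sum(axis=(1, 2, 3))
        dyb = dy.reshape(self.out_ch, nx, 2, ny, 2, nz, 2)
        dyb = dyb.transpose(0, 2, 4, 6, 1, 3, 5).reshape(self.out_ch * 8, -1)
        self.weight.grad += x.reshape(self.in_ch, -1) @ dyb.T
        dx = self.weight.data @ dyb
        return dx.reshape(self.in_ch, nx, ny, nz)


class InstanceNorm3d(Layer):
    """Per-channel normalization over the spatial axes with affine params.

    Preferred over batch statistics here because training runs at batch
    size 1, where batch normalization collapses.
    """

    def __init__(self, ch: int, eps: float = 1e-5):
        self.ch, self.eps = ch, eps
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.gamma.data[:, None, None, None] * xhat + self.beta.data[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += dy.sum(axis=(1, 2, 3))
        g = self.gamma.data[:, None, None, None]
        dxhat = dy * g
        m1 = dxhat.mean(axis=(1, 2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(1, 2, 3), keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01):
        self.slope = negative_slope
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x).astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask = self._mask
        self._mask = None
        return np.where(mask, dy, self.slope * dy).astype(DTYPE, copy=False)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        mask = self._mask
        self._mask = None
        return dy * mask


class GlobalAvgPool(Layer):
    """Spatial mean per channel, broadcast back on backward."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3), keepdims=True)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape = self._shape
        self._shape = None
        n = shape[1] * shape[2] * shape[3]
        return np.broadcast_to(dy / n, shape).astype(DTYPE)
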