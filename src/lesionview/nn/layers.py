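"""Layers for the numpy network engine.

Convolutions are im2col + BLAS matmul; their gradients are computed with the
transposed matmuls plus a col2im scatter-add over the (small) set of kernel
offsets.  Layers fed directly by data can be flagged ``first_layer`` so the
input gradient — never needed — is skipped, which saves the most expensive
gemm of the compression convolutions.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, he_uniform


def _as_tuple(v, n: int) -> tuple[int, ...]:
    if np.isscalar(v):
        return (int(v),) * n
    t = tuple(int(x) for x in v)
    assert len(t) == n
    return t


class _ConvNd(Module):
    """Shared im2col convolution for 2 or 3 spatial dimensions."""

    def __init__(self, ndim, in_channels, out_channels, kernel, stride=1,
                 padding=0, bias=True, first_layer=False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.ndim = ndim
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = _as_tuple(kernel, ndim)
        self.stride = _as_tuple(stride, ndim)
        self.padding = _as_tuple(padding, ndim)
        self.has_bias = bias
        self.first_layer = first_layer
        rng = rng or np.random.default_rng()
        fan_in = in_channels * int(np.prod(self.kernel))
        self.add_param("weight", he_uniform(rng, (out_channels, in_channels) + self.kernel, fan_in))
        if bias:
            self.add_param("bias", np.zeros(out_channels, dtype=np.float32))
        self._cache = None

    # spatial output extent: floor((S + 2p - k) / stride) + 1
    def output_extents(self, spatial: tuple[int, ...]) -> tuple[int, ...]:
        return tuple((s + 2 * p - k) // st + 1
                     for s, k, st, p in zip(spatial, self.kernel, self.stride, self.padding))

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if not any(self.padding):
            return x
        pad = [(0, 0), (0, 0)] + [(p, p) for p in self.padding]
        return np.pad(x, pad)

    def _im2col(self, xp: np.ndarray):
        axes = tuple(range(2, 2 + self.ndim))
        win = sliding_window_view(xp, self.kernel, axis=axes)
        sl = (slice(None), slice(None)) + tuple(slice(None, None, s) for s in self.stride)
        win = win[sl]  # (N, C, *out, *kernel)
        out = win.shape[2:2 + self.ndim]
        n = xp.shape[0]
        perm = (0,) + tuple(range(2, 2 + self.ndim)) + (1,) + tuple(range(2 + self.ndim, 2 + 2 * self.ndim))
        cols = win.transpose(perm).reshape(n * int(np.prod(out)), -1)
        return np.ascontiguousarray(cols, dtype=np.float32), out

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        xp = self._pad(x)
        cols, out = self._im2col(xp)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        y = cols @ wmat.T
        if self.has_bias:
            y += self.bias.data
        n = x.shape[0]
        y = y.reshape((n,) + tuple(out) + (self.out_channels,))
        y = np.moveaxis(y, -1, 1)
        if self.training:
            self._cache = (cols, x.shape, out)
        return np.ascontiguousarray(y)

    def backward(self, grad: np.ndarray) -> np.ndarray | None:
        cols, x_shape, out = self._cache
        n = x_shape[0]
        gyf = np.moveaxis(grad, 1, -1).reshape(-1, self.out_channels)
        gyf = np.ascontiguousarray(gyf, dtype=np.float32)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        self.weight.grad += (gyf.T @ cols).reshape(self.weight.data.shape)
        if self.has_bias:
            self.bias.grad += gyf.sum(axis=0)
        if self.first_layer:
            self._cache = None
            return None
        dcols = gyf @ wmat  # (N*prod(out), C*prod(k))
        dcols = dcols.reshape((n,) + tuple(out) + (self.in_channels,) + self.kernel)
        # move channel axis next to batch: (N, C, *out, *kernel)
        dcols = np.moveaxis(dcols, 1 + self.ndim, 1)
        padded_shape = tuple(s + 2 * p for s, p in zip(x_shape[2:], self.padding))
        dxp = np.zeros((n, self.in_channels) + padded_shape, dtype=np.float32)
        for offset in np.ndindex(*self.kernel):
            sl = tuple(slice(o, o + (e - 1) * s + 1, s)
                       for o, e, s in zip(offset, out, self.stride))
            dxp[(slice(None), slice(None)) + sl] += dcols[(Ellipsis,) + offset]
        if any(self.padding):
            core = tuple(slice(p, p + s) for p, s in zip(self.padding, x_shape[2:]))
            dxp = dxp[(slice(None), slice(None)) + core]
        self._cache = None
        return dxp


class Conv2d(_ConvNd):
    def __init__(self, in_channels, out_channels, kernel, **kw):
        super().__init__(2, in_channels, out_channels, kernel, **kw)


class Conv3d(_ConvNd):
    def __init__(self, in_channels, out_channels, kernel, **kw):
        super().__init__(3, in_channels, out_channels, kernel, **kw)


class BatchNorm(Module):
    """Batch normalisation over (batch, *spatial) per channel.

    ``affine=False`` keeps the normalisation but contributes no learnable
    parameters; running statistics are buffers in either case.
    """

    def __init__(self, num_features: int, affine: bool = True,
                 eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.affine = affine
        self.eps = eps
        self.momentum = momentum
        if affine:
            self.add_param("weight", np.ones(num_features, dtype=np.float32))
            self.add_param("bias", np.zeros(num_features, dtype=np.float32))
        self.add_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.add_buffer("running_var", np.ones(num_features, dtype=np.float32))
        self._cache = None

    def _bshape(self, ndim: int):
        return (1, self.num_features) + (1,) * (ndim - 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x.ndim)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // self.num_features
            m = self.momentum
            self.set_buffer("running_mean",
                            ((1 - m) * self.running_mean + m * mean).astype(np.float32))
            unbiased = var * (n / max(n - 1, 1))
            self.set_buffer("running_var",
                            ((1 - m) * self.running_var + m * unbiased).astype(np.float32))
        else:
            mean = self.running_mean
            var = self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        xhat = xhat.astype(np.float32, copy=False)
        if self.training:
            self._cache = (xhat, invstd.astype(np.float32), axes, shape)
        if self.affine:
            return self.weight.data.reshape(shape) * xhat + self.bias.data.reshape(shape)
        return xhat

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, invstd, axes, shape = self._cache
        if self.affine:
            self.weight.grad += (grad * xhat).sum(axis=axes)
            self.bias.grad += grad.sum(axis=axes)
            gyh = grad * self.weight.data.reshape(shape)
        else:
            gyh = grad
        n = grad.size // self.num_features
        mean_g = gyh.mean(axis=axes).reshape(shape)
        mean_gx = (gyh * xhat).mean(axis=axes).reshape(shape)
        dx = invstd.reshape(shape) * (gyh - mean_g - xhat * mean_gx)
        self._cache = None
        return dx.astype(np.float32, copy=False)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if self.training:
            self._mask = x > 0
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._mask
        self._mask = None
        return g


class _MaxPoolNd(Module):
    def __init__(self, ndim, kernel, stride, padding):
        super().__init__()
        self.ndim = ndim
        self.kernel = _as_tuple(kernel, ndim)
        self.stride = _as_tuple(stride, ndim)
        self.padding = _as_tuple(padding, ndim)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        pad = [(0, 0), (0, 0)] + [(p, p) for p in self.padding]
        xp = np.pad(x, pad, constant_values=-np.inf) if any(self.padding) else x
        axes = tuple(range(2, 2 + self.ndim))
        win = sliding_window_view(xp, self.kernel, axis=axes)
        sl = (slice(None), slice(None)) + tuple(slice(None, None, s) for s in self.stride)
        win = win[sl]
        out = win.shape[2:2 + self.ndim]
        flat = win.reshape(win.shape[:2 + self.ndim] + (-1,))
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if self.training:
            self._cache = (idx, x.shape, xp.shape, out)
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, x_shape, xp_shape, out = self._cache
        kk = int(np.prod(self.kernel))
        dwin = np.zeros(grad.shape + (kk,), dtype=np.float32)
        np.put_along_axis(dwin, idx[..., None], grad[..., None].astype(np.float32), axis=-1)
        dwin = dwin.reshape(grad.shape + self.kernel)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for offset in np.ndindex(*self.kernel):
            sl = tuple(slice(o, o + (e - 1) * s + 1, s)
                       for o, e, s in zip(offset, out, self.stride))
            dxp[(slice(None), slice(None)) + sl] += dwin[(Ellipsis,) + offset]
        if any(self.padding):
            core = tuple(slice(p, p + s) for p, s in zip(self.padding, x_shape[2:]))
            dxp = dxp[(slice(None), slice(None)) + core]
        self._cache = None
        return dxp


class MaxPool2d(_MaxPoolNd):
    def __init__(self, kernel=3, stride=2, padding=1):
        super().__init__(2, kernel, stride, padding)


class MaxPool3d(_MaxPoolNd):
    def __init__(self, kernel=3, stride=2, padding=1):
        super().__init__(3, kernel, stride, padding)


class GlobalAvgPool(Module):
    """Mean over all spatial axes: (N, C, *spatial) -> (N, C)."""

    def __init__(self):
        super().__init__()
        self._spatial = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._spatial = x.shape[2:]
        return x.mean(axis=tuple(range(2, x.ndim))).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        scale = 1.0 / float(np.prod(self._spatial))
        g = grad.reshape(grad.shape + (1,) * len(self._spatial)) * scale
        return np.broadcast_to(g, grad.shape + self._spatial).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_features = in_features
        self.out_features = out_features
        self.has_bias = bias
        self.add_param("weight", he_uniform(rng, (out_features, in_features), in_features))
        if bias:
            self.add_param("bias", np.zeros(out_features, dtype=np.float32))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            self._x = x
        y = x @ self.weight.data.T
        if self.has_bias:
            y += self.bias.data
        return y.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        if self.has_bias:
            self.bias.grad += grad.sum(axis=0)
        dx = grad @ self.weight.data
        self._x = None
        return dx.astype(np.float32)


class Dropout(Module):
    """Inverted dropout; identity when evaluating or when rate is 0."""

    def __init__(self, rate: float):
        super().__init__()
        self.rate = float(rate)
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate <= 0.0:
            return x
        rng = self.rng if self.rng is not None else np.random.default_rng()
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g
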