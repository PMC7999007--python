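"""A small, self-contained numpy training core for 3D convolutional networks.

Implements exactly the layer set the package's two networks need: 3D
convolution (stride 1, odd kernels, 'same' padding) as one BLAS GEMM per
layer over a numba-built patch matrix, batch normalization, ReLU,
max/average pooling in 'same' (ceil) mode, nearest-neighbor upsampling,
dense layers, softmax cross-entropy and the Adam optimizer.  Tensors are
(N, C, X, Y, Z) float32; all gradients are exact analytic backward passes
(verified against numerical differentiation in the test suite).
"""

from __future__ import annotations

from itertools import product

import numpy as np

from . import _kernels
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param", "Layer", "Conv3d", "BatchNorm", "ReLU", "MaxPool3d",
    "AvgPool3d", "Upsample3d", "Flatten", "Dense", "Sequential",
    "softmax", "softmax_cross_entropy", "Adam",
]


class Param:
    __slots__ = ("val", "grad")

    def __init__(self, val: np.ndarray):
        self.val = np.asarray(val, dtype=np.float32)
        self.grad = np.zeros_like(self.val)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d(Layer):
    """3D convolution, stride 1, odd cubic kernel, 'same' zero padding."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.cin, self.cout, self.k = cin, cout, k
        self.w = Param(_he_init(rng, (cin * k**3, cout), cin * k**3))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._cache = None
        self._buffers: dict = {}  # shape-keyed scratch, reused across steps

    def _buf(self, name, shape, zero=False):
        buf = self._buffers.get(name)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, np.float32)
            self._buffers[name] = buf
        if zero:
            buf[...] = 0.0
        return buf

    def params(self):
        return [self.w, self.b]

    @property
    def _wt(self) -> np.ndarray:
        # (C*k^3, F) column layout -> (F, C, k, k, k) tap layout
        return np.ascontiguousarray(
            self.w.val.T.reshape(self.cout, self.cin, self.k, self.k, self.k)
        )

    @staticmethod
    def _direct(k: int, d: int, h: int, w: int) -> bool:
        # on maps comparable to the kernel most 'same'-padding taps are
        # zero; the direct kernel skips them and beats im2col + GEMM
        return k > 1 and d * h * w <= 16

    def forward(self, x, train=False):
        n, c, d, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {c}")
        x = np.ascontiguousarray(x, dtype=np.float32)
        if self._direct(self.k, d, h, w):
            out = _kernels.conv3d_direct_forward(x, self._wt, self.b.val)
            if train:
                self._cache = (x, x.shape)
            return out
        p = self.k // 2
        if self.k == 1:
            cols = self._buf("cols", (c, n * d * h * w))
            cols.reshape(c, n, d, h, w)[...] = x.transpose(1, 0, 2, 3, 4)
        else:
            xp = self._buf(
                "xp", (n, c, d + 2 * p, h + 2 * p, w + 2 * p), zero=True
            )
            xp[:, :, p:p + d, p:p + h, p:p + w] = x
            cols = self._buf("cols", (c * self.k**3, n * d * h * w))
            _kernels.im2col(xp, self.k, d, h, w, cols)
        # one GEMM per layer: (F, C*k^3) @ (C*k^3, N*P)
        out = self._buf("out", (self.cout, n * d * h * w))
        np.matmul(self.w.val.T, cols, out=out)
        out += self.b.val[:, None]
        if train:
            self._cache = (cols, x.shape)
        return np.ascontiguousarray(
            out.reshape(self.cout, n, d, h, w).transpose(1, 0, 2, 3, 4)
        )

    def backward(self, dout):
        cached, xshape = self._cache
        n, c, d, h, w = xshape
        k, p = self.k, self.k // 2
        self._cache = None
        dout = np.ascontiguousarray(dout, dtype=np.float32)
        if self._direct(k, d, h, w):
            dx, dw, db = _kernels.conv3d_direct_backward(
                cached, self._wt, dout
            )
            self.w.grad += dw.reshape(self.cout, -1).T
            self.b.grad += db
            return dx
        cols = cached
        dmat = self._buf("dmat", (self.cout, n * d * h * w))
        dmat.reshape(self.cout, n, d, h, w)[...] = dout.transpose(
            1, 0, 2, 3, 4
        )
        self.w.grad += (dmat @ cols.T).T
        self.b.grad += dmat.sum(axis=1)
        dcols = self._buf("dcols", cols.shape)
        np.matmul(self.w.val, dmat, out=dcols)  # (C*k^3, N*P)
        if k == 1:
            return np.ascontiguousarray(
                dcols.reshape(c, n, d, h, w).transpose(1, 0, 2, 3, 4)
            )
        dxp = self._buf(
            "dxp", (n, c, d + 2 * p, h + 2 * p, w + 2 * p), zero=True
        )
        _kernels.col2im(dcols, k, d, h, w, dxp)
        return dxp[:, :, p:p + d, p:p + h, p:p + w]


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, spatial) with running stats."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    @staticmethod
    def _shape(x):
        # channel axis is 1; reduce over all other axes
        axes = (0,) + tuple(range(2, x.ndim))
        bshape = (1, -1) + (1,) * (x.ndim - 2)
        return axes, bshape

    def forward(self, x, train=False):
        x = x.astype(np.float32, copy=False)
        axes, bshape = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bshape)) / std.reshape(bshape)
        if train:
            self._cache = (xhat, std, axes, bshape)
        return self.gamma.val.reshape(bshape) * xhat + self.beta.val.reshape(bshape)

    def backward(self, dout):
        xhat, std, axes, bshape = self._cache
        m = dout.size // dout.shape[1]
        dg = (dout * xhat).sum(axis=axes)
        db = dout.sum(axis=axes)
        self.gamma.grad += dg
        self.beta.grad += db
        g = self.gamma.val.reshape(bshape)
        dx = (g / (m * std.reshape(bshape))) * (
            m * dout - db.reshape(bshape) - xhat * dg.reshape(bshape)
        )
        self._cache = None
        return dx.astype(np.float32, copy=False)


class ReLU(Layer):
    def forward(self, x, train=False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


def _pool_geometry(shape, k: int, s: int):
    """'Same' (ceil-mode) pooling geometry: per-axis output size and
    asymmetric padding so every input voxel belongs to some window."""
    nout, pad_lo, pad_hi = [], [], []
    for n in shape:
        o = -(-n // s)  # ceil(n / s)
        total = max((o - 1) * s + k - n, 0)
        nout.append(o)
        pad_lo.append(total // 2)
        pad_hi.append(total - total // 2)
    return nout, pad_lo, pad_hi


class _Pool3d(Layer):
    """Stride-s pooling with 'same' (ceil-mode) windows.

    Output size is ceil(n/s) per axis; windows at the border are padded
    (-inf for max, excluded-from-mean for average), so arbitrarily deep
    pooling stacks stay well defined down to single-voxel maps.
    """

    def __init__(self, k: int, stride: int):
        self.k, self.s = k, stride
        self._buffers: dict = {}

    def _buf(self, name, shape, dtype=np.float32, fill=None):
        buf = self._buffers.get(name)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype)
            self._buffers[name] = buf
        if fill is not None:
            buf[...] = fill
        return buf

    def _windows(self, x, fill):
        nout, plo, phi = _pool_geometry(x.shape[2:], self.k, self.s)
        xp = np.pad(
            x, ((0, 0), (0, 0)) + tuple(zip(plo, phi)),
            constant_values=fill,
        )
        win = sliding_window_view(xp, (self.k,) * 3, axis=(2, 3, 4))
        return win[:, :, ::self.s, ::self.s, ::self.s], nout, plo, xp.shape


class MaxPool3d(_Pool3d):
    def forward(self, x, train=False):
        x = x.astype(np.float32, copy=False)
        n, c = x.shape[:2]
        nout, plo, phi = _pool_geometry(x.shape[2:], self.k, self.s)
        pshape = (n, c) + tuple(
            s + a + b for s, a, b in zip(x.shape[2:], plo, phi)
        )
        xp = self._buf("xp", pshape, fill=-np.inf)
        sl = tuple(slice(p, p + s) for p, s in zip(plo, x.shape[2:]))
        xp[(slice(None), slice(None)) + sl] = x
        out = self._buf("out", (n, c) + tuple(nout))
        idx = self._buf("idx", (n, c) + tuple(nout), dtype=np.int32)
        _kernels.maxpool3d_forward(xp, self.k, self.s, out, idx)
        if train:
            self._cache = (idx, plo, pshape, x.shape)
        return out

    def backward(self, dout):
        idx, plo, pshape, xshape = self._cache
        self._cache = None
        dxp = self._buf("dxp", pshape, fill=0.0)
        _kernels.maxpool3d_backward(
            np.ascontiguousarray(dout, dtype=np.float32), idx,
            self.k, self.s, dxp,
        )
        sl = tuple(slice(p, p + s) for p, s in zip(plo, xshape[2:]))
        return dxp[(slice(None), slice(None)) + sl]


class AvgPool3d(_Pool3d):
    """Average pooling over the valid (unpadded) part of each window."""

    def forward(self, x, train=False):
        win, nout, plo, pshape = self._windows(
            x.astype(np.float32, copy=False), 0.0
        )
        counts = self._valid_counts(x.shape[2:], nout)
        out = win.sum(axis=(-3, -2, -1)) / counts
        if train:
            self._cache = (counts, nout, plo, pshape, x.shape)
        return out

    def _valid_counts(self, shape, nout):
        ones = np.ones((1, 1) + tuple(shape), np.float32)
        win, _, _, _ = self._windows(ones, 0.0)
        return win.sum(axis=(-3, -2, -1))[0, 0]

    def backward(self, dout):
        counts, nout, plo, pshape, xshape = self._cache
        dxp = np.zeros(pshape, np.float32)
        scaled = dout / counts
        for a, b, d in product(range(self.k), repeat=3):
            dxp[:, :,
                a:a + nout[0] * self.s:self.s,
                b:b + nout[1] * self.s:self.s,
                d:d + nout[2] * self.s:self.s] += scaled
        self._cache = None
        sl = tuple(slice(p, p + s) for p, s in zip(plo, xshape[2:]))
        return dxp[(slice(None), slice(None)) + sl]


class Upsample3d(Layer):
    """Nearest-neighbor upsampling by an integer factor per spatial axis."""

    def __init__(self, factor: int = 2):
        self.f = factor

    def forward(self, x, train=False):
        f = self.f
        self._inshape = x.shape
        return x.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)

    def backward(self, dout):
        n, c, d, h, w = self._inshape
        f = self.f
        return dout.reshape(n, c, d, f, h, f, w, f).sum(axis=(3, 5, 7))


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        self.w = Param(_he_init(rng, (fin, fout), fin))
        self.b = Param(np.zeros(fout, dtype=np.float32))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.w.val + self.b.val

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.val.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train=train)
        return x

    def backward(self, dout):
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout

    def n_params(self) -> int:
        return sum(p.val.size for p in self.params())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over rows; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(np.float32).tiny
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.val) for p in params]
        self.v = [np.zeros_like(p.val) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.val -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def iter_layers(model):
    """Depth-first iteration over primitive layers."""
    if isinstance(model, Sequential):
        for lay in model.layers:
            yield from iter_layers(lay)
    elif hasattr(model, "flat_layers"):
        for lay in model.flat_layers():
            yield from iter_layers(lay)
    else:
        yield model


def clear_caches(model) -> None:
    for lay in iter_layers(model):
        if hasattr(lay, "_cache"):
            lay._cache = None
        for attr in ("_mask", "_x"):
            if hasattr(lay, attr):
                setattr(lay, attr, None)


def recalibrate_batchnorm(model, batches) -> None:
    """Replace BN running statistics with population statistics.

    ``batches`` yields input arrays; each is forwarded in training mode
    while the BN momentum follows a cumulative-average schedule, leaving
    ``run_mean``/``run_var`` equal to the mean batch statistics over the
    calibration stream.  Small-batch training leaves exponentially-averaged
    statistics noisy enough to hurt inference; this pass fixes them.
    """
    bns = [lay for lay in iter_layers(model) if isinstance(lay, BatchNorm)]
    if not bns:
        return
    saved = [lay.momentum for lay in bns]
    for t, x in enumerate(batches):
        for lay in bns:
            lay.momentum = t / (t + 1.0)
        model.forward(x, train=True)
    for lay, m in zip(bns, saved):
        lay.momentum = m
    clear_caches(model)
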