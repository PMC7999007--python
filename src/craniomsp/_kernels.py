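"""Numba-compiled inner kernels: im2col/col2im and max pooling.

im2col emits a global (C*k^3, N*P) patch matrix so each convolution runs as
a single BLAS GEMM.  All kernels are deterministic; fastmath only relaxes
the floating-point accumulation order.
"""

from __future__ import annotations

import numba
import numpy as np

_jit = numba.njit(cache=True, fastmath=True)


@_jit
def maxpool3d_forward(xp, k, s, out, idx):
    """xp: (-inf)-padded input; fills (out, argmax flat window index)."""
    n, c = xp.shape[0], xp.shape[1]
    d, h, w = out.shape[2], out.shape[3], out.shape[4]
    for ni in range(n):
        for ci in range(c):
            for di in range(d):
                for hi in range(h):
                    for wi in range(w):
                        best = np.float32(-np.inf)
                        bi = 0
                        o = 0
                        for i in range(k):
                            for j in range(k):
                                for l in range(k):
                                    v = xp[ni, ci, di * s + i,
                                           hi * s + j, wi * s + l]
                                    if v > best:
                                        best = v
                                        bi = o
                                    o += 1
                        out[ni, ci, di, hi, wi] = best
                        idx[ni, ci, di, hi, wi] = bi


@_jit
def maxpool3d_backward(dout, idx, k, s, dxp):
    n, c = dout.shape[0], dout.shape[1]
    d, h, w = dout.shape[2], dout.shape[3], dout.shape[4]
    for ni in range(n):
        for ci in range(c):
            for di in range(d):
                for hi in range(h):
                    for wi in range(w):
                        o = idx[ni, ci, di, hi, wi]
                        l = o % k
                        j = (o // k) % k
                        i = o // (k * k)
                        dxp[ni, ci, di * s + i, hi * s + j, wi * s + l] += (
                            dout[ni, ci, di, hi, wi]
                        )


@_jit
def im2col(xp, k, d, h, w, cols):
    """Padded input (N, C, ...) -> patch matrix (C*k^3, N*d*h*w).

    The global column layout feeds a single BLAS GEMM per layer; ``cols``
    is a caller-provided buffer (reused across steps to avoid page-fault
    churn from repeated large allocations).
    """
    n, c = xp.shape[0], xp.shape[1]
    P = d * h * w
    for ci in range(c):
        o = 0
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    row = ci * k**3 + o
                    for ni in range(n):
                        p = ni * P
                        for di in range(d):
                            for hi in range(h):
                                src = xp[ni, ci, di + i, hi + j]
                                for wi in range(w):
                                    cols[row, p] = src[l + wi]
                                    p += 1
                    o += 1
    return cols


@_jit
def col2im(dcols, k, d, h, w, dxp):
    """Scatter-add (C*k^3, N*P) patch gradients onto the zeroed padded
    grid buffer ``dxp`` (caller-provided, reused across steps)."""
    n, c = dxp.shape[0], dxp.shape[1]
    P = d * h * w
    for ci in range(c):
        o = 0
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    row = ci * k**3 + o
                    for ni in range(n):
                        p = ni * P
                        for di in range(d):
                            for hi in range(h):
                                dst = dxp[ni, ci, di + i, hi + j]
                                for wi in range(w):
                                    dst[l + wi] += dcols[row, p]
                                    p += 1
                    o += 1
    return dxp


@_jit
def conv3d_direct_forward(x, wt, bias):
    """Direct convolution for small feature maps: only in-bounds taps.

    Avoids materializing an im2col matrix whose entries are mostly
    'same'-padding zeros when the kernel is large relative to the map.
    """
    n, c, d, h, w = x.shape
    f_out, k = wt.shape[0], wt.shape[2]
    p = k // 2
    out = np.empty((n, f_out, d, h, w), np.float32)
    for ni in range(n):
        for f in range(f_out):
            for di in range(d):
                for hi in range(h):
                    for wi in range(w):
                        acc = bias[f]
                        for i in range(max(0, p - di), min(k, d + p - di)):
                            si = di + i - p
                            for j in range(max(0, p - hi),
                                           min(k, h + p - hi)):
                                sj = hi + j - p
                                for l in range(max(0, p - wi),
                                               min(k, w + p - wi)):
                                    sl = wi + l - p
                                    for ci in range(c):
                                        acc += (wt[f, ci, i, j, l]
                                                * x[ni, ci, si, sj, sl])
                        out[ni, f, di, hi, wi] = acc
    return out


@_jit
def conv3d_direct_backward(x, wt, dout):
    """Gradients (dx, dw, db) for the direct small-map convolution."""
    n, c, d, h, w = x.shape
    f_out, k = wt.shape[0], wt.shape[2]
    p = k // 2
    dx = np.zeros_like(x)
    dw = np.zeros_like(wt)
    db = np.zeros(f_out, np.float32)
    for ni in range(n):
        for f in range(f_out):
            for di in range(d):
                for hi in range(h):
                    for wi in range(w):
                        g = dout[ni, f, di, hi, wi]
                        db[f] += g
                        for i in range(max(0, p - di), min(k, d + p - di)):
                            si = di + i - p
                            for j in range(max(0, p - hi),
                                           min(k, h + p - hi)):
                                sj = hi + j - p
                                for l in range(max(0, p - wi),
                                               min(k, w + p - wi)):
                                    sl = wi + l - p
                                    for ci in range(c):
                                        dw[f, ci, i, j, l] += (
                                            g * x[ni, ci, si, sj, sl])
                                        dx[ni, ci, si, sj, sl] += (
                                            g * wt[f, ci, i, j, l])
    return dx, dw, db
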