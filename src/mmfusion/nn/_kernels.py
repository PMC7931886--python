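"""JIT-compiled im2col/col2im kernels for the convolution layer.

The GEMMs stay in BLAS; these kernels only gather/scatter the convolution
windows, avoiding the strided-copy overhead of a pure NumPy implementation.
Column order is (kernel_row, kernel_col, channel) — channel innermost for
contiguous access — matching the ``(kh, kw, C, O)`` weight layout flattened to
``(kh*kw*C, O)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def im2col(xp, kh, kw, s, ho, wo):
    n, hp, wp, c = xp.shape
    out = np.empty((n * ho * wo, kh * kw * c), dtype=xp.dtype)
    row = 0
    for b in range(n):
        for y in range(ho):
            ys = y * s
            for x in range(wo):
                xs = x * s
                col = 0
                for i in range(kh):
                    for j in range(kw):
                        for cc in range(c):
                            out[row, col] = xp[b, ys + i, xs + j, cc]
                            col += 1
                row += 1
    return out


@njit(cache=True)
def adam_update(p, g, m, v, lr, b1, b2, eps, bias1, bias2):
    n = p.size
    for i in range(n):
        m[i] = b1 * m[i] + (1.0 - b1) * g[i]
        v[i] = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
        p[i] -= lr * (m[i] / bias1) / (np.sqrt(v[i] / bias2) + eps)


@njit(cache=True)
def bn_forward_train(xf, eps):
    """Single-thread fused batch-norm statistics + normalisation.

    Returns (xhat, mean, var, inv_std) for a 2-D (rows, channels) view.
    """
    m, c = xf.shape
    mean = np.zeros(c, dtype=xf.dtype)
    for i in range(m):
        for j in range(c):
            mean[j] += xf[i, j]
    for j in range(c):
        mean[j] /= m
    var = np.zeros(c, dtype=xf.dtype)
    for i in range(m):
        for j in range(c):
            d = xf[i, j] - mean[j]
            var[j] += d * d
    inv_std = np.empty(c, dtype=xf.dtype)
    for j in range(c):
        var[j] /= m
        inv_std[j] = 1.0 / np.sqrt(var[j] + eps)
    xhat = np.empty_like(xf)
    for i in range(m):
        for j in range(c):
            xhat[i, j] = (xf[i, j] - mean[j]) * inv_std[j]
    return xhat, mean, var, inv_std


@njit(cache=True)
def bn_backward(gf, xhat, inv_std, gamma):
    """Fused batch-norm backward; returns (dx, dgamma, dbeta)."""
    m, c = gf.shape
    dgamma = np.zeros(c, dtype=gf.dtype)
    dbeta = np.zeros(c, dtype=gf.dtype)
    for i in range(m):
        for j in range(c):
            dgamma[j] += gf[i, j] * xhat[i, j]
            dbeta[j] += gf[i, j]
    a = np.empty(c, dtype=gf.dtype)
    mg = np.empty(c, dtype=gf.dtype)
    mgx = np.empty(c, dtype=gf.dtype)
    for j in range(c):
        a[j] = inv_std[j] * gamma[j]
        mg[j] = dbeta[j] / m
        mgx[j] = dgamma[j] / m
    dx = np.empty_like(gf)
    for i in range(m):
        for j in range(c):
            dx[i, j] = a[j] * (gf[i, j] - mg[j] - xhat[i, j] * mgx[j])
    return dx, dgamma, dbeta


@njit(cache=True)
def maxpool2x2_forward(x):
    """2x2/2 max pooling with argmax bookkeeping (index 0..3 per window)."""
    n, h, w, c = x.shape
    ho, wo = h // 2, w // 2
    out = np.empty((n, ho, wo, c), dtype=x.dtype)
    arg = np.empty((n, ho, wo, c), dtype=np.uint8)
    for b in range(n):
        for y in range(ho):
            for xx in range(wo):
                for cc in range(c):
                    best = x[b, 2 * y, 2 * xx, cc]
                    k = 0
                    v = x[b, 2 * y, 2 * xx + 1, cc]
                    if v > best:
                        best, k = v, 1
                    v = x[b, 2 * y + 1, 2 * xx, cc]
                    if v > best:
                        best, k = v, 2
                    v = x[b, 2 * y + 1, 2 * xx + 1, cc]
                    if v > best:
                        best, k = v, 3
                    out[b, y, xx, cc] = best
                    arg[b, y, xx, cc] = k
    return out, arg


@njit(cache=True)
def maxpool2x2_backward(grad, arg, h, w):
    n, ho, wo, c = grad.shape
    dx = np.zeros((n, h, w, c), dtype=grad.dtype)
    for b in range(n):
        for y in range(ho):
            for xx in range(wo):
                for cc in range(c):
                    k = arg[b, y, xx, cc]
                    dx[b, 2 * y + (k >> 1), 2 * xx + (k & 1), cc] = grad[b, y, xx, cc]
    return dx


@njit(cache=True)
def col2im_add(dcols, n, hp, wp, c, kh, kw, s, ho, wo):
    dxp = np.zeros((n, hp, wp, c), dtype=dcols.dtype)
    row = 0
    for b in range(n):
        for y in range(ho):
            ys = y * s
            for x in range(wo):
                xs = x * s
                col = 0
                for i in range(kh):
                    for j in range(kw):
                        for cc in range(c):
                            dxp[b, ys + i, xs + j, cc] += dcols[row, col]
                            col += 1
                row += 1
    return dxp
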