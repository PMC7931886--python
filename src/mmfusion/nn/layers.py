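"""Minimal trainable layer library on NumPy arrays.

All image-like tensors use the NHWC layout ``(batch, height, width, channels)``
in a configurable floating dtype (float32 by default, see :func:`set_dtype`).
Every layer implements ``forward(x, train)`` and
``backward(grad)``; ``backward`` accumulates parameter gradients in
``Parameter.grad`` and returns the gradient with respect to the layer input.
Gradients of every layer are verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._kernels import (bn_backward, bn_forward_train, col2im_add, im2col,
                       maxpool2x2_backward, maxpool2x2_forward)

_DTYPE = np.float32  # training dtype; float64 available for gradient checking


def set_dtype(dtype) -> None:
    """Set the floating dtype used by newly created layers and forward passes.

    float32 (default) is preferred for training throughput; gradient-check
    tests switch to float64 for accurate finite differences.
    """
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


def get_dtype():
    return _DTYPE


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=_DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class; stateless layers only override forward/backward."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def params(self) -> list[Parameter]:
        return []

    def children(self) -> list["Layer"]:
        return []


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2D(Layer):
    """2-D convolution (cross-correlation) with optional zero padding.

    Kernels may be rectangular; a kernel spanning the full input width turns the
    layer into a "wide" text convolution that slides along the token axis only.
    """

    def __init__(self, in_ch: int, out_ch: int, kh: int, kw: int,
                 stride: int = 1, pad: int | str = "same",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = kh * kw * in_ch
        self.kh, self.kw, self.stride = kh, kw, stride
        if pad == "same":
            # same-size output for stride 1 (asymmetric for even kernels)
            self.pad = ((kh - 1) // 2, kh - 1 - (kh - 1) // 2,
                        (kw - 1) // 2, kw - 1 - (kw - 1) // 2)
        elif pad == "valid" or pad == 0:
            self.pad = (0, 0, 0, 0)
        else:
            p = int(pad)
            self.pad = (p, p, p, p)
        self.w = Parameter("conv_w", _he_init(rng, (kh, kw, in_ch, out_ch), fan_in))
        self.b = Parameter("conv_b", np.zeros(out_ch))
        self._cols = None
        self._xshape = None

    @property
    def params(self) -> list[Parameter]:
        return [self.w, self.b]

    def _pad_input(self, x: np.ndarray) -> np.ndarray:
        pt, pb, pl, pr = self.pad
        if pt or pb or pl or pr:
            return np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        xp = self._pad_input(np.asarray(x, dtype=_DTYPE))
        s = self.stride
        n, hp, wp = xp.shape[:3]
        ho = (hp - self.kh) // s + 1
        wo = (wp - self.kw) // s + 1
        mat = im2col(xp, self.kh, self.kw, s, ho, wo)
        out_ch = self.w.value.shape[-1]
        wflat = self.w.value.reshape(-1, out_ch)
        out = (mat @ wflat + self.b.value).reshape(n, ho, wo, out_ch)
        self._mat = mat if train else None
        self._xshape = x.shape
        self._xpshape = xp.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mat = self._mat
        if mat is None:
            raise RuntimeError("backward called without a training forward pass")
        n, ho, wo, out_ch = grad.shape
        gf = np.ascontiguousarray(grad.reshape(-1, out_ch))
        wflat = self.w.value.reshape(-1, out_ch)
        self.w.grad += (mat.T @ gf).reshape(self.w.value.shape)
        self.b.grad += gf.sum(axis=0)
        pt, pb, pl, pr = self.pad
        h, w = self._xshape[1], self._xshape[2]
        _, hp, wp, c = self._xpshape
        dcols = gf @ wflat.T
        dxp = col2im_add(dcols, n, hp, wp, c, self.kh, self.kw, self.stride,
                         ho, wo)
        return dxp[:, pt:pt + h, pl:pl + w, :]


class Pool2D(Layer):
    """Max or average pooling with square kernel/stride."""

    def __init__(self, size: int = 2, stride: int | None = None,
                 pad: int = 0, kind: str = "max"):
        self.size = size
        self.stride = stride or size
        self.pad = pad
        if kind not in ("max", "avg"):
            raise ValueError(f"unknown pooling kind {kind!r}")
        self.kind = kind
        self._cache = None

    def _fast_path(self, x: np.ndarray) -> bool:
        return (self.pad == 0 and self.stride == self.size
                and x.shape[1] % self.size == 0 and x.shape[2] % self.size == 0)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        s, k = self.stride, self.size
        if self.kind == "max" and k == 2 and self._fast_path(x):
            out, arg = maxpool2x2_forward(np.ascontiguousarray(x))
            if train:
                self._cache = ("max2", x.shape, arg, out)
            return out
        if self._fast_path(x):
            n, h, w, c = x.shape
            blocks = x.reshape(n, h // k, k, w // k, k, c)
            out = blocks.max(axis=(2, 4)) if self.kind == "max" \
                else blocks.mean(axis=(2, 4))
            if train:
                self._cache = ("fast", x.shape, blocks if self.kind == "max" else None, out)
            return out
        if self.pad:
            p = self.pad
            fill = -np.inf if self.kind == "max" else 0.0
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), constant_values=fill)
        else:
            xp = x
        wins = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        if self.kind == "max":
            out = wins.max(axis=(4, 5))
        else:
            out = wins.mean(axis=(4, 5))
        if train:
            self._cache = ("slow", (x.shape, xp.shape),
                           wins if self.kind == "max" else None, out)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        path, shapes, wins, out = self._cache
        s, k = self.stride, self.size
        if path == "max2":
            # gradient routed to the first element attaining the window maximum
            return maxpool2x2_backward(np.ascontiguousarray(grad), wins,
                                       shapes[1], shapes[2])
        if path == "fast":
            n, ho, wo, c = grad.shape
            if self.kind == "max":
                # gradient routed to every element attaining the block maximum
                mask = wins == out[:, :, None, :, None, :]
                dx = mask * grad[:, :, None, :, None, :]
            else:
                dx = np.broadcast_to(grad[:, :, None, :, None, :] / (k * k),
                                     (n, ho, k, wo, k, c))
            return dx.reshape(shapes)
        xshape, xpshape = shapes
        dxp = np.zeros(xpshape, dtype=grad.dtype)
        n, ho, wo = grad.shape[:3]
        if self.kind == "max":
            mask = wins == out[..., None, None]
            contrib = mask * grad[..., None, None]
        else:
            contrib = np.broadcast_to(grad[..., None, None] / (k * k),
                                      grad.shape + (k, k))
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + ho * s:s, j:j + wo * s:s, :] += contrib[..., i, j]
        p = self.pad
        if p:
            return dxp[:, p:p + xshape[1], p:p + xshape[2], :]
        return dxp


class GlobalMaxPool(Layer):
    """Max over the spatial axes; standard max-over-time pooling for text CNNs."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        out = x.max(axis=(1, 2))
        if train:
            self._cache = (x, out)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, out = self._cache
        mask = x == out[:, None, None, :]
        return mask * grad[:, None, None, :]


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Parameter("dense_w", _he_init(rng, (in_dim, out_dim), in_dim))
        self.b = Parameter("dense_b", np.zeros(out_dim))

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x, train: bool = False):
        self._x = x if train else None
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class BatchNorm(Layer):
    """Batch normalization over all axes except the last (feature/channel) axis."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter("bn_gamma", np.ones(n_features))
        self.beta = Parameter("bn_beta", np.zeros(n_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features, dtype=_DTYPE)
        self.running_var = np.ones(n_features, dtype=_DTYPE)

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train: bool = False):
        x = np.asarray(x, dtype=_DTYPE)
        shape = x.shape
        xf = np.ascontiguousarray(x.reshape(-1, shape[-1]))
        if train:
            xhat, mean, var, inv_std = bn_forward_train(xf, float(self.eps))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(x.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(x.dtype)
            self._cache = (xhat, inv_std, shape)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (xf - self.running_mean) * inv_std
        return (self.gamma.value * xhat + self.beta.value).reshape(shape)

    def backward(self, grad):
        xhat, inv_std, shape = self._cache
        gf = np.ascontiguousarray(
            np.asarray(grad, dtype=xhat.dtype).reshape(-1, shape[-1]))
        dx, dgamma, dbeta = bn_backward(gf, xhat, inv_std, self.gamma.value)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        return dx.reshape(shape)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train: bool = False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        mask = self.rng.random(x.shape) >= self.p
        self._mask = mask.astype(x.dtype) / x.dtype.type(1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Concat(Layer):
    """Channel-axis concatenation of a list of tensors (used in dense blocks)."""

    def forward(self, xs: list[np.ndarray], train: bool = False):
        self._splits = np.cumsum([x.shape[-1] for x in xs])[:-1]
        return np.concatenate(xs, axis=-1)

    def backward(self, grad):
        return np.split(grad, self._splits, axis=-1)
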