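"""Losses on logits with optional per-class positive weighting.

Both losses fold the output activation into the loss for numerical stability:
networks emit logits, ``softmax``/``sigmoid`` are applied here and in
``predict``-time activations.  Class weights scale the positive terms of the
loss (the standard counterweight to label imbalance).
"""

from __future__ import annotations

import numpy as np


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def categorical_cross_entropy(logits: np.ndarray, y_onehot: np.ndarray,
                              class_weights: np.ndarray | None = None
                              ) -> tuple[float, np.ndarray]:
    """Weighted CCE over one-hot targets; returns (mean loss, dLoss/dLogits)."""
    logits = np.asarray(logits)
    y_onehot = np.asarray(y_onehot, dtype=logits.dtype)
    n = logits.shape[0]
    p = softmax(logits)
    logp = logits - logits.max(axis=-1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=-1, keepdims=True))
    w = np.ones(n, dtype=logits.dtype) if class_weights is None \
        else y_onehot @ np.asarray(class_weights, dtype=logits.dtype)
    loss = -(w * (y_onehot * logp).sum(axis=1)).mean()
    grad = w[:, None] * (p - y_onehot) / n
    return float(loss), grad.astype(logits.dtype, copy=False)


def binary_cross_entropy(logits: np.ndarray, y: np.ndarray,
                         class_weights: np.ndarray | None = None
                         ) -> tuple[float, np.ndarray]:
    """Weighted multi-label BCE; weights apply to positive terms only."""
    logits = np.asarray(logits)
    y = np.asarray(y, dtype=logits.dtype)
    n, k = logits.shape
    p = sigmoid(logits)
    w = np.ones(k, dtype=logits.dtype) if class_weights is None \
        else np.asarray(class_weights, dtype=logits.dtype)
    # stable log-sigmoid: log σ(z) = -softplus(-z); log(1-σ(z)) = -softplus(z)
    softplus = np.logaddexp(0.0, logits)
    log_p = logits - softplus
    log_1mp = -softplus
    loss = -(w * y * log_p + (1.0 - y) * log_1mp).sum() / (n * k)
    grad = (w * y * (p - 1.0) + (1.0 - y) * p) / (n * k)
    return float(loss), grad.astype(logits.dtype, copy=False)
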