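"""Adam optimizer with a stepped learning-rate schedule."""

from __future__ import annotations

import numpy as np

from ._kernels import adam_update
from .layers import Parameter


def step_decay_schedule(base_lr: float, total_epochs: int,
                        factor: float = 0.1) -> "callable":
    """Learning rate decays by ``factor`` at 50% and 75% of the epoch budget
    (epochs 40 and 60 of an 80-epoch run)."""
    m1 = total_epochs // 2
    m2 = (3 * total_epochs) // 4

    def lr_at(epoch: int) -> float:
        lr = base_lr
        if epoch >= m1:
            lr *= factor
        if epoch >= m2:
            lr *= factor
        return lr

    return lr_at


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            adam_update(p.value.ravel(), p.grad.ravel(), m.ravel(), v.ravel(),
                        self.lr, b1, b2, self.eps, bias1, bias2)
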