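"""DenseNet-121 feature extractor built from the layer library.

Standard topology: 7x7/2 stem, 3x3/2 max pool, four dense blocks of
(6, 12, 24, 16) bottlenecked units with growth rate 32, transition layers with
0.5 compression, and a final BN+ReLU.  A 224x224x1 input yields 7x7x1024
feature maps.  Intended for full-scale runs; the desk-scale ``tiny_test``
backbone exposes the identical interface contract.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm, Conv2D, Layer, Parameter, Pool2D, ReLU
from .net import Sequential

GROWTH_RATE = 32
BLOCK_CONFIG = (6, 12, 24, 16)
COMPRESSION = 0.5


class DenseUnit(Layer):
    """One bottlenecked unit: x -> concat(x, conv3x3(conv1x1(x)))."""

    def __init__(self, in_ch: int, growth: int, rng: np.random.Generator):
        self.body = Sequential([
            BatchNorm(in_ch), ReLU(),
            Conv2D(in_ch, 4 * growth, 1, 1, pad=0, rng=rng),
            BatchNorm(4 * growth), ReLU(),
            Conv2D(4 * growth, growth, 3, 3, pad="same", rng=rng),
        ])

    @property
    def params(self) -> list[Parameter]:
        return self.body.params

    def children(self):
        return [self.body]

    def forward(self, x, train: bool = False):
        new = self.body.forward(x, train=train)
        self._in_ch = x.shape[-1]
        return np.concatenate([x, new], axis=-1)

    def backward(self, grad):
        gx, gnew = grad[..., :self._in_ch], grad[..., self._in_ch:]
        return gx + self.body.backward(gnew)


def _transition(in_ch: int, rng: np.random.Generator) -> tuple[Sequential, int]:
    out_ch = int(in_ch * COMPRESSION)
    return Sequential([
        BatchNorm(in_ch), ReLU(),
        Conv2D(in_ch, out_ch, 1, 1, pad=0, rng=rng),
        Pool2D(2, kind="avg"),
    ]), out_ch


def densenet121_features(in_channels: int = 1,
                         rng: np.random.Generator | None = None) -> Sequential:
    """The DenseNet-121 convolutional feature extractor (no classifier head)."""
    rng = rng or np.random.default_rng(0)
    layers: list[Layer] = [
        Conv2D(in_channels, 64, 7, 7, stride=2, pad=3, rng=rng),
        BatchNorm(64), ReLU(),
        Pool2D(3, stride=2, pad=1, kind="max"),
    ]
    ch = 64
    for i, n_units in enumerate(BLOCK_CONFIG):
        for _ in range(n_units):
            layers.append(DenseUnit(ch, GROWTH_RATE, rng))
            ch += GROWTH_RATE
        if i < len(BLOCK_CONFIG) - 1:
            trans, ch = _transition(ch, rng)
            layers.append(trans)
    layers += [BatchNorm(ch), ReLU()]
    return Sequential(layers)
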