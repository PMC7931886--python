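"""Network containers: sequential stacks and two-branch feature fusion."""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm, Layer, Parameter


def iter_layers(root: Layer):
    """Depth-first traversal over a layer tree (deterministic order)."""
    yield root
    for child in root.children():
        yield from iter_layers(child)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def children(self) -> list[Layer]:
        return self.layers

    @property
    def params(self) -> list[Parameter]:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class TwoBranchNet(Layer):
    """Two modality branches whose flattened features are concatenated into a
    shared dense head — the intermediate ("model") fusion topology, trainable
    end-to-end: head gradients propagate into both branches."""

    def __init__(self, branch_a: Sequential, branch_b: Sequential, head: Sequential):
        self.branch_a = branch_a
        self.branch_b = branch_b
        self.head = head

    def children(self) -> list[Layer]:
        return [self.branch_a, self.branch_b, self.head]

    @property
    def params(self) -> list[Parameter]:
        return self.branch_a.params + self.branch_b.params + self.head.params

    def forward(self, xs, train: bool = False):
        xa, xb = xs
        fa = self.branch_a.forward(xa, train=train)
        fb = self.branch_b.forward(xb, train=train)
        if fa.ndim != 2 or fb.ndim != 2:
            raise ValueError("branches must emit flattened (batch, features) arrays")
        self._split = fa.shape[1]
        return self.head.forward(np.concatenate([fa, fb], axis=1), train=train)

    def backward(self, grad):
        g = self.head.backward(grad)
        ga = self.branch_a.backward(g[:, :self._split])
        gb = self.branch_b.backward(g[:, self._split:])
        return ga, gb


def get_weights(net: Layer) -> list[np.ndarray]:
    """Snapshot the full trainable state: parameters plus batch-norm running
    statistics (which checkpoint restores must carry along)."""
    out = [p.value.copy() for p in net.params]
    for layer in iter_layers(net):
        if isinstance(layer, BatchNorm):
            out.append(layer.running_mean.copy())
            out.append(layer.running_var.copy())
    return out


def set_weights(net: Layer, weights: list[np.ndarray]) -> None:
    params = net.params
    bns = [l for l in iter_layers(net) if isinstance(l, BatchNorm)]
    expected = len(params) + 2 * len(bns)
    if expected != len(weights):
        raise ValueError(f"expected {expected} arrays, got {len(weights)}")
    for p, w in zip(params, weights):
        if p.value.shape != w.shape:
            raise ValueError(f"shape mismatch for {p.name}: {p.value.shape} vs {w.shape}")
        p.value[...] = w
    tail = weights[len(params):]
    for bn, mean, var in zip(bns, tail[::2], tail[1::2]):
        bn.running_mean[...] = mean
        bn.running_var[...] = var
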