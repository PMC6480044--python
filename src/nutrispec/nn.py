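"""Minimal fully-connected network core: dense layers, ReLU, Adam.

Deliberately small: the architectures used here are plain MLPs of at most a
few hundred thousand parameters trained on CPU, so a hand-rolled forward /
backward pass over dense layers is all that is required.  All randomness is
drawn from an explicit ``numpy`` Generator so builds are reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "MLP", "Adam"]


class Dense:
    """Affine layer ``y = x @ W + b`` with optional ReLU."""

    def __init__(self, n_in: int, n_out: int, relu: bool,
                 rng: np.random.Generator):
        # He-normal initialization, suited to ReLU stacks
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.relu = relu
        self._x: np.ndarray | None = None
        self._pre: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        pre = x @ self.W + self.b
        out = np.maximum(pre, 0.0) if self.relu else pre
        if cache:
            self._x, self._pre = x, pre
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self.relu:
            grad_out = grad_out * (self._pre > 0.0)
        self.dW = self._x.T @ grad_out
        self.db = grad_out.sum(axis=0)
        return grad_out @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class MLP:
    """A stack of Dense layers; hidden layers ReLU, output configurable."""

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 relu_last: bool = False):
        if len(widths) < 2:
            raise ValueError("an MLP needs at least an input and an output width")
        self.layers = [
            Dense(widths[i], widths[i + 1],
                  relu=(i < len(widths) - 2) or relu_last, rng=rng)
            for i in range(len(widths) - 1)
        ]
        self.widths = list(widths)

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, cache=cache)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1.0 - b2 ** self.t) / (1.0 - b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = b1 * m + (1.0 - b1) * g
            v[...] = b2 * v + (1.0 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
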