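"""Minimal fully-connected network engine: forward, backprop, Adam.

Weights are float64 throughout; with a fixed seed (and fixed BLAS thread
count) every training run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class Layer:
    W: np.ndarray  # (fan_in, fan_out)
    b: np.ndarray  # (fan_out,)
    activation: str  # "relu" | "linear"

    def copy(self) -> "Layer":
        return Layer(self.W.copy(), self.b.copy(), self.activation)


def make_layer(rng: np.random.Generator, fan_in: int, fan_out: int, activation: str) -> Layer:
    return Layer(glorot_uniform(rng, fan_in, fan_out), np.zeros(fan_out), activation)


class MLP:
    """A chain of dense layers with ReLU or linear activations."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, X: np.ndarray, cache: bool = False):
        """Return the output, plus (inputs, pre-activations) if caching."""
        inputs, pres = [], []
        h = X
        for layer in self.layers:
            if cache:
                inputs.append(h)
            pre = h @ layer.W + layer.b
            if cache:
                pres.append(pre)
            h = np.maximum(pre, 0.0) if layer.activation == "relu" else pre
        if cache:
            return h, (inputs, pres)
        return h

    def backward(self, cache, d_out: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """Gradients of the loss w.r.t. each layer's (W, b), given dL/d(output)."""
        inputs, pres = cache
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.layers)
        d = d_out
        for i in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[i]
            if layer.activation == "relu":
                d = d * (pres[i] > 0)
            grads[i] = (inputs[i].T @ d, d.sum(axis=0))
            if i > 0:
                d = d @ layer.W.T
        return grads

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend((layer.W, layer.b))
        return out


class Adam:
    """Adam optimizer with the Keras-style defaults."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1.0 - b2 ** self.t) / (1.0 - b1 ** self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class MinibatchSampler:
    """Seeded shuffling with cycling: successive slices of a permutation,
    reshuffled whenever the pool is exhausted."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        self.n = n
        self.batch_size = min(batch_size, n)
        self.rng = rng
        self._perm = rng.permutation(n)
        self._pos = 0

    def next_batch(self) -> np.ndarray:
        if self._pos + self.batch_size > self.n:
            self._perm = self.rng.permutation(self.n)
            self._pos = 0
        idx = self._perm[self._pos:self._pos + self.batch_size]
        self._pos += self.batch_size
        return idx
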