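"""Minimal dense neural-network building blocks in numpy.

Implements exactly what the pipeline's small models need: linear layers with
ReLU, manual reverse-mode gradients, softmax, and Adam. Networks here are a few
thousand parameters trained full-batch, where numpy is entirely adequate.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np


class Linear:
    """Affine layer with He-scaled Gaussian init."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T


class MLP:
    """Feed-forward stack of :class:`Linear` layers with ReLU activations.

    ``relu_after_last`` controls whether the final layer output is rectified
    (used for the encoder, whose latent codes are rectified) or left linear
    (decoder output, classifier logits).
    """

    def __init__(self, dims: Sequence[int], rng: np.random.Generator,
                 relu_after_last: bool = False):
        self.layers = [Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self.relu_after_last = relu_after_last
        self._pre: List[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pre = []
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            x = layer.forward(x)
            if i < last or self.relu_after_last:
                self._pre.append(x)
                x = np.maximum(x, 0.0)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        last = len(self.layers) - 1
        pre = list(self._pre)
        for i in range(last, -1, -1):
            if i < last or self.relu_after_last:
                grad = grad * (pre.pop() > 0)
            grad = self.layers[i].backward(grad)
        return grad

    @property
    def params(self) -> List[np.ndarray]:
        out: List[np.ndarray] = []
        for l in self.layers:
            out.extend([l.W, l.b])
        return out

    @property
    def grads(self) -> List[np.ndarray]:
        out: List[np.ndarray] = []
        for l in self.layers:
            out.extend([l.gW, l.gb])
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam optimizer updating a fixed list of parameter arrays in place."""

    def __init__(self, params: List[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
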