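"""A small CPU training engine for 1-D convolutional classifiers.

Implements exactly the pieces the sleep-wake networks need -- 1-D valid
convolution, ReLU, max-pooling, dense layers, dropout, a softmax
cross-entropy loss with class weights, and Adam -- on plain numpy arrays.
Everything is deterministic under a seeded :class:`numpy.random.Generator`
(single-threaded numpy), which the repeated-training protocol relies on.

Array convention: batches are ``(N, L, C)`` (samples, length, channels)
until a :class:`Flatten`, then ``(N, F)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv1D",
    "ReLU",
    "MaxPool1D",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "Adam",
    "softmax",
    "weighted_cross_entropy",
]


class Layer:
    """Base layer: forward caches what backward needs."""

    trainable = True

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1D(Layer):
    """Valid 1-D convolution (cross-correlation), He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.W = rng.standard_normal((out_ch, in_ch, kernel)) * scale
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        self._x = x
        out_ch, _, k = self.W.shape
        lp = x.shape[1] - k + 1
        out = np.broadcast_to(self.b, (x.shape[0], lp, out_ch)).copy()
        for j in range(k):
            out += x[:, j : j + lp, :] @ self.W[:, :, j].T
        return out

    def backward(self, grad):
        x = self._x
        k = self.W.shape[2]
        lp = grad.shape[1]
        dx = np.zeros_like(x)
        for j in range(k):
            self.dW[:, :, j] = np.tensordot(grad, x[:, j : j + lp, :], axes=([0, 1], [0, 1]))
            dx[:, j : j + lp, :] += grad @ self.W[:, :, j]
        self.db[:] = grad.sum(axis=(0, 1))
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis (floor division)."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, train=False, rng=None):
        n, l, c = x.shape
        lp = l // self.size
        xr = x[:, : lp * self.size, :].reshape(n, lp, self.size, c)
        self._arg = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, grad):
        n, lp, c = grad.shape
        dx = np.zeros(self._shape)
        dxr = dx[:, : lp * self.size, :].reshape(n, lp, self.size, c)
        ni, li, ci = np.ogrid[:n, :lp, :c]
        dxr[ni, li, self._arg, ci] = grad
        return dx


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[:] = self._x.T @ grad
        self.db[:] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Dropout(Layer):
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout fraction must be in [0, 1), got {p}")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        assert rng is not None, "training-mode dropout needs an rng"
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential:
    """A plain layer stack; also used for the convolutional branches."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for l in self.layers if l.trainable for p in l.params()]

    def grads(self):
        return [g for l in self.layers if l.trainable for g in l.grads()]

    def all_params(self):
        return [p for l in self.layers for p in l.params()]

    def freeze(self):
        for layer in self.layers:
            layer.trainable = False


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy.

    Returns ``(loss, dlogits)`` with the loss normalized by the total
    sample weight, so gradients are comparable across batch compositions.
    """
    p = softmax(logits)
    n = logits.shape[0]
    w = class_weights[y]
    wsum = w.sum()
    loss = float(-(w * np.log(p[np.arange(n), y] + 1e-12)).sum() / wsum)
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (w / wsum)[:, None]
    return loss, grad


class Adam:
    """Adam optimizer over a fixed list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
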