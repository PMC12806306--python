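"""Minimal dense-network primitives with explicit backpropagation.

The networks here are small (tens of units, a few layers), so the layers
compute their own gradients analytically: each layer caches what its
backward pass needs during ``forward`` and accumulates parameter gradients
in ``backward``.  Weight initialization is uniform fan-in scaling with an
explicit generator so training runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: parameter-free by default."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.w = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = rng.uniform(-bound, bound, size=n_out)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw += self._x.T @ grad
        self.gb += grad.sum(axis=0)
        return grad @ self.w.T


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class BatchNorm(Layer):
    """Batch normalization with running statistics for evaluation mode."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def forward(self, x, training):
        if training:
            if x.shape[0] < 2:
                raise ValueError(
                    "batch normalization is undefined for a training batch of size 1"
                )
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        self.ggamma += (grad * self._xhat).sum(axis=0)
        self.gbeta += grad.sum(axis=0)
        if not self._training:
            return grad * self.gamma / self._std
        n = grad.shape[0]
        gxhat = grad * self.gamma
        return (
            gxhat - gxhat.mean(axis=0) - self._xhat * (gxhat * self._xhat).mean(axis=0)
        ) / self._std


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, training):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self):
        for g in self.grads():
            g[...] = 0.0


class Adam:
    """Adaptive-moment gradient descent over a fixed list of parameter arrays."""

    def __init__(self, params, grads, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grad_refs = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def parameter_hash(params: list[np.ndarray]) -> int:
    """Order-sensitive hash of a parameter list, for change detection."""
    acc = 0
    for p in params:
        acc ^= hash(p.tobytes())
    return acc
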