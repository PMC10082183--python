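"""Minimal dense neural-network primitives (NumPy, manual backprop).

Only what the embedding and clustering stages need: fully connected layers
with ReLU/tanh/linear activations, mean-squared-error loss, an Adam
optimizer for autoencoder training and SGD with momentum for the clustering
phase.  All randomness flows through an explicit numpy Generator so runs
are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Adam", "SGDMomentum", "forward_chain", "backward_chain"]


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    if name == "linear":
        return z
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(z.dtype)
    if name == "tanh":
        return 1.0 - a * a
    if name == "linear":
        return np.ones_like(z)
    raise ValueError(f"unknown activation {name!r}")


class Dense:
    """Fully connected layer a = act(x @ W + b) with Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, activation: str, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.activation = activation
        self._cache: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        z = x @ self.W + self.b
        a = _act(self.activation, z)
        if cache:
            self._cache = (x, z, a)
        return a

    def backward(self, grad_a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Given dL/da, return (dL/dx, dL/dW, dL/db) using the cached forward."""
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        x, z, a = self._cache
        gz = grad_a * _act_grad(self.activation, z, a)
        return gz @ self.W.T, x.T @ gz, gz.sum(axis=0)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]


def forward_chain(layers: list[Dense], x: np.ndarray, cache: bool = True) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x, cache=cache)
    return x


def backward_chain(layers: list[Dense], grad_out: np.ndarray) -> list[np.ndarray]:
    """Backprop dL/d(output) through the chain; returns flat grads per param."""
    grads: list[np.ndarray] = []
    g = grad_out
    for layer in reversed(layers):
        g, gW, gb = layer.backward(g)
        grads.extend([gb, gW])
    grads.reverse()  # now [W0, b0, W1, b1, ...] order matching params_of
    return grads


def params_of(layers: list[Dense]) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for layer in layers:
        out.extend(layer.params)
    return out


class Adam:
    """Adaptive-moment estimation over a fixed list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
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
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGDMomentum:
    """Classical momentum SGD: u <- mu*u - lr*g; p <- p + u."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.01, momentum: float = 0.9):
        self.params = params
        self.lr, self.momentum = lr, momentum
        self.u = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, u in zip(self.params, grads, self.u):
            u *= self.momentum
            u -= self.lr * g
            p += u
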