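"""Feed-forward layers, losses and the Adam optimiser.

Each layer exposes aligned ``params`` / ``grads`` lists of ndarrays;
``forward(x, train)`` caches what ``backward(dout)`` needs. Batch-style
normalisation keeps running statistics for inference so that single-sample
prediction equals batched prediction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "BatchNorm1d",
    "LayerNorm",
    "Tanh",
    "Sequential",
    "Adam",
    "softmax",
    "mse_loss",
    "mse_grad",
    "cross_entropy_loss",
    "cross_entropy_grad",
    "glorot",
]


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = glorot(rng, n_in, n_out)
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


class BatchNorm1d(Layer):
    """Normalisation over the batch axis with learnable scale/shift.

    Training uses batch statistics and updates exponential running estimates;
    inference uses the running estimates, making outputs independent of batch
    composition.
    """

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_sd
        self._cache = (xhat, inv_sd, x.shape[0], train)
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        xhat, inv_sd, b, train = self._cache
        self.grads[0][...] = (dout * xhat).sum(axis=0)
        self.grads[1][...] = dout.sum(axis=0)
        dxhat = dout * self.gamma
        if not train:
            return dxhat * inv_sd
        return (inv_sd / b) * (
            b * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )


class LayerNorm(Layer):
    """Per-sample normalisation across features; batch-size independent."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.eps = eps
        self._cache = None

    def forward(self, x, train=True):
        mean = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_sd
        self._cache = (xhat, inv_sd, x.shape[1])
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        xhat, inv_sd, d = self._cache
        self.grads[0][...] = (dout * xhat).sum(axis=0)
        self.grads[1][...] = dout.sum(axis=0)
        dxhat = dout * self.gamma
        return (inv_sd / d) * (
            d * dxhat
            - dxhat.sum(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=1, keepdims=True)
        )


class Tanh(Layer):
    def __init__(self):
        self.params, self.grads = [], []
        self._y = None

    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y**2)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class Adam:
    """Adaptive-moment gradient descent over a fixed parameter list."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def mse_loss(x: np.ndarray, xhat: np.ndarray) -> float:
    """Mean of squared elementwise differences over all entries."""
    x, xhat = np.asarray(x, float), np.asarray(xhat, float)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    return float(np.mean((x - xhat) ** 2))


def mse_grad(x: np.ndarray, xhat: np.ndarray) -> np.ndarray:
    """d(mse)/d(xhat)."""
    return 2.0 * (xhat - x) / x.size


def cross_entropy_loss(logits: np.ndarray, labels: np.ndarray,
                       weights: np.ndarray | None = None) -> float:
    p = softmax(logits)
    picked = np.clip(p[np.arange(len(labels)), labels], 1e-12, None)
    nll = -np.log(picked)
    if weights is not None:
        w = weights[labels]
        return float((nll * w).sum() / w.sum())
    return float(nll.mean())


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray,
                       weights: np.ndarray | None = None) -> np.ndarray:
    p = softmax(logits)
    onehot = np.zeros_like(p)
    onehot[np.arange(len(labels)), labels] = 1.0
    if weights is not None:
        w = weights[labels][:, None]
        return (p - onehot) * w / w.sum()
    return (p - onehot) / len(labels)
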