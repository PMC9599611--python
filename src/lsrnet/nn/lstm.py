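"""LSTM layer with full backpropagation through time.

Standard recurrences with gate order (input, forget, cell, output):

    a_t = x_t W + h_{t-1} U + b                    (split into i, f, g, o)
    i, f, o = sigmoid(...);  g = tanh(...)
    c_t = f * c_{t-1} + i * g
    h_t = o * tanh(c_t)

A bidirectional pass is two independent layers, one fed the time-reversed
sequence; the dynamic-feature vector is the concatenation of the two final
hidden states.
"""

from __future__ import annotations

import numpy as np

from .core import glorot

__all__ = ["LSTMLayer"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTMLayer:
    """Single-direction LSTM over inputs of shape (batch, steps, input_dim)."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        self.input_dim, self.hidden = input_dim, hidden
        self.w = glorot(rng, input_dim, 4 * hidden)
        self.u = glorot(rng, hidden, 4 * hidden)
        self.b = np.zeros(4 * hidden)
        self.params = [self.w, self.u, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Returns all hidden states, shape (batch, steps, hidden)."""
        b, m, d = x.shape
        h = self.hidden
        hs = np.zeros((b, m, h))
        cs = np.zeros((b, m, h))
        gates = np.zeros((b, m, 4 * h))
        h_prev = np.zeros((b, h))
        c_prev = np.zeros((b, h))
        for t in range(m):
            a = x[:, t] @ self.w + h_prev @ self.u + self.b
            i = _sigmoid(a[:, :h])
            f = _sigmoid(a[:, h : 2 * h])
            g = np.tanh(a[:, 2 * h : 3 * h])
            o = _sigmoid(a[:, 3 * h :])
            c_prev = f * c_prev + i * g
            h_prev = o * np.tanh(c_prev)
            hs[:, t], cs[:, t] = h_prev, c_prev
            gates[:, t] = np.concatenate([i, f, g, o], axis=1)
        if not np.all(np.isfinite(hs)):
            raise FloatingPointError("non-finite LSTM activations")
        self._cache = (x, hs, cs, gates)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        """BPTT given gradients w.r.t. every hidden state (batch, steps, hidden)."""
        x, hs, cs, gates = self._cache
        b, m, d = x.shape
        h = self.hidden
        dw, du, db = (np.zeros_like(self.w), np.zeros_like(self.u),
                      np.zeros_like(self.b))
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, h))
        dc_next = np.zeros((b, h))
        for t in range(m - 1, -1, -1):
            i = gates[:, t, :h]
            f = gates[:, t, h : 2 * h]
            g = gates[:, t, 2 * h : 3 * h]
            o = gates[:, t, 3 * h :]
            c = cs[:, t]
            c_prev = cs[:, t - 1] if t > 0 else np.zeros((b, h))
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((b, h))
            tanh_c = np.tanh(c)
            dh = dhs[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di, dg, df = dc * g, dc * i, dc * c_prev
            dc_next = dc * f
            da = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dw += x[:, t].T @ da
            du += h_prev.T @ da
            db += da.sum(axis=0)
            dh_next = da @ self.u.T
            dx[:, t] = da @ self.w.T
        self.grads[0][...] = dw
        self.grads[1][...] = du
        self.grads[2][...] = db
        return dx
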