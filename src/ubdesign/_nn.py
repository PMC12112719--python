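"""Minimal NumPy neural-network primitives for the sequence VAE.

Implements exactly what the generator needs — dense layers, a batched LSTM
with full backpropagation through time, softmax cross-entropy and Adam —
with parameters kept in plain ``dict[str, np.ndarray]`` containers so the
whole model state is trivially serialisable.  Gradient correctness is
guarded by a finite-difference test in the suite.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# Dense


def dense_forward(x, W, b):
    return x @ W + b, x


def dense_backward(dy, W, cache):
    x = cache
    dW = x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
    db = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
    dx = dy @ W.T
    return dx, dW, db


# ---------------------------------------------------------------------------
# LSTM (batch-major: x is (B, T, D); gate order i, f, g, o)


def lstm_step(x_t, h_prev, c_prev, Wx, Wh, b):
    H = h_prev.shape[1]
    a = x_t @ Wx + h_prev @ Wh + b
    i = sigmoid(a[:, :H])
    f = sigmoid(a[:, H : 2 * H])
    g = np.tanh(a[:, 2 * H : 3 * H])
    o = sigmoid(a[:, 3 * H :])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c, (x_t, h_prev, c_prev, i, f, g, o, c)


def lstm_forward(x, h0, c0, Wx, Wh, b):
    B, T, _ = x.shape
    H = h0.shape[1]
    hs = np.empty((B, T, H))
    h, c = h0, c0
    caches = []
    for t in range(T):
        h, c, cache = lstm_step(x[:, t, :], h, c, Wx, Wh, b)
        hs[:, t, :] = h
        caches.append(cache)
    return hs, (h, c), caches


def lstm_backward(dhs, dh_last, dc_last, Wx, Wh, caches):
    """Backprop through time.

    ``dhs`` carries per-step output gradients (zeros allowed); ``dh_last``
    and ``dc_last`` are extra gradients on the final hidden/cell state.
    Returns (dx, dh0, dc0, dWx, dWh, db).
    """
    B, T, H = dhs.shape
    D = Wx.shape[0]
    dx = np.zeros((B, T, D))
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dh_next = dh_last.copy()
    dc_next = dc_last.copy()
    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, c = caches[t]
        dh = dhs[:, t, :] + dh_next
        tanh_c = np.tanh(c)
        do = dh * tanh_c
        dc = dc_next + dh * o * (1.0 - tanh_c**2)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dc_next = dc * f
        da = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += x_t.T @ da
        dWh += h_prev.T @ da
        db += da.sum(axis=0)
        dx[:, t, :] = da @ Wx.T
        dh_next = da @ Wh.T
    return dx, dh_next, dc_next, dWx, dWh, db


# ---------------------------------------------------------------------------
# Adam


class Adam:
    """Adam optimiser over a named parameter dict (beta1=0.9, beta2=0.999)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
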