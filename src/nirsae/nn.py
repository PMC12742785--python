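"""Minimal NumPy sequence-model primitives: Dense, LSTM, Adam.

Everything is float32, batch-first, and fully deterministic given the
initialization seed and the data order.  Backpropagation through time is
implemented explicitly; gate order inside the fused LSTM weight matrices
is (input, forget, candidate, output).

The LSTM supports a ReLU cell activation (applied to the candidate and to
the cell output) in addition to the classical tanh; ReLU-activated cells
are unbounded, so training code is expected to clip gradients.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

DTYPE = np.float32


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _act(name: str, x: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "tanh":
        return np.tanh(x)
    raise ValueError(f"unknown activation {name!r}")


def _act_grad_from_output(name: str, y: np.ndarray) -> np.ndarray:
    # derivative expressed through the activation *output* (valid a.e. for relu)
    if name == "relu":
        return (y > 0).astype(y.dtype)
    if name == "tanh":
        return 1.0 - y * y
    raise ValueError(f"unknown activation {name!r}")


def glorot_uniform(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out)).astype(DTYPE)


class Dense:
    """Affine map with optional activation; applies over the last axis."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, activation: str | None = None):
        self.n_in, self.n_out = n_in, n_out
        self.activation = activation
        self.W = glorot_uniform(rng, n_in, n_out)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x @ self.W + self.b
        y = _act(self.activation, z) if self.activation else z
        self._x, self._y = x, y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.activation:
            dy = dy * _act_grad_from_output(self.activation, self._y)
        flat_x = self._x.reshape(-1, self.n_in)
        flat_dy = dy.reshape(-1, self.n_out)
        self.dW[...] = flat_x.T @ flat_dy
        self.db[...] = flat_dy.sum(axis=0)
        return (dy @ self.W.T).reshape(self._x.shape)


class LSTM:
    """Single LSTM layer over (batch, time, features) input."""

    def __init__(
        self,
        rng: np.random.Generator,
        n_in: int,
        n_units: int,
        activation: str = "relu",
        return_sequences: bool = True,
    ):
        self.n_in, self.n_units = n_in, n_units
        self.activation = activation
        self.return_sequences = return_sequences
        H = n_units
        self.Wx = glorot_uniform(rng, n_in, 4 * H)
        self.Wh = glorot_uniform(rng, H, 4 * H)
        self.b = np.zeros(4 * H, dtype=DTYPE)
        self.b[H : 2 * H] = 1.0  # forget-gate bias init
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]

    @property
    def grads(self):
        return [self.dWx, self.dWh, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, T, _ = x.shape
        H = self.n_units
        Zx = x @ self.Wx  # one big matmul for all time steps
        h = np.zeros((N, H), dtype=DTYPE)
        c = np.zeros((N, H), dtype=DTYPE)
        cache = []
        Hs = np.empty((N, T, H), dtype=DTYPE)
        for t in range(T):
            z = Zx[:, t] + h @ self.Wh + self.b
            i = expit(z[:, :H])
            f = expit(z[:, H : 2 * H])
            g = _act(self.activation, z[:, 2 * H : 3 * H])
            o = expit(z[:, 3 * H :])
            c_prev, h_prev = c, h
            c = f * c + i * g
            ca = _act(self.activation, c)
            h = o * ca
            Hs[:, t] = h
            cache.append((i, f, g, o, c_prev, h_prev, c, ca))
        self._x, self._cache, self._T = x, cache, T
        return Hs if self.return_sequences else h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, cache, T = self._x, self._cache, self._T
        N = x.shape[0]
        H = self.n_units
        act = self.activation
        self.dWh[...] = 0.0
        self.db[...] = 0.0
        dZx = np.empty((N, T, 4 * H), dtype=DTYPE)
        dh_next = np.zeros((N, H), dtype=DTYPE)
        dc_next = np.zeros((N, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, c, ca = cache[t]
            if self.return_sequences:
                dh = dh_next + dout[:, t]
            else:
                dh = dh_next + (dout if t == T - 1 else 0.0)
            do = dh * ca
            dc = dc_next + dh * o * _act_grad_from_output(act, ca)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * _act_grad_from_output(act, g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dh_next = dz @ self.Wh.T
            dZx[:, t] = dz
        flat_x = x.reshape(-1, self.n_in)
        self.dWx[...] = flat_x.T @ dZx.reshape(-1, 4 * H)
        self._cache = None
        return (dZx @ self.Wx.T).reshape(x.shape)


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(p.dtype)


def clip_global_norm(grads, max_norm: float) -> float:
    """Scale all gradient arrays so their joint L2 norm is <= max_norm."""
    total = float(np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total
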