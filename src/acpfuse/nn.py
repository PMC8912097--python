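"""Minimal numpy neural-network engine for the hybrid classifier.

Implements exactly the pieces the model needs — a token embedding with a
masked padding index, an LSTM layer (standard forget/input/output-gate cell)
run in both directions, fully connected layers, inverted dropout, and an
Adam optimizer — with explicit reverse-mode gradients. Everything is
deterministic given the ``numpy.random.Generator`` passed in.

Array conventions: batches are leading, so dense inputs are ``(B, D)`` and
sequence inputs ``(B, T)`` (integer indices) or ``(B, T, D)`` (embedded).
Padded timesteps (index 0) are masked: the recurrent state is carried
through them unchanged and they receive no gradient.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base: parameters and their gradient accumulators, by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Dense(Layer):
    """Affine layer with optional ReLU."""

    def __init__(
        self, rng: np.random.Generator, n_in: int, n_out: int, relu: bool = True
    ) -> None:
        super().__init__()
        scale = np.sqrt((2.0 if relu else 1.0) / n_in)
        self.params["W"] = rng.normal(0.0, scale, (n_in, n_out))
        self.params["b"] = np.zeros(n_out)
        self.relu = relu
        self.zero_grad()

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        z = x @ self.params["W"] + self.params["b"]
        a = np.maximum(z, 0.0) if self.relu else z
        return a, (x, z)

    def backward(self, da: np.ndarray, cache: tuple) -> np.ndarray:
        x, z = cache
        dz = da * (z > 0.0) if self.relu else da
        self.grads["W"] += x.T @ dz
        self.grads["b"] += dz.sum(axis=0)
        return dz @ self.params["W"].T


class Embedding(Layer):
    """Token embedding; row 0 is the padding vector, pinned at zero."""

    def __init__(self, rng: np.random.Generator, n_tokens: int, dim: int) -> None:
        super().__init__()
        W = rng.normal(0.0, 0.1, (n_tokens, dim))
        W[0] = 0.0
        self.params["W"] = W
        self.zero_grad()

    def forward(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.params["W"][idx], idx

    def backward(self, dout: np.ndarray, idx: np.ndarray) -> None:
        np.add.at(self.grads["W"], idx, dout)
        self.grads["W"][0] = 0.0  # padding row never trains


class LSTM(Layer):
    """Single-direction LSTM returning the final hidden state.

    The cell follows the standard gate equations: forget gate f, input
    gate i, output gate o (logistic), candidate g (tanh),
    c_t = f*c_{t-1} + i*g,  h_t = o * tanh(c_t).
    Gate order in the stacked weight matrices is [i, f, o, g]. The forget
    gate bias starts at 1 (common trick to ease gradient flow early on).
    At masked timesteps h and c are carried through unchanged.
    """

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int) -> None:
        super().__init__()
        self.H = n_hidden
        sx = np.sqrt(1.0 / n_in)
        sh = np.sqrt(1.0 / n_hidden)
        self.params["Wx"] = rng.normal(0.0, sx, (n_in, 4 * n_hidden))
        self.params["Wh"] = rng.normal(0.0, sh, (n_hidden, 4 * n_hidden))
        b = np.zeros(4 * n_hidden)
        b[n_hidden : 2 * n_hidden] = 1.0
        self.params["b"] = b
        self.zero_grad()

    def forward(
        self, X: np.ndarray, mask: np.ndarray
    ) -> tuple[np.ndarray, list[tuple]]:
        B, T, _ = X.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        caches: list[tuple] = []
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        for t in range(T):
            z = X[:, t] @ Wx + h @ Wh + b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            o = sigmoid(z[:, 2 * H : 3 * H])
            g = np.tanh(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = mask[:, t : t + 1]
            caches.append((h, c, i, f, o, g, tc, m))
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
        return h, caches

    def backward(
        self, dh: np.ndarray, X: np.ndarray, caches: list[tuple]
    ) -> np.ndarray:
        B, T, _ = X.shape
        H = self.H
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dX = np.zeros_like(X)
        dc = np.zeros((B, H))
        dh = dh.copy()
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, o, g, tc, m = caches[t]
            dh_new = dh * m
            dh_prev = dh * (1.0 - m)
            dc_new = dc * m
            dc_prev = dc * (1.0 - m)
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1.0 - tc**2)
            df = dc_new * c_prev
            di = dc_new * g
            dg = dc_new * i
            dc_prev = dc_prev + dc_new * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    do * o * (1.0 - o),
                    dg * (1.0 - g**2),
                ],
                axis=1,
            )
            self.grads["Wx"] += X[:, t].T @ dz
            self.grads["Wh"] += h_prev.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dX[:, t] = dz @ Wx.T
            dh = dh_prev + dz @ Wh.T
            dc = dc_prev
        return dX


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(
        self, x: np.ndarray, rng: np.random.Generator | None
    ) -> tuple[np.ndarray, np.ndarray | None]:
        if rng is None or self.rate == 0.0:
            return x, None
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * mask, mask

    @staticmethod
    def backward(dx: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
        return dx if mask is None else dx * mask


class Adam:
    """Adam optimizer over a flat dict of parameter arrays."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * g**2
            mhat = self.m[k] / (1.0 - b1**self.t)
            vhat = self.v[k] / (1.0 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_loss(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on logits (numerically stable) and its
    gradient with respect to the logits, averaged over the batch."""
    p = sigmoid(logits)
    loss = float(np.mean(np.logaddexp(0.0, logits) - y * logits))
    return loss, (p - y) / len(y)
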