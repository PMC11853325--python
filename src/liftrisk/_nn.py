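"""Seeded pure-numpy neural-network core.

Implements the three small architectures used for lifting-risk
classification (feed-forward, 1-D convolutional, LSTM) with explicit
backpropagation, Adam updates, binary cross-entropy loss and
early stopping on a held-out validation fraction.  Everything is driven
by a single :class:`numpy.random.Generator`, so training is bit-identical
under a fixed seed.

Shapes
------
Dense layers operate on ``(batch, features)``; sequence layers
(Conv1D, MaxPool1D, LSTM) on ``(batch, time, channels)``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: forward caches whatever backward needs."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x):
        self._y = expit(x)
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Conv1D(Layer):
    """Valid-mode 1-D convolution, ``(N, T, C) -> (N, T - k + 1, filters)``."""

    def __init__(self, c_in: int, filters: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.c_in = c_in
        fan_in = c_in * kernel
        self.W = _glorot(rng, (fan_in, filters), fan_in, filters)
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        n, t, c = x.shape
        k = self.kernel
        # (N, L, C, k) -> (N, L, k*C) im2col
        cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        cols = np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(n, t - k + 1, k * c)
        self._cols = cols
        self._xshape = x.shape
        return cols @ self.W + self.b

    def backward(self, dy):
        n, length, _ = dy.shape
        k, c = self.kernel, self._xshape[2]
        self.dW[...] = np.einsum("nlc,nlf->cf", self._cols, dy)
        self.db[...] = dy.sum(axis=(0, 1))
        dcols = (dy @ self.W.T).reshape(n, length, k, c)
        dx = np.zeros(self._xshape)
        for j in range(k):
            dx[:, j : j + length, :] += dcols[:, :, j, :]
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; trailing remainder dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x):
        n, t, c = x.shape
        p = self.pool
        length = t // p
        xr = x[:, : length * p].reshape(n, length, p, c)
        self._arg = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy):
        n, length, c = dy.shape
        p = self.pool
        dxr = np.zeros((n, length, p, c))
        np.put_along_axis(dxr, self._arg[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(self._shape)
        dx[:, : length * p] = dxr.reshape(n, length * p, c)
        return dx


class LSTM(Layer):
    """Single LSTM layer returning the last hidden state, ``(N, T, C) -> (N, H)``.

    Gate order i, f, g, o; forget-gate bias initialised to 1 (standard
    trick to avoid vanishing memory early in training).
    """

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        h4 = 4 * hidden
        self.Wx = _glorot(rng, (c_in, h4), c_in + hidden, hidden)
        self.Wh = _glorot(rng, (hidden, h4), c_in + hidden, hidden)
        self.b = np.zeros(h4)
        self.b[hidden : 2 * hidden] = 1.0
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def grads(self):
        return [self.dWx, self.dWh, self.db]

    def forward(self, x):
        n, t, _ = x.shape
        hdim = self.hidden
        h = np.zeros((n, hdim))
        c = np.zeros((n, hdim))
        self._x = x
        self._cache = []
        for step in range(t):
            x_t = x[:, step, :]
            z = x_t @ self.Wx + h @ self.Wh + self.b
            i = expit(z[:, :hdim])
            f = expit(z[:, hdim : 2 * hdim])
            g = np.tanh(z[:, 2 * hdim : 3 * hdim])
            o = expit(z[:, 3 * hdim :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            self._cache.append((x_t, h_prev, c_prev, i, f, g, o, c))
        return h

    def backward(self, dy):
        x = self._x
        n, t, c_in = x.shape
        hdim = self.hidden
        self.dWx[...] = 0.0
        self.dWh[...] = 0.0
        self.db[...] = 0.0
        dx = np.zeros_like(x)
        dh = dy
        dc = np.zeros((n, hdim))
        for step in range(t - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c = self._cache[step]
            tc = np.tanh(c)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.dWx += x_t.T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, step, :] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight list does not match model parameters")
        for p, w in zip(own, weights):
            p[...] = w

    def predict(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        out = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


_EPS = 1e-7


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def fit(
    model: Sequential,
    x: np.ndarray,
    y: np.ndarray,
    *,
    rng: np.random.Generator,
    learning_rate: float = 1e-3,
    batch_size: int = 512,
    max_epochs: int = 50,
    patience: int = 5,
    validation_fraction: float = 0.1,
) -> dict[str, list[float]]:
    """Minibatch Adam training with early stopping on validation loss.

    The best-validation weights are restored before returning.  Returns a
    history dict with per-epoch ``loss``, ``accuracy``, ``val_loss`` and
    ``val_accuracy``.
    """
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    n = len(x)
    order = rng.permutation(n)
    n_val = max(1, int(round(validation_fraction * n))) if validation_fraction > 0 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("no training rows left after validation split")
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    opt = Adam(model.params(), lr=learning_rate)
    history: dict[str, list[float]] = {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []
    }
    best_val = np.inf
    best_weights = model.get_weights()
    wait = 0
    for _epoch in range(max_epochs):
        perm = rng.permutation(len(x_tr))
        losses = []
        correct = 0
        for start in range(0, len(perm), batch_size):
            idx = perm[start : start + batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            p = model.forward(xb)
            losses.append(bce_loss(p, yb) * len(idx))
            correct += int(np.sum((p >= 0.5) == (yb >= 0.5)))
            pc = np.clip(p, _EPS, 1.0 - _EPS)
            # d(BCE)/dp; chained through the output sigmoid this is (p - y)/B
            dy = (pc - yb) / (pc * (1.0 - pc)) / len(idx)
            model.backward(dy)
            opt.step(model.params(), model.grads())
        history["loss"].append(float(np.sum(losses) / len(x_tr)))
        history["accuracy"].append(correct / len(x_tr))
        if n_val:
            p_val = model.predict(x_val)
            val_loss = bce_loss(p_val, y_val)
            history["val_loss"].append(val_loss)
            history["val_accuracy"].append(
                float(np.mean((p_val >= 0.5) == (y_val >= 0.5)))
            )
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_weights = model.get_weights()
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    break
    if n_val:
        model.set_weights(best_weights)
    return history
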