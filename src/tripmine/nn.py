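"""Minimal numpy neural-network layers with hand-written backpropagation.

Only what the relation classifiers need: dense layers (optionally applied per
time step), LSTM and GRU recurrences with masking, bidirectional wrappers, a
1-D convolution over time, masked pooling, and softmax cross-entropy.  All
layers share one contract:

* ``forward(...)`` caches what backward needs and returns the output;
* ``backward(dout)`` accumulates parameter gradients into ``grads`` and
  returns the gradient w.r.t. the input;
* ``params`` / ``grads`` are name -> array dicts consumed by :class:`SGD`.

Masking convention: ``mask`` is (B, T) boolean; at mask-false steps the
recurrent state is carried through unchanged, so padding columns (which are
all-zero by construction) never influence the result.
"""

from __future__ import annotations

import numpy as np


def glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype=np.float32):
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class Layer:
    """Base: parameter/gradient bookkeeping."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)


class Dense(Layer):
    """Affine map; inputs of any leading shape (..., n_in)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.params = {"W": glorot(rng, (n_in, n_out), dtype),
                       "b": np.zeros(n_out, dtype=dtype)}
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.grads["W"] += x2.T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pos = x > 0
        return np.where(self._pos, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._pos, dy, 0.0)


class LSTM(Layer):
    """Single-direction LSTM over (B, T, n_in) with state carry at masked steps.

    Gate layout in the fused weight matrix: input, forget, cell, output.
    The forget-gate bias starts at 1 (standard remedy for early forgetting).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.n_in, self.n_hidden = n_in, n_hidden
        b = np.zeros(4 * n_hidden, dtype=dtype)
        b[n_hidden : 2 * n_hidden] = 1.0
        self.params = {"W": glorot(rng, (n_in + n_hidden, 4 * n_hidden), dtype),
                       "b": b}
        self.zero_grad()

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        h = self.n_hidden
        dtype = x.dtype
        h_t = np.zeros((B, h), dtype=dtype)
        c_t = np.zeros((B, h), dtype=dtype)
        self._x, self._mask = x, mask
        self._cache = []
        H = np.empty((B, T, h), dtype=dtype)
        W, b = self.params["W"], self.params["b"]
        for t in range(T):
            xh = np.concatenate([x[:, t], h_t], axis=1)
            z = xh @ W + b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_new = f * c_t + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = mask[:, t, None].astype(dtype)
            self._cache.append((xh, i, f, g, o, c_t, tc, h_t, m))
            c_t = m * c_new + (1 - m) * c_t
            h_t = m * h_new + (1 - m) * h_t
            H[:, t] = h_t
        return H

    def backward(self, dH: np.ndarray) -> np.ndarray:
        B, T, _ = self._x.shape
        h = self.n_hidden
        W = self.params["W"]
        dx = np.zeros_like(self._x)
        dh_next = np.zeros((B, h), dtype=self._x.dtype)
        dc_next = np.zeros((B, h), dtype=self._x.dtype)
        for t in range(T - 1, -1, -1):
            xh, i, f, g, o, c_prev, tc, h_prev, m = self._cache[t]
            dh = dH[:, t] + dh_next
            dh_step = m * dh
            dh_carry = (1 - m) * dh
            dc = m * dc_next
            dc_carry = (1 - m) * dc_next
            do = dh_step * tc
            dc = dc + dh_step * o * (1 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g),
                 do * o * (1 - o)], axis=1)
            self.grads["W"] += xh.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dxh = dz @ W.T
            dx[:, t] = dxh[:, : self.n_in]
            dh_next = dxh[:, self.n_in :] + dh_carry
            dc_next = dc * f + dc_carry
        return dx


class GRU(Layer):
    """Single-direction GRU: h = (1-z)*h_prev + z*htilde, with mask carry."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.n_in, self.n_hidden = n_in, n_hidden
        self.params = {
            "Wg": glorot(rng, (n_in + n_hidden, 2 * n_hidden), dtype),
            "bg": np.zeros(2 * n_hidden, dtype=dtype),
            "Wh": glorot(rng, (n_in + n_hidden, n_hidden), dtype),
            "bh": np.zeros(n_hidden, dtype=dtype),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        h = self.n_hidden
        dtype = x.dtype
        h_t = np.zeros((B, h), dtype=dtype)
        self._x, self._mask = x, mask
        self._cache = []
        H = np.empty((B, T, h), dtype=dtype)
        Wg, bg = self.params["Wg"], self.params["bg"]
        Wh, bh = self.params["Wh"], self.params["bh"]
        for t in range(T):
            xh = np.concatenate([x[:, t], h_t], axis=1)
            zr = _sigmoid(xh @ Wg + bg)
            z, r = zr[:, :h], zr[:, h:]
            xrh = np.concatenate([x[:, t], r * h_t], axis=1)
            ht = np.tanh(xrh @ Wh + bh)
            h_new = (1 - z) * h_t + z * ht
            m = mask[:, t, None].astype(dtype)
            self._cache.append((xh, xrh, z, r, ht, h_t, m))
            h_t = m * h_new + (1 - m) * h_t
            H[:, t] = h_t
        return H

    def backward(self, dH: np.ndarray) -> np.ndarray:
        B, T, _ = self._x.shape
        h = self.n_hidden
        Wg, Wh = self.params["Wg"], self.params["Wh"]
        dx = np.zeros_like(self._x)
        dh_next = np.zeros((B, h), dtype=self._x.dtype)
        for t in range(T - 1, -1, -1):
            xh, xrh, z, r, ht, h_prev, m = self._cache[t]
            dh = dH[:, t] + dh_next
            dh_step = m * dh
            dh_carry = (1 - m) * dh
            dz = dh_step * (ht - h_prev)
            dht = dh_step * z
            dh_prev = dh_step * (1 - z) + dh_carry
            da = dht * (1 - ht * ht)  # pre-activation of candidate
            self.grads["Wh"] += xrh.T @ da
            self.grads["bh"] += da.sum(axis=0)
            dxrh = da @ Wh.T
            dx[:, t] += dxrh[:, : self.n_in]
            drh = dxrh[:, self.n_in :]
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r
            dzr = np.concatenate([dz * z * (1 - z), dr * r * (1 - r)], axis=1)
            self.grads["Wg"] += xh.T @ dzr
            self.grads["bg"] += dzr.sum(axis=0)
            dxh = dzr @ Wg.T
            dx[:, t] += dxh[:, : self.n_in]
            dh_next = dh_prev + dxh[:, self.n_in :]
        return dx


class Bidirectional(Layer):
    """Run two recurrent layers over opposite time orders; concatenate states."""

    def __init__(self, fwd: Layer, bwd: Layer) -> None:
        super().__init__()
        self.fwd, self.bwd = fwd, bwd
        self.params = {f"fwd.{k}": v for k, v in fwd.params.items()}
        self.params.update({f"bwd.{k}": v for k, v in bwd.params.items()})
        self.zero_grad()

    def zero_grad(self) -> None:
        self.fwd.zero_grad()
        self.bwd.zero_grad()
        self.grads = {f"fwd.{k}": v for k, v in self.fwd.grads.items()}
        self.grads.update({f"bwd.{k}": v for k, v in self.bwd.grads.items()})

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x, mask)
        hb = self.bwd.forward(x[:, ::-1], mask[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dH: np.ndarray) -> np.ndarray:
        h = dH.shape[2] // 2
        dxf = self.fwd.backward(np.ascontiguousarray(dH[:, :, :h]))
        dxb = self.bwd.backward(np.ascontiguousarray(dH[:, ::-1, h:]))[:, ::-1]
        self.grads = {f"fwd.{k}": v for k, v in self.fwd.grads.items()}
        self.grads.update({f"bwd.{k}": v for k, v in self.bwd.grads.items()})
        return dxf + dxb


class Conv1D(Layer):
    """Same-padded 1-D convolution over time: (B, T, n_in) -> (B, T, filters)."""

    def __init__(self, n_in: int, filters: int, window: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        self.n_in, self.filters, self.window = n_in, filters, window
        self.params = {"W": glorot(rng, (window * n_in, filters), dtype),
                       "b": np.zeros(filters, dtype=dtype)}
        self.zero_grad()

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        pad = self.window // 2
        xp = np.zeros((B, T + 2 * pad, D), dtype=x.dtype)
        xp[:, pad : pad + T] = x
        cols = np.concatenate(
            [xp[:, k : k + T] for k in range(self.window)], axis=2
        )
        return cols  # (B, T, window * n_in)

    def forward(self, x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        return self._cols @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, T, D = self._x_shape
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.grads["W"] += cols2.T @ dy2
        self.grads["b"] += dy2.sum(axis=0)
        dcols = (dy @ self.params["W"].T).reshape(B, T, self.window * D)
        pad = self.window // 2
        dxp = np.zeros((B, T + 2 * pad, D), dtype=dy.dtype)
        for k in range(self.window):
            dxp[:, k : k + T] += dcols[:, :, k * D : (k + 1) * D]
        return dxp[:, pad : pad + T]


class MaskedMaxPool(Layer):
    """Max over time with masked steps excluded: (B, T, F) -> (B, F)."""

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        neg = np.where(mask[:, :, None], x, -np.inf)
        self._arg = neg.argmax(axis=1)  # (B, F)
        self._shape = x.shape
        return np.take_along_axis(x, self._arg[:, None, :], axis=1)[:, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=dy.dtype)
        np.put_along_axis(dx, self._arg[:, None, :], dy[:, None, :], axis=1)
        return dx


class MaskedMeanPool(Layer):
    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        m = mask.astype(x.dtype)
        self._m = m
        self._n = np.maximum(m.sum(axis=1, keepdims=True), 1.0)  # (B, 1)
        return (x * m[:, :, None]).sum(axis=1) / self._n

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (dy / self._n)[:, None, :] * self._m[:, :, None]


class FinalState(Layer):
    """Last mask-true step of each sequence: (B, T, F) -> (B, F)."""

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        T = x.shape[1]
        idx = np.where(mask.any(axis=1),
                       T - 1 - mask[:, ::-1].argmax(axis=1), 0)
        self._idx, self._shape = idx, x.shape
        return x[np.arange(x.shape[0]), idx]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=dy.dtype)
        dx[np.arange(dx.shape[0]), self._idx] = dy
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits.astype(np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy; returns (loss, dlogits, probabilities)."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, dlogits.astype(logits.dtype), p


def global_grad_norm(layers) -> float:
    total = 0.0
    for layer in layers:
        for g in layer.grads.values():
            total += float((g.astype(np.float64) ** 2).sum())
    return float(np.sqrt(total))


class SGD:
    """Plain mini-batch stochastic gradient descent with global-norm clipping."""

    def __init__(self, layers, learning_rate: float, clip_norm: float | None = 5.0):
        self.layers = list(layers)
        self.learning_rate = learning_rate
        self.clip_norm = clip_norm

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            norm = global_grad_norm(self.layers)
            if norm > self.clip_norm:
                scale = self.clip_norm / (norm + 1e-12)
        for layer in self.layers:
            for k, p in layer.params.items():
                p -= (self.learning_rate * scale) * layer.grads[k]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()
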