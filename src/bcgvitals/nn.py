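"""Minimal dense/conv/LSTM network stack with explicit backpropagation.

All math is float64 NumPy. Every layer implements ``forward`` (caching
what backward needs) and ``backward`` (returning the gradient w.r.t.
its input while accumulating parameter gradients), so analytic
gradients can be validated against central finite differences to high
precision. Input tensors for the convolutional front end are
(batch, T, H, W, C); recurrent layers take (batch, T, features).
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Dense",
    "TimeDistributed",
    "Conv",
    "LeakyReLU",
    "MaxPool",
    "Dropout",
    "FlattenFeatures",
    "FlattenDense",
    "LSTM",
    "Softmax",
    "Adam",
    "softmax_cross_entropy",
    "mse_loss",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine map on the last axis."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense"):
        lim = np.sqrt(6.0 / (n_in + n_out))
        self.W = Param(rng.uniform(-lim, lim, size=(n_in, n_out)), f"{name}.W")
        self.b = Param(np.zeros(n_out), f"{name}.b")
        self.name = name

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.W.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return grad @ self.W.value.T


class TimeDistributed(Layer):
    """Apply an inner layer independently at every timestep by folding
    the time axis into the batch axis."""

    def __init__(self, inner: Layer):
        self.inner = inner

    def params(self):
        return self.inner.params()

    def forward(self, x, train=False):
        b, t = x.shape[:2]
        self._bt = (b, t)
        y = self.inner.forward(x.reshape(b * t, *x.shape[2:]), train)
        return y.reshape(b, t, *y.shape[1:])

    def backward(self, grad):
        b, t = self._bt
        g = self.inner.backward(grad.reshape(b * t, *grad.shape[2:]))
        return g.reshape(b, t, *g.shape[1:])


class Conv(Layer):
    """2-D convolution over (H, W, C) inputs with a (1, k) kernel and
    same padding along W — the height axis is a singleton in this
    architecture, so the kernel slides along the feature width only."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, name: str = "conv"):
        lim = np.sqrt(6.0 / (k * c_in + k * c_out))
        self.K = Param(rng.uniform(-lim, lim, size=(k, c_in, c_out)), f"{name}.K")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self.k = k
        self.name = name

    def params(self):
        return [self.K, self.b]

    def forward(self, x, train=False):
        # x: (N, H, W, C_in); conv along W, same padding
        n, h, w, ci = x.shape
        self._shape = x.shape
        pad_l = (self.k - 1) // 2
        pad_r = self.k - 1 - pad_l
        xp = np.pad(x, ((0, 0), (0, 0), (pad_l, pad_r), (0, 0)))
        cols = np.stack([xp[:, :, d : d + w, :] for d in range(self.k)], axis=3)
        self._cols = cols  # (N, H, W, k, C_in)
        return np.einsum("nhwkc,kco->nhwo", cols, self.K.value, optimize=True) + self.b.value

    def backward(self, grad):
        n, h, w, ci = self._shape
        self.K.grad += np.einsum("nhwkc,nhwo->kco", self._cols, grad, optimize=True)
        self.b.grad += grad.sum(axis=(0, 1, 2))
        gcols = np.einsum("nhwo,kco->nhwkc", grad, self.K.value, optimize=True)
        pad_l = (self.k - 1) // 2
        pad_r = self.k - 1 - pad_l
        gx = np.zeros((n, h, w + self.k - 1, ci))
        for d in range(self.k):
            gx[:, :, d : d + w, :] += gcols[:, :, :, d, :]
        return gx[:, :, pad_l : pad_l + w, :]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, train=False):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class MaxPool(Layer):
    """Halving max-pool along the W axis of (N, H, W, C)."""

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        self._odd = w % 2
        if self._odd:
            x = x[:, :, : w - 1, :]
        xr = x.reshape(n, h, w // 2, 2, c)
        self._arg = xr.argmax(axis=3)
        self._shape = (n, h, w, c)
        return xr.max(axis=3)

    def backward(self, grad):
        n, h, w, c = self._shape
        gx = np.zeros((n, h, w // 2, 2, c))
        idx = np.indices(self._arg.shape)
        gx[idx[0], idx[1], idx[2], self._arg, idx[3]] = grad
        gx = gx.reshape(n, h, (w // 2) * 2, c)
        if self._odd:
            gx = np.pad(gx, ((0, 0), (0, 0), (0, 1), (0, 0)))
        return gx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class FlattenFeatures(Layer):
    """Collapse all trailing axes of (N, ...) into one feature axis."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class FlattenDense(Layer):
    """Flatten (N, H, W, C) into features and apply one dense map."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "fc"):
        self.flat = FlattenFeatures()
        self.dense = Dense(n_in, n_out, rng, name)

    def params(self):
        return self.dense.params()

    def forward(self, x, train=False):
        return self.dense.forward(self.flat.forward(x, train), train)

    def backward(self, grad):
        return self.flat.backward(self.dense.backward(grad))


class LSTM(Layer):
    """LSTM over (batch, T, n_in) with forget/input/output gates.

    Gate pre-activations are packed [f, i, o, g] where g is the cell
    candidate; f, i, o pass through the logistic function, g and the
    cell state through tanh. Initial cell and hidden states are zero.
    ``return_sequences`` keeps every step's hidden state, otherwise the
    last step only.
    """

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator,
                 return_sequences: bool = True, name: str = "lstm"):
        lim = np.sqrt(6.0 / (n_in + n_units))
        self.Wx = Param(rng.uniform(-lim, lim, size=(n_in, 4 * n_units)), f"{name}.Wx")
        limr = np.sqrt(6.0 / (2 * n_units))
        self.Wh = Param(rng.uniform(-limr, limr, size=(n_units, 4 * n_units)), f"{name}.Wh")
        self.b = Param(np.zeros(4 * n_units), f"{name}.b")
        self.n_units = n_units
        self.return_sequences = return_sequences
        self.name = name

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x, train=False):
        b, t, _ = x.shape
        H = self.n_units
        self._x = x
        h = np.zeros((b, H))
        c = np.zeros((b, H))
        self._cache = []
        hs = np.empty((b, t, H))
        for step in range(t):
            z = x[:, step, :] @ self.Wx.value + h @ self.Wh.value + self.b.value
            f = _sigmoid(z[:, :H])
            i = _sigmoid(z[:, H : 2 * H])
            o = _sigmoid(z[:, 2 * H : 3 * H])
            g = np.tanh(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, f, i, o, g, tc))
            h, c = h_new, c_new
            hs[:, step, :] = h
        self._hs = hs
        return hs if self.return_sequences else hs[:, -1, :]

    def backward(self, grad):
        x = self._x
        b, t, _ = x.shape
        H = self.n_units
        gx = np.zeros_like(x)
        dh_next = np.zeros((b, H))
        dc_next = np.zeros((b, H))
        if self.return_sequences:
            gseq = grad
        else:
            gseq = np.zeros((b, t, H))
            gseq[:, -1, :] = grad
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, f, i, o, g, tc = self._cache[step]
            dh = gseq[:, step, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dz = np.concatenate(
                [
                    df * f * (1.0 - f),
                    di * i * (1.0 - i),
                    do * o * (1.0 - o),
                    dg * (1.0 - g**2),
                ],
                axis=1,
            )
            self.Wx.grad += x[:, step, :].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            gx[:, step, :] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
            dc_next = dc * f
        return gx


class Softmax(Layer):
    def forward(self, x, train=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, grad):
        p = self._p
        return p * (grad - (grad * p).sum(axis=-1, keepdims=True))


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer ``labels`` under softmax(logits);
    returns the loss and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    n = logits.shape[0]
    loss = -float(logp[np.arange(n), labels].mean())
    grad = np.exp(logp)
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
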