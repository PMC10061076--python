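"""Layers with hand-derived backward passes.

Every layer exposes ``forward(x, train)`` and ``backward(dout)``; parameters
are ``Param`` objects accumulating gradients in ``.grad``.  Shapes follow the
common DL-framework conventions: 2D inputs are ``(batch, features)``, conv
inputs ``(batch, channels, height, width)``, recurrent inputs
``(batch, steps, features)``.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay  # whether L2 weight decay applies


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(n_in)
        self.w = Param(rng.uniform(-k, k, size=(n_in, n_out)))
        self.b = Param(rng.uniform(-k, k, size=n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train: bool):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class BatchNorm(Layer):
    """Batch normalization over axis 0 of a (batch, features) input."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features), decay=False)
        self.beta = Param(np.zeros(n_features), decay=False)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train: bool):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._ivar
        self._train = train
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dout):
        xhat, ivar = self._xhat, self._ivar
        self.gamma.grad += (dout * xhat).sum(axis=0)
        self.beta.grad += dout.sum(axis=0)
        dxhat = dout * self.gamma.value
        if not self._train:
            return dxhat * ivar
        n = dout.shape[0]
        return (ivar / n) * (n * dxhat - dxhat.sum(axis=0)
                             - xhat * (dxhat * xhat).sum(axis=0))


class ReLU(Layer):
    def forward(self, x, train: bool):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train: bool):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def _im2col(x, kh, kw):
    n, c, h, w = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + oh, j:j + ow]
    return cols.reshape(n, c * kh * kw, oh * ow), oh, ow


class Conv2d(Layer):
    """2D convolution (cross-correlation) with explicit zero padding."""

    def __init__(self, c_in: int, c_out: int, kh: int, kw: int,
                 pad_h: int, pad_w: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(c_in * kh * kw)
        self.w = Param(rng.uniform(-k, k, size=(c_out, c_in * kh * kw)))
        self.b = Param(rng.uniform(-k, k, size=c_out))
        self.kh, self.kw = kh, kw
        self.pad = (pad_h, pad_w)

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train: bool):
        ph, pw = self.pad
        if x.shape[2] + 2 * ph < self.kh or x.shape[3] + 2 * pw < self.kw:
            raise ValueError("input grid smaller than convolution kernel")
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        cols, oh, ow = _im2col(xp, self.kh, self.kw)
        self._cols = cols
        self._xp_shape = xp.shape
        out = np.matmul(self.w.value, cols) + self.b.value[None, :, None]
        return out.reshape(x.shape[0], -1, oh, ow)

    def backward(self, dout):
        n, c_out, oh, ow = dout.shape
        dflat = dout.reshape(n, c_out, oh * ow)
        self.w.grad += np.einsum("nop,nkp->ok", dflat, self._cols)
        self.b.grad += dflat.sum(axis=(0, 2))
        dcols = np.matmul(self.w.value.T, dflat)  # (n, c*kh*kw, oh*ow)
        _, c, hp, wp = self._xp_shape
        dxp = np.zeros(self._xp_shape, dtype=dout.dtype)
        dcols = dcols.reshape(n, c, self.kh, self.kw, oh, ow)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i:i + oh, j:j + ow] += dcols[:, :, i, j]
        ph, pw = self.pad
        return dxp[:, :, ph:hp - ph or None, pw:wp - pw or None]


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class LSTM(Layer):
    """Single-layer LSTM over (batch, steps, features); returns all hidden
    states.  Carries separate input-hidden and hidden-hidden bias vectors.
    Gate order: input, forget, cell, output."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(n_hidden)
        self.w_ih = Param(rng.uniform(-k, k, size=(4 * n_hidden, n_in)))
        self.w_hh = Param(rng.uniform(-k, k, size=(4 * n_hidden, n_hidden)))
        self.b_ih = Param(rng.uniform(-k, k, size=4 * n_hidden))
        self.b_hh = Param(rng.uniform(-k, k, size=4 * n_hidden))
        self.n_hidden = n_hidden

    def params(self):
        return [self.w_ih, self.w_hh, self.b_ih, self.b_hh]

    def forward(self, x, train: bool):
        n, steps, _ = x.shape
        hdim = self.n_hidden
        h = np.zeros((n, hdim))
        c = np.zeros((n, hdim))
        self._cache = []
        self._x = x
        out = np.empty((n, steps, hdim))
        for t in range(steps):
            z = (x[:, t] @ self.w_ih.value.T + self.b_ih.value
                 + h @ self.w_hh.value.T + self.b_hh.value)
            i = _sigmoid(z[:, :hdim])
            f = _sigmoid(z[:, hdim:2 * hdim])
            g = np.tanh(z[:, 2 * hdim:3 * hdim])
            o = _sigmoid(z[:, 3 * hdim:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            out[:, t] = h
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
        return out

    def backward(self, dout):
        x = self._x
        n, steps, _ = x.shape
        hdim = self.n_hidden
        dx = np.zeros_like(x)
        dh_next = np.zeros((n, hdim))
        dc_next = np.zeros((n, hdim))
        for t in range(steps - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = self._cache[t]
            dh = dout[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            self.w_ih.grad += dz.T @ x[:, t]
            self.w_hh.grad += dz.T @ h_prev
            self.b_ih.grad += dz.sum(axis=0)
            self.b_hh.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.w_ih.value
            dh_next = dz @ self.w_hh.value
            dc_next = dc * f
        return dx


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay (decay added
    to the gradient, as in the common framework default)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        for k, p in enumerate(self.params):
            g = p.grad
            if self.wd and p.decay:
                g = g + self.wd * p.value
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
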