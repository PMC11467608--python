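"""Layers, losses and the Adam optimizer (pure numpy, explicit backprop)."""

from __future__ import annotations

import numpy as np

from ..errors import ConfigError


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def astype(self, dtype) -> None:
        self.value = self.value.astype(dtype)
        self.grad = self.grad.astype(dtype)


def orthogonal(rng: np.random.Generator, shape: tuple[int, int], gain: float = 1.0) -> np.ndarray:
    """Orthogonal initialization for a 2-D weight matrix."""
    rows, cols = shape
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))  # deterministic sign convention
    if rows < cols:
        q = q.T
    return gain * q[:rows, :cols]


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(orthogonal(rng, (d_in, d_out)))
        self.b = Param(np.zeros(d_out))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Conv2d(Layer):
    """Same-padding 2-D convolution over (N, C, H, W) via im2col."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, int],
        rng: np.random.Generator,
    ):
        kh, kw = kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ConfigError("conv kernel dims must be odd for same padding")
        self.c_in, self.c_out, self.kh, self.kw = c_in, c_out, kh, kw
        self.W = Param(orthogonal(rng, (c_out, c_in * kh * kw)))
        self.b = Param(np.zeros(c_out))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    # Below this im2col size the materialized patch matrix is cheap and one
    # big GEMM beats the per-shift accumulation.
    _IM2COL_MAX_K = 64

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, H, Wd = x.shape
        ph, pw = self.kh // 2, self.kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        self._xp, self._in_shape = xp, x.shape
        K = C * self.kh * self.kw
        if K <= self._IM2COL_MAX_K:
            cols = np.empty((N, H, Wd, K), dtype=x.dtype)
            k = 0
            for i in range(self.kh):
                for j in range(self.kw):
                    cols[..., k * C : (k + 1) * C] = xp[
                        :, :, i : i + H, j : j + Wd
                    ].transpose(0, 2, 3, 1)
                    k += 1
            self._cols = cols.reshape(N * H * Wd, K)
            out = self._cols @ self.W.value.T + self.b.value
            return np.ascontiguousarray(
                out.reshape(N, H, Wd, self.c_out).transpose(0, 3, 1, 2)
            )
        # sum over kernel shifts of (N*H*W, C) x (C, F) GEMMs: avoids
        # materializing the kh*kw-fold duplicated im2col matrix
        self._cols = None
        out = np.zeros((N, H, Wd, self.c_out), dtype=x.dtype)
        k = 0
        for i in range(self.kh):
            for j in range(self.kw):
                wk = self.W.value[:, k * C : (k + 1) * C]  # (F, C)
                out += np.tensordot(xp[:, :, i : i + H, j : j + Wd], wk, axes=([1], [1]))
                k += 1
        out += self.b.value
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, Wd = self._in_shape
        ph, pw = self.kh // 2, self.kw // 2
        gt = np.ascontiguousarray(grad.transpose(0, 2, 3, 1))  # (N, H, W, F)
        self.b.grad += gt.sum(axis=(0, 1, 2))
        gxp = np.zeros_like(self._xp)
        if self._cols is not None:
            gl = gt.reshape(N * H * Wd, self.c_out)
            self.W.grad += gl.T @ self._cols
            gcols = (gl @ self.W.value).reshape(N, H, Wd, -1)
            k = 0
            for i in range(self.kh):
                for j in range(self.kw):
                    gxp[:, :, i : i + H, j : j + Wd] += gcols[
                        ..., k * C : (k + 1) * C
                    ].transpose(0, 3, 1, 2)
                    k += 1
            return gxp[:, :, ph : ph + H, pw : pw + Wd]
        k = 0
        for i in range(self.kh):
            for j in range(self.kw):
                patch = self._xp[:, :, i : i + H, j : j + Wd]
                self.W.grad[:, k * C : (k + 1) * C] += np.tensordot(
                    gt, patch, axes=([0, 1, 2], [0, 2, 3])
                )
                wk = self.W.value[:, k * C : (k + 1) * C]
                gxp[:, :, i : i + H, j : j + Wd] += np.tensordot(
                    gt, wk, axes=([3], [0])
                ).transpose(0, 3, 1, 2)
                k += 1
        return gxp[:, :, ph : ph + H, pw : pw + Wd]


class MaxPool2d(Layer):
    """Non-overlapping max pooling; trailing rows/cols are dropped."""

    def __init__(self, ph: int, pw: int):
        self.ph, self.pw = ph, pw

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, H, Wd = x.shape
        Ho, Wo = H // self.ph, Wd // self.pw
        xc = x[:, :, : Ho * self.ph, : Wo * self.pw]
        xr = xc.reshape(N, C, Ho, self.ph, Wo, self.pw)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Ho, Wo, self.ph * self.pw)
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, Wd = self._in_shape
        Ho, Wo = H // self.ph, Wd // self.pw
        gr = np.zeros((N, C, Ho, Wo, self.ph * self.pw), dtype=grad.dtype)
        np.put_along_axis(gr, self._idx[..., None], grad[..., None], axis=-1)
        gr = gr.reshape(N, C, Ho, Wo, self.ph, self.pw).transpose(0, 1, 2, 4, 3, 5)
        gx = np.zeros(self._in_shape, dtype=grad.dtype)
        gx[:, :, : Ho * self.ph, : Wo * self.pw] = gr.reshape(N, C, Ho * self.ph, Wo * self.pw)
        return gx


class GroupNorm(Layer):
    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        if channels % groups != 0:
            raise ConfigError("channels must be divisible by groups")
        self.g, self.c, self.eps = groups, channels, eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, H, Wd = x.shape
        xg = x.reshape(N, self.g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = np.maximum((xg * xg).mean(axis=2, keepdims=True) - mu * mu, 0.0)
        self._std = np.sqrt(var + self.eps)
        self._xhat = ((xg - mu) / self._std).reshape(x.shape)
        return self._xhat * self.gamma.value[None, :, None, None] + self.beta.value[
            None, :, None, None
        ]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, C, H, Wd = grad.shape
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        gxhat = (grad * self.gamma.value[None, :, None, None]).reshape(N, self.g, -1)
        xhat = self._xhat.reshape(N, self.g, -1)
        m1 = gxhat.mean(axis=2, keepdims=True)
        m2 = (gxhat * xhat).mean(axis=2, keepdims=True)
        gx = (gxhat - m1 - xhat * m2) / self._std
        return gx.reshape(grad.shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Layer):
    """Single-layer LSTM over (N, T, D) returning the full (N, T, H) output."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.d_in, self.hidden = d_in, hidden
        self.Wx = Param(orthogonal(rng, (d_in, 4 * hidden)))
        self.Wh = Param(orthogonal(rng, (hidden, 4 * hidden)))
        self.b = Param(np.zeros(4 * hidden))

    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, T, D = x.shape
        H = self.hidden
        h = np.zeros((N, H), dtype=x.dtype)
        c = np.zeros((N, H), dtype=x.dtype)
        self._cache = []
        self._x = x
        hs = np.empty((N, T, H), dtype=x.dtype)
        for t in range(T):
            z = x[:, t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            self._cache.append((h, c, i, f, g, o, tc))
            h = o * tc
            c = c_new
            hs[:, t] = h
        return hs

    def backward(self, grad: np.ndarray) -> np.ndarray:
        N, T, H = grad.shape
        x = self._x
        gx = np.empty_like(x)
        dh_next = np.zeros((N, H), dtype=x.dtype)
        dc_next = np.zeros((N, H), dtype=x.dtype)
        for t in reversed(range(T)):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = grad[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.Wx.grad += x[:, t].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            gx[:, t] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
        return gx


class AdditiveAttention(Layer):
    """Bahdanau-style attention pooling a sequence (N, T, H) to (N, H)."""

    def __init__(self, hidden: int, attn_dim: int, rng: np.random.Generator):
        self.Wa = Param(orthogonal(rng, (hidden, attn_dim)))
        self.ba = Param(np.zeros(attn_dim))
        self.v = Param(orthogonal(rng, (attn_dim, 1))[:, 0])

    def params(self) -> list[Param]:
        return [self.Wa, self.ba, self.v]

    def forward(self, hs: np.ndarray, train: bool = True) -> np.ndarray:
        u = np.tanh(hs @ self.Wa.value + self.ba.value)  # (N, T, A)
        e = u @ self.v.value  # (N, T)
        e = e - e.max(axis=1, keepdims=True)
        alpha = np.exp(e)
        alpha /= alpha.sum(axis=1, keepdims=True)
        self._hs, self._u, self._alpha = hs, u, alpha
        return (alpha[..., None] * hs).sum(axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        hs, u, alpha = self._hs, self._u, self._alpha
        g_hs = alpha[..., None] * grad[:, None, :]
        g_alpha = (hs * grad[:, None, :]).sum(axis=-1)  # (N, T)
        g_e = alpha * (g_alpha - (g_alpha * alpha).sum(axis=1, keepdims=True))
        self.v.grad += (u * g_e[..., None]).sum(axis=(0, 1))
        g_u = g_e[..., None] * self.v.value
        g_pre = g_u * (1.0 - u**2)
        self.Wa.grad += np.einsum("nth,nta->ha", hs, g_pre)
        self.ba.grad += g_pre.sum(axis=(0, 1))
        g_hs += g_pre @ self.Wa.value.T
        return g_hs


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    return p / p.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    N = logits.shape[0]
    p = softmax_probs(logits)
    loss = float(-np.log(np.clip(p[np.arange(N), labels], 1e-300, None)).mean())
    grad = p.copy()
    grad[np.arange(N), labels] -= 1.0
    return loss, grad / N


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            mhat = m / (1.0 - self.b1**self.t)
            vhat = v / (1.0 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
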