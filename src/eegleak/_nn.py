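"""Minimal numpy neural-network layers with reverse-mode gradients.

Supports exactly what the two EEG classifiers need: temporal convolution,
depthwise spatial and temporal convolution, batch normalisation, ELU /
leaky-ReLU, average / max pooling along time, dropout, dense layers, a
softmax cross-entropy head and an Adam optimizer.  Tensors are
``(batch, feature_maps, height, time)`` in float32; convolutions run along
the time axis only, implemented as sliding-window views contracted with
BLAS through ``einsum``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _same_pads(k: int) -> tuple[int, int]:
    left = (k - 1) // 2
    return left, k - 1 - left


class Layer:
    """Base layer: forward caches what backward needs; params/grads are
    parallel lists of arrays updated in place by the optimizer."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, d_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ConvTime(Layer):
    """Convolution along time: weights (F_out, F_in, K), 'same' padding,
    stride 1, height dimension preserved."""

    def __init__(self, f_in: int, f_out: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True) -> None:
        super().__init__()
        self.k = kernel
        scale = np.sqrt(2.0 / (f_in * kernel))
        self.w = (rng.standard_normal((f_out, f_in, kernel)) * scale).astype(np.float32)
        self.params = [self.w]
        self.grads = [np.zeros_like(self.w)]
        self.b = None
        if bias:
            self.b = np.zeros(f_out, dtype=np.float32)
            self.params.append(self.b)
            self.grads.append(np.zeros_like(self.b))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        pl, pr = _same_pads(self.k)
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (pl, pr)))
        win = sliding_window_view(xp, self.k, axis=3)  # (N,Fin,H,T,K)
        self._win = win if train else None
        out = np.einsum("nfhtk,ofk->noht", win, self.w, optimize=True)
        if self.b is not None:
            out += self.b[None, :, None, None]
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        pl, pr = _same_pads(self.k)
        self.grads[0][...] = np.einsum("nfhtk,noht->ofk", self._win, d_out, optimize=True)
        if self.b is not None:
            self.grads[1][...] = d_out.sum(axis=(0, 2, 3))
        dp = np.pad(d_out, ((0, 0), (0, 0), (0, 0), (self.k - 1 - pl, self.k - 1 - pr)))
        dwin = sliding_window_view(dp, self.k, axis=3)
        dx = np.einsum("nohtk,ofk->nfht", dwin, self.w[:, :, ::-1], optimize=True)
        self._win = None
        return np.ascontiguousarray(dx, dtype=np.float32)


class DepthwiseSpatial(Layer):
    """Collapses the height (electrode) axis: for each of F input maps,
    D spatial filters spanning all H electrodes; output (N, F*D, 1, T)."""

    def __init__(self, f_in: int, depth: int, height: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.f_in, self.depth = f_in, depth
        scale = np.sqrt(2.0 / height)
        self.w = (rng.standard_normal((f_in, depth, height)) * scale).astype(np.float32)
        self.params = [self.w]
        self.grads = [np.zeros_like(self.w)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        out = np.einsum("nfht,fdh->nfdt", x, self.w, optimize=True)
        n, f, d, t = out.shape
        return np.ascontiguousarray(out.reshape(n, f * d, 1, t), dtype=np.float32)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        n, fd, _, t = d_out.shape
        d4 = d_out.reshape(n, self.f_in, self.depth, t)
        self.grads[0][...] = np.einsum("nfht,nfdt->fdh", self._x, d4, optimize=True)
        dx = np.einsum("nfdt,fdh->nfht", d4, self.w, optimize=True)
        self._x = None
        return np.ascontiguousarray(dx, dtype=np.float32)


class DepthwiseTime(Layer):
    """Per-map temporal convolution (one K-tap filter per feature map)."""

    def __init__(self, f: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.k = kernel
        self.w = (rng.standard_normal((f, kernel)) * np.sqrt(2.0 / kernel)).astype(np.float32)
        self.params = [self.w]
        self.grads = [np.zeros_like(self.w)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        pl, pr = _same_pads(self.k)
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (pl, pr)))
        win = sliding_window_view(xp, self.k, axis=3)
        self._win = win if train else None
        return np.ascontiguousarray(
            np.einsum("nfhtk,fk->nfht", win, self.w, optimize=True), dtype=np.float32)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        pl, pr = _same_pads(self.k)
        self.grads[0][...] = np.einsum("nfhtk,nfht->fk", self._win, d_out, optimize=True)
        dp = np.pad(d_out, ((0, 0), (0, 0), (0, 0), (self.k - 1 - pl, self.k - 1 - pr)))
        dwin = sliding_window_view(dp, self.k, axis=3)
        dx = np.einsum("nfhtk,fk->nfht", dwin, self.w[:, ::-1], optimize=True)
        self._win = None
        return np.ascontiguousarray(dx, dtype=np.float32)


class BatchNorm(Layer):
    """Per-feature-map batch normalisation with running eval statistics."""

    def __init__(self, f: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(f, dtype=np.float32)
        self.beta = np.zeros(f, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.run_mean = np.zeros(f, dtype=np.float32)
        self.run_var = np.ones(f, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._xhat, self._inv = xhat, inv
        return (self.gamma[None, :, None, None] * xhat
                + self.beta[None, :, None, None]).astype(np.float32)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        m = d_out.shape[0] * d_out.shape[2] * d_out.shape[3]
        self.grads[0][...] = (d_out * self._xhat).sum(axis=axes)
        self.grads[1][...] = d_out.sum(axis=axes)
        g = self.gamma[None, :, None, None]
        inv = self._inv[None, :, None, None]
        dxhat = d_out * g
        dx = inv / m * (m * dxhat
                        - dxhat.sum(axis=axes, keepdims=True)
                        - self._xhat * (dxhat * self._xhat).sum(axis=axes, keepdims=True))
        self._xhat = self._inv = None
        return dx.astype(np.float32)


class ELU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
        self._out, self._pos = (out, x > 0) if train else (None, None)
        return out.astype(np.float32)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        dx = d_out * np.where(self._pos, 1.0, self._out + 1.0)
        self._out = self._pos = None
        return dx.astype(np.float32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._pos = x > 0 if train else None
        return np.where(x > 0, x, self.slope * x).astype(np.float32)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        dx = d_out * np.where(self._pos, 1.0, self.slope)
        self._pos = None
        return dx.astype(np.float32)


class AvgPoolTime(Layer):
    """Average pooling by an integer factor along time; trailing samples
    that do not fill a window are dropped (floor semantics)."""

    def __init__(self, factor: int) -> None:
        super().__init__()
        self.p = factor

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, f, h, t = x.shape
        tt = (t // self.p) * self.p
        self._t_in = t
        return x[..., :tt].reshape(n, f, h, tt // self.p, self.p).mean(axis=4)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        n, f, h, to = d_out.shape
        dx = np.zeros((n, f, h, self._t_in), dtype=np.float32)
        dx[..., :to * self.p] = np.repeat(d_out / self.p, self.p, axis=3)
        return dx


class MaxPoolTime(Layer):
    def __init__(self, factor: int) -> None:
        super().__init__()
        self.p = factor

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, f, h, t = x.shape
        tt = (t // self.p) * self.p
        self._t_in = t
        xr = x[..., :tt].reshape(n, f, h, tt // self.p, self.p)
        self._arg = xr.argmax(axis=4) if train else None
        return xr.max(axis=4)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        n, f, h, to = d_out.shape
        dxr = np.zeros((n, f, h, to, self.p), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None], d_out[..., None], axis=4)
        dx = np.zeros((n, f, h, self._t_in), dtype=np.float32)
        dx[..., :to * self.p] = dxr.reshape(n, f, h, to * self.p)
        self._arg = None
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(np.float32)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return d_out
        dx = d_out * self._mask
        self._mask = None
        return dx.astype(np.float32)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        return d_out.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.w = (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return x @ self.w + self.b

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ d_out
        self.grads[1][...] = d_out.sum(axis=0)
        dx = d_out @ self.w.T
        self._x = None
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                upto: int | None = None) -> np.ndarray:
        for layer in self.layers[:upto]:
            x = layer.forward(x, train)
        return x

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            d_out = layer.backward(d_out)
        return d_out

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(p, g) for layer in self.layers for p, g in zip(layer.params, layer.grads)]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
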