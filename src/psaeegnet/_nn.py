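"""Minimal neural-network layers with explicit, hand-derived gradients.

All feature maps are arrays of shape ``(batch, channels, height, width)``;
for EEG epochs the height axis carries electrodes and the width axis time.
Every layer implements ``forward(x, training, rng)`` and ``backward(dy)``;
parameters live in ``layer.params`` (name -> array) and gradients of the
most recent backward pass in ``layer.grads``. The layers are the smallest
set needed by the host network: temporal (grouped / depthwise) convolution,
a full-height spatial depthwise convolution, batch normalisation, ELU,
windowed average pooling with an explicit target length, dropout, affine
map and softmax.

Long temporal convolutions are evaluated in the frequency domain
(correlation theorem, real FFTs, linear-convolution padding); short ones
with sliding-window views contracted by einsum. Both paths are exact up to
floating round-off and share one gradient derivation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sp_fft

DEFAULT_DTYPE = np.float32

# kernel length at/above which the FFT path is used for temporal convolution
_FFT_KERNEL_THRESHOLD = 32


def truncated_normal(rng: np.random.Generator, shape, std: float, dtype):
    """Normal draws truncated at two standard deviations, then scaled."""
    x = rng.standard_normal(shape)
    bad = np.abs(x) > 2.0
    while bad.any():
        x[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(x) > 2.0
    return (x * std).astype(dtype, copy=False)


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training: bool = False, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError

    def named_params(self, prefix: str):
        for k, v in self.params.items():
            yield (f"{prefix}.{k}" if prefix else k), v

    def named_grads(self, prefix: str):
        for k, v in self.grads.items():
            yield (f"{prefix}.{k}" if prefix else k), v

    def n_params(self) -> int:
        return int(sum(v.size for _, v in self.named_params("p")))


def _same_padding(k: int) -> tuple[int, int]:
    # even kernels put the extra padded sample on the left
    return k // 2, (k - 1) // 2


class TemporalConv(Layer):
    """Bias-free correlation along the time (last) axis.

    weight shape: (out_ch, in_ch // groups, k). ``padding`` is ``"same"``
    (output length equals input length) or ``"valid"``.
    """

    def __init__(self, in_ch, out_ch, kernel, groups=1, padding="same",
                 rng=None, dtype=DEFAULT_DTYPE):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError("channel counts must be divisible by groups")
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, int(kernel)
        self.groups, self.padding = groups, padding
        rng = rng or np.random.default_rng()
        fan_in = (in_ch // groups) * self.k
        self.params["w"] = truncated_normal(
            rng, (out_ch, in_ch // groups, self.k), fan_in ** -0.5, dtype)
        self._cache = None

    @property
    def depthwise(self) -> bool:
        return self.groups == self.in_ch and self.in_ch > 1

    def _pads(self):
        return _same_padding(self.k) if self.padding == "same" else (0, 0)

    # -- direct (windowed) path -------------------------------------------
    def _forward_direct(self, x):
        pl, pr = self._pads()
        w = self.params["w"]
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (pl, pr)))
        win = sliding_window_view(xp, self.k, axis=3)  # (B, Cin, H, Wo, k)
        if self.depthwise:
            m = self.out_ch // self.in_ch
            wk = w.reshape(self.in_ch, m, self.k)
            y = np.einsum("bchwk,cmk->bcmhw", win, wk, optimize=True)
            B, _, _, H, Wo = y.shape
            y = y.reshape(B, self.out_ch, H, Wo)
        elif self.groups == 1:
            y = np.einsum("bchwk,ock->bohw", win, w, optimize=True)
        else:
            cg, og = self.in_ch // self.groups, self.out_ch // self.groups
            outs = [np.einsum("bchwk,ock->bohw", win[:, g * cg:(g + 1) * cg],
                              w[g * og:(g + 1) * og], optimize=True)
                    for g in range(self.groups)]
            y = np.concatenate(outs, axis=1)
        self._cache = ("direct", x.shape, win)
        return y

    def _backward_direct(self, dy):
        _, xshape, win = self._cache
        pl, _ = self._pads()
        w = self.params["w"]
        W_in = xshape[3]
        if self.depthwise:
            m = self.out_ch // self.in_ch
            B, _, H, Wo = dy.shape
            dyr = dy.reshape(B, self.in_ch, m, H, Wo)
            dwk = np.einsum("bchwk,bcmhw->cmk", win, dyr, optimize=True)
            self.grads["w"] = dwk.reshape(self.out_ch, 1, self.k).astype(w.dtype)
            dyp = np.pad(dy, ((0, 0), (0, 0), (0, 0), (self.k - 1 - pl, pl)))
            gwin = sliding_window_view(dyp, self.k, axis=3)[..., :W_in, :]
            gwin = gwin.reshape(B, self.in_ch, m, H, W_in, self.k)
            wflip = w[:, 0, ::-1].reshape(self.in_ch, m, self.k)
            dx = np.einsum("bcmhwk,cmk->bchw", gwin, wflip, optimize=True)
            return dx
        if self.groups == 1:
            self.grads["w"] = np.einsum(
                "bchwk,bohw->ock", win, dy, optimize=True).astype(w.dtype)
            dyp = np.pad(dy, ((0, 0), (0, 0), (0, 0), (self.k - 1 - pl, pl)))
            gwin = sliding_window_view(dyp, self.k, axis=3)[..., :W_in, :]
            wflip = w[:, :, ::-1]
            dx = np.einsum("bohwk,ock->bchw", gwin, wflip, optimize=True)
            return dx
        cg, og = self.in_ch // self.groups, self.out_ch // self.groups
        dw = np.empty_like(w)
        dxs = []
        dyp = np.pad(dy, ((0, 0), (0, 0), (0, 0), (self.k - 1 - pl, pl)))
        gwin_all = sliding_window_view(dyp, self.k, axis=3)[..., :W_in, :]
        for g in range(self.groups):
            wg = w[g * og:(g + 1) * og]
            dyg = dy[:, g * og:(g + 1) * og]
            dw[g * og:(g + 1) * og] = np.einsum(
                "bchwk,bohw->ock", win[:, g * cg:(g + 1) * cg], dyg, optimize=True)
            dxs.append(np.einsum("bohwk,ock->bchw",
                                 gwin_all[:, g * og:(g + 1) * og],
                                 wg[:, :, ::-1], optimize=True))
        self.grads["w"] = dw
        return np.concatenate(dxs, axis=1)

    # -- FFT path (long kernels, groups == 1) ------------------------------
    def _forward_fft(self, x):
        pl, pr = self._pads()
        w = self.params["w"]
        B, C, H, W = x.shape
        Wo = W if self.padding == "same" else W - self.k + 1
        L = sp_fft.next_fast_len(W + self.k - 1, real=True)
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (pl, pr)))
        Xf = sp_fft.rfft(xp, n=L, axis=-1)
        Wf = sp_fft.rfft(w, n=L, axis=-1)
        Yf = np.einsum("bchf,ocf->bohf", Xf, np.conj(Wf), optimize=True)
        y = sp_fft.irfft(Yf, n=L, axis=-1)[..., :Wo].astype(x.dtype, copy=False)
        self._cache = ("fft", x.shape, Xf, Wf, L, Wo)
        return y

    def _backward_fft(self, dy):
        _, xshape, Xf, Wf, L, Wo = self._cache
        pl, _ = self._pads()
        w = self.params["w"]
        W_in = xshape[3]
        Gf = sp_fft.rfft(dy, n=L, axis=-1)
        dWf = np.einsum("bchf,bohf->ocf", Xf, np.conj(Gf), optimize=True)
        dw = sp_fft.irfft(dWf, n=L, axis=-1)[..., :self.k]
        self.grads["w"] = dw.astype(w.dtype, copy=False)
        dXf = np.einsum("bohf,ocf->bchf", Gf, Wf, optimize=True)
        dx = sp_fft.irfft(dXf, n=L, axis=-1)[..., pl:pl + W_in]
        return dx.astype(w.dtype, copy=False)

    def forward(self, x, training=False, rng=None):
        use_fft = self.k >= _FFT_KERNEL_THRESHOLD and self.groups == 1
        return self._forward_fft(x) if use_fft else self._forward_direct(x)

    def backward(self, dy):
        kind = self._cache[0]
        return self._backward_fft(dy) if kind == "fft" else self._backward_direct(dy)


class SpatialDepthwiseConv(Layer):
    """Depthwise convolution with a full-height kernel (valid padding).

    Collapses the electrode axis: input (B, C, H, W) -> (B, C*mult, 1, W),
    weight shape (C, mult, H). This is the EEGNet-style spatial filter.
    """

    def __init__(self, in_ch, height, mult=2, rng=None, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.in_ch, self.height, self.mult = in_ch, height, mult
        rng = rng or np.random.default_rng()
        self.params["w"] = truncated_normal(rng, (in_ch, mult, height),
                                            height ** -0.5, dtype)
        self._x = None

    def forward(self, x, training=False, rng=None):
        if x.shape[2] != self.height:
            raise ValueError(
                f"spatial depthwise expects height {self.height}, got {x.shape[2]}")
        self._x = x
        y = np.einsum("bchw,cdh->bcdw", x, self.params["w"], optimize=True)
        B, _, _, W = x.shape
        return y.reshape(B, self.in_ch * self.mult, 1, W)

    def backward(self, dy):
        x = self._x
        B, _, _, W = dy.shape
        dyr = dy.reshape(B, self.in_ch, self.mult, W)
        self.grads["w"] = np.einsum("bchw,bcdw->cdh", x, dyr, optimize=True)
        return np.einsum("bcdw,cdh->bchw", dyr, self.params["w"], optimize=True)


class BatchNorm2d(Layer):
    """Per-channel normalisation over (batch, height, width)."""

    def __init__(self, n_ch, eps=1e-5, momentum=0.1, dtype=DEFAULT_DTYPE):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(n_ch, dtype)
        self.params["beta"] = np.zeros(n_ch, dtype)
        self.running_mean = np.zeros(n_ch, dtype)
        self.running_var = np.ones(n_ch, dtype)
        self._cache = None

    def forward(self, x, training=False, rng=None):
        axes = (0, 2, 3)
        if training:
            if x.shape[0] < 2:
                raise ValueError("batch normalisation in training mode needs batch >= 2")
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            # eval path fused into one multiply-add; xhat kept lazily for
            # backward via the cached affine coefficients
            mu, var = self.running_mean, self.running_var
            inv = 1.0 / np.sqrt(var + self.eps)
            scale = (self.params["gamma"] * inv)[:, None, None]
            shift = (self.params["beta"] - self.params["gamma"] * mu * inv)[:, None, None]
            self._cache = (x, mu, inv, False)
            return x * scale + shift
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) * inv[:, None, None]
        self._cache = (xhat, None, inv, True)
        return self.params["gamma"][:, None, None] * xhat + self.params["beta"][:, None, None]

    def backward(self, dy):
        cached, mu, inv, training = self._cache
        axes = (0, 2, 3)
        if training:
            xhat = cached
        else:
            xhat = (cached - mu[:, None, None]) * inv[:, None, None]
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"][:, None, None] * inv[:, None, None]
        if not training:
            return dy * g
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        mean_dy = dy.mean(axis=axes)[:, None, None]
        mean_dyx = (dy * xhat).sum(axis=axes)[:, None, None] / n
        return g * (dy - mean_dy - xhat * mean_dyx)


class ELU(Layer):
    def __init__(self, alpha=1.0):
        super().__init__()
        self.alpha = alpha
        self._cache = None

    def forward(self, x, training=False, rng=None):
        neg = self.alpha * np.expm1(np.minimum(x, 0))
        y = np.where(x > 0, x, neg)
        self._cache = (x > 0, neg)
        return y

    def backward(self, dy):
        pos, neg = self._cache
        return dy * np.where(pos, 1.0, neg + self.alpha)


class AvgPoolTime(Layer):
    """Windowed average pooling along time with an explicit output length.

    Windows start at multiples of ``pool``; a final window shorter than
    ``pool`` averages only the samples that exist (right padding is never
    counted). With ``out_len`` beyond floor(W/pool) this reproduces
    ceil-style pooling; below it, trailing samples are dropped.
    """

    def __init__(self, pool, out_len=None):
        super().__init__()
        self.pool, self.out_len = pool, out_len
        self._cache = None

    def _bounds(self, W):
        n = self.out_len if self.out_len is not None else W // self.pool
        bounds = []
        for i in range(n):
            s = i * self.pool
            e = min(s + self.pool, W)
            if s >= W:
                raise ValueError(
                    f"pool target length {n} needs window start {s} < input length {W}")
            bounds.append((s, e))
        return bounds

    def forward(self, x, training=False, rng=None):
        W = x.shape[3]
        bounds = self._bounds(W)
        y = np.stack([x[..., s:e].mean(axis=3) for s, e in bounds], axis=3)
        self._cache = (x.shape, bounds)
        return y

    def backward(self, dy):
        xshape, bounds = self._cache
        dx = np.zeros(xshape, dtype=dy.dtype)
        for i, (s, e) in enumerate(bounds):
            dx[..., s:e] += dy[..., i:i + 1] / (e - s)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity when not training or p == 0."""

    def __init__(self, p=0.5):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask = None
        self._own_rng = np.random.default_rng(0)

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        rng = rng or self._own_rng
        keep = (rng.random(x.shape) >= self.p).astype(x.dtype)
        self._mask = keep / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in, n_out, bias=True, rng=None, dtype=DEFAULT_DTYPE):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["w"] = truncated_normal(rng, (n_in, n_out), n_in ** -0.5, dtype)
        if bias:
            self.params["b"] = np.zeros(n_out, dtype)
        self._x = None

    def forward(self, x, training=False, rng=None):
        self._x = x
        y = x @ self.params["w"]
        if "b" in self.params:
            y = y + self.params["b"]
        return y

    def backward(self, dy):
        self.grads["w"] = self._x.T @ dy
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["w"].T


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._pos = None

    def forward(self, x, training=False, rng=None):
        self._pos = x > 0
        return np.where(self._pos, x, 0.0)

    def backward(self, dy):
        return dy * self._pos


class Sigmoid(Layer):
    def __init__(self):
        super().__init__()
        self._y = None

    def forward(self, x, training=False, rng=None):
        y = 1.0 / (1.0 + np.exp(-x))
        self._y = y
        return y

    def backward(self, dy):
        y = self._y
        return dy * y * (1.0 - y)


class Softmax(Layer):
    """Row-wise softmax with the exact Jacobian in backward."""

    def __init__(self, axis=-1):
        super().__init__()
        self.axis = axis
        self._y = None

    def forward(self, x, training=False, rng=None):
        z = x - x.max(axis=self.axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=self.axis, keepdims=True)
        self._y = y
        return y

    def backward(self, dy):
        y = self._y
        return y * (dy - (dy * y).sum(axis=self.axis, keepdims=True))


class Sequential(Layer):
    def __init__(self, layers: list[tuple[str, Layer]]):
        super().__init__()
        self.layers = layers

    def forward(self, x, training=False, rng=None):
        for _, layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dy):
        for _, layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def named_params(self, prefix=""):
        for name, layer in self.layers:
            full = f"{prefix}.{name}" if prefix else name
            yield from layer.named_params(full)

    def named_grads(self, prefix=""):
        for name, layer in self.layers:
            full = f"{prefix}.{name}" if prefix else name
            yield from layer.named_grads(full)

    def named_layers(self, prefix=""):
        for name, layer in self.layers:
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(layer, Sequential):
                yield from layer.named_layers(full)
            else:
                yield full, layer


class Adam:
    """Adam with in-place parameter updates (Kingma & Ba defaults)."""

    def __init__(self, named_params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = dict(named_params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in self.params.items()}

    def step(self, named_grads: dict):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, g in named_grads.items():
            p = self.params[k]
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def get_state(layer: Layer) -> dict:
    state = {k: v.copy() for k, v in layer.named_params("")}
    for name, sub in _iter_bn(layer):
        state[f"{name}#running_mean"] = sub.running_mean.copy()
        state[f"{name}#running_var"] = sub.running_var.copy()
    return state


def set_state(layer: Layer, state: dict) -> None:
    for k, v in layer.named_params(""):
        v[...] = state[k]
    for name, sub in _iter_bn(layer):
        sub.running_mean = state[f"{name}#running_mean"].copy()
        sub.running_var = state[f"{name}#running_var"].copy()


def _iter_bn(layer):
    if isinstance(layer, Sequential):
        for name, sub in layer.named_layers(""):
            if isinstance(sub, BatchNorm2d):
                yield name, sub
    elif isinstance(layer, BatchNorm2d):
        yield "", layer
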