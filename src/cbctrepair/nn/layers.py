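"""Neural-network layers with hand-written forward/backward passes.

Convolution is im2col + matmul; transposed convolution is implemented as the
exact adjoint of the corresponding strided convolution, so the two share the
same three primitives (forward, data-gradient, weight-gradient). Batch
normalisation always uses batch statistics — with the batch size of 1 used
throughout this package that is instance-style normalisation, the behaviour
of the canonical conditional-GAN translation recipe.
"""

from __future__ import annotations

import hashlib

import numpy as np

F32 = np.float32


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride][:, :, :ho, :wo]  # (n,c,ho,wo,k,k)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int, ho: int, wo: int):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[:, :, i, j]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


def _conv_fwd(x, wmat, k, stride, pad):
    cols, ho, wo = _im2col(x, k, stride, pad)
    out = wmat @ cols  # (f, ckk) @ (n, ckk, L) -> (n, f, L)
    return out.reshape(x.shape[0], wmat.shape[0], ho, wo), cols, ho, wo


class Layer:
    """Base: parameter dict, gradient dict, trainable flag, checksum."""

    kind = "Layer"

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.trainable = True

    @property
    def parameterized(self) -> bool:
        return bool(self.params)

    def zero_grad(self):
        for k in self.grads:
            self.grads[k][...] = 0.0

    def checksum(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()

    def forward(self, x, training: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    kind = "Convolution 2D Layer"

    def __init__(self, in_ch: int, out_ch: int, k: int = 4, stride: int = 2, pad: int = 1,
                 rng: np.random.Generator | None = None, init_std: float = 0.02):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["w"] = rng.normal(0.0, init_std, (out_ch, in_ch, k, k)).astype(F32)
        self.params["b"] = np.zeros(out_ch, dtype=F32)
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def forward(self, x, training: bool):
        wmat = self.params["w"].reshape(self.out_ch, -1)
        out, cols, ho, wo = _conv_fwd(x, wmat, self.k, self.stride, self.pad)
        self._cache = (cols, x.shape, ho, wo)
        return out + self.params["b"][None, :, None, None]

    def backward(self, g):
        cols, x_shape, ho, wo = self._cache
        n = g.shape[0]
        g2 = g.reshape(n, self.out_ch, -1)
        self.grads["w"] += np.einsum("nfl,ncl->fc", g2, cols).reshape(self.params["w"].shape)
        self.grads["b"] += g2.sum(axis=(0, 2))
        wmat = self.params["w"].reshape(self.out_ch, -1)
        dcols = np.einsum("fc,nfl->ncl", wmat, g2)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, ho, wo)


class ConvTranspose2d(Layer):
    """Stride-s transposed convolution: the adjoint of Conv2d(k, s, pad)."""

    kind = "Transposed Convolution 2D Layer"

    def __init__(self, in_ch: int, out_ch: int, k: int = 4, stride: int = 2, pad: int = 1,
                 rng: np.random.Generator | None = None, init_std: float = 0.02):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["w"] = rng.normal(0.0, init_std, (in_ch, out_ch, k, k)).astype(F32)
        self.params["b"] = np.zeros(out_ch, dtype=F32)
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def _out_hw(self, h, w):
        return ((h - 1) * self.stride - 2 * self.pad + self.k,
                (w - 1) * self.stride - 2 * self.pad + self.k)

    def forward(self, x, training: bool):
        n, _, h, w = x.shape
        ho, wo = self._out_hw(h, w)
        wmat = self.params["w"].reshape(self.in_ch, -1)  # (cin, cout*k*k)
        x2 = x.reshape(n, self.in_ch, h * w)
        dcols = np.einsum("fc,nfl->ncl", wmat, x2)  # (n, cout*k*k, h*w)
        out = _col2im(dcols, (n, self.out_ch, ho, wo), self.k, self.stride, self.pad, h, w)
        self._cache = (x2, (h, w))
        return out + self.params["b"][None, :, None, None]

    def backward(self, g):
        x2, (h, w) = self._cache
        n = g.shape[0]
        cols_g, ho_c, wo_c = _im2col(g, self.k, self.stride, self.pad)  # L = h*w
        wmat = self.params["w"].reshape(self.in_ch, -1)
        dx = (wmat @ cols_g).reshape(n, self.in_ch, h, w)
        self.grads["w"] += np.einsum("nfl,ncl->fc", x2, cols_g).reshape(self.params["w"].shape)
        self.grads["b"] += g.sum(axis=(0, 2, 3))
        return dx


class BatchNorm2d(Layer):
    kind = "Batch Normalization Layer"

    def __init__(self, ch: int, eps: float = 1e-5, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.eps = eps
        self.params["gamma"] = rng.normal(1.0, 0.02, ch).astype(F32)
        self.params["beta"] = np.zeros(ch, dtype=F32)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training: bool):
        m = x.mean(axis=(0, 2, 3), keepdims=True)
        v = x.var(axis=(0, 2, 3), keepdims=True)
        std = np.sqrt(v + self.eps)
        xhat = (x - m) / std
        self._cache = (xhat, std, x.shape)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, g):
        xhat, std, shape = self._cache
        mcount = shape[0] * shape[2] * shape[3]
        self.grads["gamma"] += (g * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += g.sum(axis=(0, 2, 3))
        gxhat = g * self.params["gamma"][None, :, None, None]
        # dx for batch-statistics normalisation
        s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (gxhat - s1 / mcount - xhat * s2 / mcount) / std


class LeakyReLU(Layer):
    kind = "Leaky ReLU Layer"

    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x, training: bool):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g):
        return np.where(self._mask, g, self.slope * g)


class Tanh(Layer):
    kind = "Tanh Layer"

    def forward(self, x, training: bool):
        self._y = np.tanh(x)
        return self._y

    def backward(self, g):
        return g * (1.0 - self._y**2)


class Dropout(Layer):
    kind = "Dropout Layer"

    def __init__(self, rate: float = 0.5, rng: np.random.Generator | None = None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training: bool):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask
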