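"""Minimal volumetric NN layers with analytic gradients.

Arrays are single-sample, channels-first ``(C, X, Y, Z)``; mini-batches are
handled by the trainer, which accumulates gradients across samples.  Each
layer caches what its backward pass needs, exposes ``params`` / ``grads``
dicts, and returns the input gradient from ``backward``.

Convolutions are stride-1, same-padded, implemented by im2col + matmul; the
input gradient of a convolution is again a convolution with the
channel-transposed, spatially flipped kernel, so both passes share one
primitive.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3d",
    "Upsample3d",
    "MultiHeadAttention3d",
    "kaiming_conv",
]


class Layer:
    """Base class: parameterless layers reuse these empty dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


def kaiming_conv(cout: int, cin: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Kaiming-normal weights for a ReLU-followed convolution."""
    fan_in = cin * k**3
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k, k)).astype(np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, X, Y, Z) -> (C * k^3, N) patch matrix with same padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))  # (C, X, Y, Z, k, k, k)
    c = x.shape[0]
    n = x.shape[1] * x.shape[2] * x.shape[3]
    return win.transpose(0, 4, 5, 6, 1, 2, 3).reshape(c * k**3, n)


class Conv3d(Layer):
    """Stride-1 same-padded 3D convolution."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.params = {
            "W": kaiming_conv(cout, cin, k, rng),
            "b": np.zeros(cout, dtype=np.float32),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x, self.k)
        wmat = self.params["W"].reshape(self.cout, -1)
        y = wmat @ self._cols + self.params["b"][:, None]
        return y.reshape(self.cout, *x.shape[1:])

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy.reshape(self.cout, -1)
        self.grads["W"] += (g @ self._cols.T).reshape(self.params["W"].shape)
        self.grads["b"] += g.sum(axis=1)
        # dx = conv(gy, W transposed over channels and flipped spatially)
        w_t = self.params["W"].transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        cols = _im2col(gy, self.k)
        gx = (w_t.reshape(self.cin, -1) @ cols).reshape(self.cin, *self._shape[1:])
        return gx


class BatchNorm3d(Layer):
    """Per-channel feature normalization with learned scale and shift.

    Statistics are taken over the spatial extent of the current sample
    (mini-batches are processed sample-by-sample); running estimates are kept
    for inference.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(c, dtype=np.float32), "beta": np.zeros(c, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        if self.training:
            mu = flat.mean(axis=1)
            var = flat.var(axis=1)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (flat - mu[:, None]) / self._std[:, None]
        y = self.params["gamma"][:, None] * self._xhat + self.params["beta"][:, None]
        return y.reshape(x.shape)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c = gy.shape[0]
        g = gy.reshape(c, -1)
        n = g.shape[1]
        self.grads["gamma"] += (g * self._xhat).sum(axis=1)
        self.grads["beta"] += g.sum(axis=1)
        if not self.training:
            gx = g * (self.params["gamma"] / self._std)[:, None]
            return gx.reshape(gy.shape)
        gxhat = g * self.params["gamma"][:, None]
        gx = (
            gxhat
            - gxhat.mean(axis=1, keepdims=True)
            - self._xhat * (gxhat * self._xhat).mean(axis=1, keepdims=True)
        ) / self._std[:, None]
        return gx.reshape(gy.shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool3d(Layer):
    """2x2x2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, X, Y, Z = x.shape
        if X % 2 or Y % 2 or Z % 2:
            raise ValueError(f"spatial shape {(X, Y, Z)} not divisible by 2 for pooling")
        blocks = x.reshape(c, X // 2, 2, Y // 2, 2, Z // 2, 2)
        blocks = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, X // 2, Y // 2, Z // 2, 8)
        self._argmax = blocks.argmax(axis=-1)
        self._inshape = x.shape
        return blocks.max(axis=-1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c, X2, Y2, Z2 = gy.shape
        out = np.zeros((c, X2, Y2, Z2, 8), dtype=gy.dtype)
        np.put_along_axis(out, self._argmax[..., None], gy[..., None], axis=-1)
        out = out.reshape(c, X2, Y2, Z2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        return out.reshape(self._inshape)


class Upsample3d(Layer):
    """Nearest-neighbour x2 upsampling; backward sum-pools."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c, X, Y, Z = gy.shape
        return (
            gy.reshape(c, X // 2, 2, Y // 2, 2, Z // 2, 2).sum(axis=(2, 4, 6))
        )


class MultiHeadAttention3d(Layer):
    """Multi-head attention fusing two volumetric feature blocks.

    Every spatial position is one token.  Queries come from the structure
    features, keys and values from the CT features; per head,
    ``scores = softmax(Q K^T / sqrt(head_dim))`` (the scaling is optional),
    the attended values are concatenated over heads and projected back to the
    structure channel width.
    """

    def __init__(
        self,
        c_struct: int,
        c_ct: int,
        n_heads: int = 8,
        head_dim: int = 64,
        scale: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.h, self.d, self.scale = n_heads, head_dim, scale
        e = n_heads * head_dim
        self.embed_dim = e

        def lin(rows: int, cols: int) -> np.ndarray:
            return rng.normal(0.0, np.sqrt(2.0 / cols), size=(rows, cols)).astype(np.float32)

        self.params = {
            "Wq": lin(e, c_struct),
            "Wk": lin(e, c_ct),
            "Wv": lin(e, c_ct),
            "Wo": lin(c_struct, e),
            "bo": np.zeros(c_struct, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, xs: np.ndarray, xc: np.ndarray) -> np.ndarray:
        if xs.shape[1:] != xc.shape[1:]:
            raise ValueError("structure and CT feature blocks must share spatial shape")
        self._spatial = xs.shape[1:]
        cs, cc = xs.shape[0], xc.shape[0]
        n = int(np.prod(self._spatial))
        s = xs.reshape(cs, n)
        c = xc.reshape(cc, n)
        self._s, self._c = s, c
        h, d = self.h, self.d
        q = (self.params["Wq"] @ s).reshape(h, d, n)
        k = (self.params["Wk"] @ c).reshape(h, d, n)
        v = (self.params["Wv"] @ c).reshape(h, d, n)
        self._q, self._k, self._v = q, k, v
        alpha = 1.0 / np.sqrt(d) if self.scale else 1.0
        logits = alpha * np.einsum("hdn,hdm->hnm", q, k)
        logits -= logits.max(axis=2, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=2, keepdims=True)
        self._p, self._alpha = p, alpha
        att = np.einsum("hnm,hdm->hdn", p, v).reshape(h * d, n)
        self._att = att
        y = self.params["Wo"] @ att + self.params["bo"][:, None]
        return y.reshape(cs, *self._spatial)

    def attention_weights(self) -> np.ndarray:
        """Row-stochastic attention matrices of the last forward, (h, n, n)."""
        return self._p

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cs = gy.shape[0]
        n = int(np.prod(self._spatial))
        g = gy.reshape(cs, n)
        self.grads["Wo"] += g @ self._att.T
        self.grads["bo"] += g.sum(axis=1)
        gatt = (self.params["Wo"].T @ g).reshape(self.h, self.d, n)
        p, q, k, v = self._p, self._q, self._k, self._v
        gp = np.einsum("hdn,hdm->hnm", gatt, v)
        gv = np.einsum("hnm,hdn->hdm", p, gatt)
        # softmax backward per row
        glogits = p * (gp - (gp * p).sum(axis=2, keepdims=True))
        gq = self._alpha * np.einsum("hnm,hdm->hdn", glogits, k)
        gk = self._alpha * np.einsum("hnm,hdn->hdm", glogits, q)
        e = self.h * self.d
        gq, gk, gv = (a.reshape(e, n) for a in (gq, gk, gv))
        self.grads["Wq"] += gq @ self._s.T
        self.grads["Wk"] += gk @ self._c.T
        self.grads["Wv"] += gv @ self._c.T
        gs = self.params["Wq"].T @ gq
        gc = self.params["Wk"].T @ gk + self.params["Wv"].T @ gv
        return gs.reshape(-1, *self._spatial), gc.reshape(-1, *self._spatial)
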