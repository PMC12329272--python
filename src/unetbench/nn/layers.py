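"""Minimal NCHW neural-network layers with manual backpropagation.

Everything runs in float32 numpy. Convolutions use im2col so the inner loop
is a BLAS matmul; the transposed convolution exploits stride == kernel (no
output overlap), which reduces it to an einsum. Each layer caches what its
backward pass needs, accumulates parameter gradients in ``grads`` and returns
the gradient with respect to its input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base: parameter/grad dicts plus optional non-trainable buffers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0

    def param_count(self) -> int:
        return sum(p.size for p in self.params.values()) + sum(
            b.size for b in self.buffers.values()
        )


class Conv2D(Layer):
    """Same-padding, stride-1 square convolution."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("same-padding convolution needs an odd kernel")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.params["w"] = he_uniform(rng, (c_out, c_in, kernel, kernel), c_in * kernel * kernel)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n,c,h,w,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h * w, c * k * k)
        out = cols @ self.params["w"].reshape(self.c_out, -1).T
        out += self.params["b"]
        if train:
            self._cols, self._shape = cols, x.shape
        return np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(n, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        k, p = self.k, self.k // 2
        dmat = dy.reshape(n, self.c_out, h * w).transpose(0, 2, 1)  # (n,hw,c_out)
        w_mat = self.params["w"].reshape(self.c_out, -1)
        self.grads["w"] += np.einsum("nqo,nqi->oi", dmat, self._cols).reshape(self.params["w"].shape)
        self.grads["b"] += dmat.sum(axis=(0, 1))
        dcols = dmat @ w_mat  # (n,hw,c*k*k)
        dcols = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, i, j]
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ConvTranspose2D(Layer):
    """Learnable upsampler with stride equal to kernel size (no overlap)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.params["w"] = he_uniform(rng, (c_in, c_out, kernel, kernel), c_in * kernel * kernel)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.k
        out = np.einsum("ncij,cdab->ndiajb", x, self.params["w"], optimize=True)
        out = out.reshape(n, self.c_out, h * s, w * s)
        out += self.params["b"][:, None, None]
        if train:
            self._x = x
        return np.ascontiguousarray(out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        s = self.k
        dy6 = dy.reshape(n, self.c_out, h, s, w, s)
        self.grads["w"] += np.einsum("ncij,ndiajb->cdab", x, dy6, optimize=True)
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        self._x = None
        return np.einsum("ndiajb,cdab->ncij", dy6, self.params["w"], optimize=True)


class MaxPool2D(Layer):
    """2x2, stride-2 max pooling."""

    def __init__(self) -> None:
        super().__init__()
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("max-pool input must have even spatial size")
        xw = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xw = np.ascontiguousarray(xw).reshape(n, c, h // 2, w // 2, 4)
        idx = xw.argmax(axis=-1)
        out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxw = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(dxw, self._idx[..., None], dy[..., None], axis=-1)
        dx = dxw.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._idx = None
        return np.ascontiguousarray(dx).reshape(n, c, h, w)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics.

    Training normalizes by the current batch mean/variance; evaluation uses
    the running estimates. gamma/beta are trainable; the running mean and
    variance are buffers (they still count toward the parameter audit).
    """

    def __init__(self, channels: int, epsilon: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.epsilon, self.momentum = epsilon, momentum
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.buffers["running_mean"] = np.zeros(channels, dtype=DTYPE)
        self.buffers["running_var"] = np.ones(channels, dtype=DTYPE)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        g = self.params["gamma"][:, None, None]
        b = self.params["beta"][:, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.buffers["running_mean"] = ((1 - m) * self.buffers["running_mean"] + m * mean).astype(DTYPE)
            self.buffers["running_var"] = ((1 - m) * self.buffers["running_var"] + m * var).astype(DTYPE)
            inv_std = 1.0 / np.sqrt(var + self.epsilon)
            xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
            self._cache = (xhat, inv_std)
            return (g * xhat + b).astype(DTYPE)
        mean = self.buffers["running_mean"][:, None, None]
        var = self.buffers["running_var"][:, None, None]
        return (g * (x - mean) / np.sqrt(var + self.epsilon) + b).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n_eff = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][:, None, None]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3))[:, None, None]
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3))[:, None, None]
        ) * inv_std[:, None, None]
        self._cache = None
        return dx.astype(DTYPE)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def fold_batchnorm(
    gamma: np.ndarray,
    beta: np.ndarray,
    mean: np.ndarray,
    var: np.ndarray,
    epsilon: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Effective affine (scale, shift) of a frozen batch normalization.

    For a pre-activation ``z`` (the convolution output, bias included),
    ``BN(z) = scale * z + shift`` with ``scale = gamma / sqrt(var + eps)`` and
    ``shift = beta - scale * mean``.
    """
    scale = gamma / np.sqrt(var + epsilon)
    return scale, beta - scale * mean
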