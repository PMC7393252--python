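"""Norm, activation, pooling, linear and resampling layers."""

from __future__ import annotations

import numpy as np

from .core import Module, Parameter


class BatchNorm3d(Module):
    """Per-channel batch norm over (B, D, H, W); running stats for eval."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels), name="bn.gamma")
        self.beta = Parameter(np.zeros(channels), name="bn.beta")
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[1]
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // c
            self._buffers["running_mean"] *= 1.0 - self.momentum
            self._buffers["running_mean"] += self.momentum * mean
            # unbiased variance for the running estimate, as is conventional
            unbiased = var * (n / max(n - 1, 1))
            self._buffers["running_var"] *= 1.0 - self.momentum
            self._buffers["running_var"] += self.momentum * unbiased
        else:
            mean = self._buffers["running_mean"]
            var = self._buffers["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        shape = (1, c, 1, 1, 1)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        out = self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)
        self._cache = (xhat, inv_std)
        return out.astype(np.float32, copy=False)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        c = gy.shape[1]
        axes = (0, 2, 3, 4)
        shape = (1, c, 1, 1, 1)
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = self.gamma.data.reshape(shape)
        if self.training:
            n = gy.size // c
            gxhat = gy * g
            gx = (
                gxhat
                - gxhat.mean(axis=axes).reshape(shape)
                - xhat * (gxhat * xhat).mean(axis=axes).reshape(shape)
            ) * inv_std.reshape(shape)
        else:
            gx = gy * g * inv_std.reshape(shape)
        self._cache = None
        return gx.astype(np.float32, copy=False)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, gy):
        gx = np.where(self._mask, gy, 0.0).astype(np.float32, copy=False)
        self._mask = None
        return gx


class Sigmoid(Module):
    def __init__(self):
        super().__init__()
        self._y = None

    def forward(self, x):
        e = np.exp(-np.abs(x))
        y = np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
        self._y = y
        return y

    def backward(self, gy):
        gx = gy * self._y * (1.0 - self._y)
        self._y = None
        return gx


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        self.weight = Parameter(w, name="linear.weight")
        self.bias = Parameter(np.zeros(out_features), name="linear.bias")
        self._x = None

    def forward(self, x):
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, gy):
        self.weight.grad += gy.T @ self._x
        self.bias.grad += gy.sum(axis=0)
        gx = gy @ self.weight.data
        self._x = None
        return gx


class GlobalAvgPool3d(Module):
    """(B, C, D, H, W) -> (B, C)."""

    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, gy):
        b, c, d, h, w = self._shape
        gx = np.broadcast_to(gy.reshape(b, c, 1, 1, 1), self._shape) / (d * h * w)
        return np.ascontiguousarray(gx, dtype=np.float32)


class AvgPool3d(Module):
    """Non-overlapping mean pooling; spatial dims must divide the factors."""

    def __init__(self, factor=(1, 2, 2)):
        super().__init__()
        self.factor = tuple(int(f) for f in factor)
        self._shape = None

    def forward(self, x):
        b, c, d, h, w = x.shape
        fd, fh, fw = self.factor
        if d % fd or h % fh or w % fw:
            raise ValueError(f"spatial dims {(d, h, w)} not divisible by pool factor {self.factor}")
        self._shape = x.shape
        y = x.reshape(b, c, d // fd, fd, h // fh, fh, w // fw, fw).mean(axis=(3, 5, 7))
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, gy):
        b, c, d, h, w = self._shape
        fd, fh, fw = self.factor
        scale = 1.0 / (fd * fh * fw)
        g = gy.reshape(b, c, d // fd, 1, h // fh, 1, w // fw, 1) * scale
        gx = np.broadcast_to(g, (b, c, d // fd, fd, h // fh, fh, w // fw, fw))
        return np.ascontiguousarray(gx.reshape(self._shape), dtype=np.float32)


def _interp_matrix(n_in: int, factor: int) -> np.ndarray:
    """1D linear-interpolation matrix (n_in*factor, n_in), half-pixel centers."""
    n_out = n_in * factor
    m = np.zeros((n_out, n_in), dtype=np.float32)
    for o in range(n_out):
        src = (o + 0.5) / factor - 0.5
        i0 = int(np.floor(src))
        w1 = src - i0
        i0c = min(max(i0, 0), n_in - 1)
        i1c = min(max(i0 + 1, 0), n_in - 1)
        m[o, i0c] += 1.0 - w1
        m[o, i1c] += w1
    return m


class Upsample3d(Module):
    """Trilinear upsampling by integer factors (depth factor may be 1)."""

    def __init__(self, factor=(1, 2, 2)):
        super().__init__()
        self.factor = tuple(int(f) for f in factor)
        self._mats: dict[tuple[int, int], np.ndarray] = {}
        self._in_shape = None

    def _mat(self, n_in: int, factor: int) -> np.ndarray:
        key = (n_in, factor)
        if key not in self._mats:
            self._mats[key] = _interp_matrix(n_in, factor)
        return self._mats[key]

    @staticmethod
    def _apply_axis(x: np.ndarray, m: np.ndarray, axis: int) -> np.ndarray:
        moved = np.moveaxis(x, axis, -1)
        out = moved @ m.T
        return np.ascontiguousarray(np.moveaxis(out, -1, axis), dtype=np.float32)

    def forward(self, x):
        self._in_shape = x.shape
        fd, fh, fw = self.factor
        y = x
        if fd > 1:
            y = self._apply_axis(y, self._mat(x.shape[2], fd), 2)
        if fh > 1:
            y = self._apply_axis(y, self._mat(x.shape[3], fh), 3)
        if fw > 1:
            y = self._apply_axis(y, self._mat(x.shape[4], fw), 4)
        return y

    def backward(self, gy):
        fd, fh, fw = self.factor
        g = gy
        if fw > 1:
            g = self._apply_axis(g, self._mat(self._in_shape[4], fw).T, 4)
        if fh > 1:
            g = self._apply_axis(g, self._mat(self._in_shape[3], fh).T, 3)
        if fd > 1:
            g = self._apply_axis(g, self._mat(self._in_shape[2], fd).T, 2)
        return g
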