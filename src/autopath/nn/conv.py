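"""3D convolution via im2col + GEMM, with stride and dilation."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, Parameter


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError(f"expected 3 values, got {v!r}")
        return tuple(int(x) for x in v)
    return (int(v),) * 3


class Conv3d(Module):
    """Convolution over (B, C, D, H, W) with 'same'-style symmetric padding.

    Padding defaults to ((k-1)*dilation)//2 per axis, so with odd kernels the
    output spatial size is ceil(in / stride).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size=3,
        stride=1,
        dilation=1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = _triple(kernel_size)
        self.stride = _triple(stride)
        self.dilation = _triple(dilation)
        self.pad = tuple(((k - 1) * d) // 2 for k, d in zip(self.kernel, self.dilation))
        rng = rng if rng is not None else np.random.default_rng()
        fan_in = in_channels * int(np.prod(self.kernel))
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels) + self.kernel)
        self.weight = Parameter(w, name="conv.weight")
        self.has_bias = bias
        if bias:
            self.bias = Parameter(np.zeros(out_channels), name="conv.bias")
        self._cache = None

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        kd, kh, kw = self.kernel
        sd, sh, sw = self.stride
        dd, dh, dw = self.dilation
        pd, ph, pw = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        span = ((kd - 1) * dd + 1, (kh - 1) * dh + 1, (kw - 1) * dw + 1)
        win = sliding_window_view(xp, span, axis=(2, 3, 4))
        # dilate within the window, then stride across window positions
        win = win[:, :, ::sd, ::sh, ::sw, ::dd, ::dh, ::dw]
        b, c, do, ho, wo = win.shape[:5]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        cols = cols.reshape(b * do * ho * wo, c * kd * kh * kw)
        return cols, (b, do, ho, wo, xp.shape)

    def out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        out = []
        for n, k, s, d, p in zip(spatial, self.kernel, self.stride, self.dilation, self.pad):
            span = (k - 1) * d + 1
            out.append((n + 2 * p - span) // s + 1)
        return tuple(out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        cols, (b, do, ho, wo, xp_shape) = self._im2col(x)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        out = cols @ wmat.T
        if self.has_bias:
            out += self.bias.data
        out = out.reshape(b, do, ho, wo, self.out_channels).transpose(0, 4, 1, 2, 3)
        self._cache = (cols, (b, do, ho, wo), xp_shape, x.shape)
        return np.ascontiguousarray(out)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, (b, do, ho, wo), xp_shape, x_shape = self._cache
        kd, kh, kw = self.kernel
        sd, sh, sw = self.stride
        dd, dh, dw = self.dilation
        pd, ph, pw = self.pad
        gmat = np.ascontiguousarray(gy.transpose(0, 2, 3, 4, 1)).reshape(-1, self.out_channels)
        wmat = self.weight.data.reshape(self.out_channels, -1)
        self.weight.grad += (gmat.T @ cols).reshape(self.weight.data.shape)
        if self.has_bias:
            self.bias.grad += gmat.sum(axis=0)
        gcols = gmat @ wmat  # (B*Do*Ho*Wo, C*kd*kh*kw)
        g6 = gcols.reshape(b, do, ho, wo, self.in_channels, kd, kh, kw)
        g6 = g6.transpose(0, 4, 1, 2, 3, 5, 6, 7)
        gxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    gxp[
                        :,
                        :,
                        i * dd : i * dd + (do - 1) * sd + 1 : sd,
                        j * dh : j * dh + (ho - 1) * sh + 1 : sh,
                        k * dw : k * dw + (wo - 1) * sw + 1 : sw,
                    ] += g6[:, :, :, :, :, i, j, k]
        d, h, w = x_shape[2:]
        gx = gxp[:, :, pd : pd + d, ph : ph + h, pw : pw + w]
        self._cache = None
        return np.ascontiguousarray(gx)

    def macs(self, in_spatial: tuple[int, int, int]) -> int:
        """Analytic multiply-accumulate count for one sample."""
        do, ho, wo = self.out_shape(in_spatial)
        return (
            do * ho * wo * self.out_channels * self.in_channels * int(np.prod(self.kernel))
        )
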