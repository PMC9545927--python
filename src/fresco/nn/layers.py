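"""Layers with explicit forward/backward passes."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _conv3d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Correlation of (C,T,H,W) with (Cout,Cin,kt,kh,kw), zero-padded same."""
    kt, kh, kw = w.shape[2:]
    xp = np.pad(
        x,
        ((0, 0), (kt // 2, kt // 2), (kh // 2, kh // 2), (kw // 2, kw // 2)),
    )
    win = sliding_window_view(xp, (kt, kh, kw), axis=(1, 2, 3))
    return np.tensordot(w, win, axes=([1, 2, 3, 4], [0, 4, 5, 6]))


class Conv3d(Layer):
    """3D convolution, stride 1, odd kernel, zero-padded to 'same'."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: tuple[int, int, int] = (3, 3, 3),
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        kt, kh, kw = kernel
        assert kt % 2 == 1 and kh % 2 == 1 and kw % 2 == 1
        fan_in = in_ch * kt * kh * kw
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.w = Param((rng.normal(size=(out_ch, in_ch, kt, kh, kw)) * scale).astype(dtype))
        self.b = Param(np.zeros(out_ch, dtype=dtype))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        return _conv3d_same(x, self.w.data) + self.b.data[:, None, None, None]

    def backward(self, g):
        x = self._x
        kt, kh, kw = self.w.data.shape[2:]
        xp = np.pad(
            x, ((0, 0), (kt // 2, kt // 2), (kh // 2, kh // 2), (kw // 2, kw // 2))
        )
        win = sliding_window_view(xp, (kt, kh, kw), axis=(1, 2, 3))
        self.w.grad += np.tensordot(g, win, axes=([1, 2, 3], [1, 2, 3]))
        self.b.grad += g.sum(axis=(1, 2, 3))
        # input gradient: correlate the output grad with the flipped,
        # transposed kernel (same padding works because kernels are odd)
        w_t = self.w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        return _conv3d_same(g, w_t)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class AvgPool3d(Layer):
    """Average pooling by integer factors (ft, fh, fw)."""

    def __init__(self, factor: tuple[int, int, int] = (2, 2, 2)):
        self.f = factor

    def forward(self, x):
        C, T, H, W = x.shape
        ft, fh, fw = self.f
        if T % ft or H % fh or W % fw:
            raise ValueError(f"shape {x.shape} not divisible by pool factor {self.f}")
        self._shape = x.shape
        return x.reshape(C, T // ft, ft, H // fh, fh, W // fw, fw).mean(axis=(2, 4, 6))

    def backward(self, g):
        ft, fh, fw = self.f
        scale = 1.0 / (ft * fh * fw)
        g = np.repeat(np.repeat(np.repeat(g, ft, axis=1), fh, axis=2), fw, axis=3)
        return (g * scale).astype(g.dtype)


class Upsample3d(Layer):
    """Nearest-neighbour upsampling by integer factors."""

    def __init__(self, factor: tuple[int, int, int] = (2, 2, 2)):
        self.f = factor

    def forward(self, x):
        ft, fh, fw = self.f
        return np.repeat(np.repeat(np.repeat(x, ft, axis=1), fh, axis=2), fw, axis=3)

    def backward(self, g):
        C, T, H, W = g.shape
        ft, fh, fw = self.f
        return (
            g.reshape(C, T // ft, ft, H // fh, fh, W // fw, fw).sum(axis=(2, 4, 6))
        )
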