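"""2D+time U-Net built from the explicit-backward layers."""

from __future__ import annotations

import numpy as np

from .layers import AvgPool3d, Conv3d, Layer, ReLU, Upsample3d


class _ConvStack(Layer):
    def __init__(self, in_ch, out_ch, n_blocks, rng, dtype):
        self.layers = []
        c = in_ch
        for _ in range(n_blocks):
            self.layers += [Conv3d(c, out_ch, rng=rng, dtype=dtype), ReLU()]
            c = out_ch

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class UNet3D(Layer):
    """Encoder-decoder over (C, T, H, W) blocks with skip connections.

    Each scale halves (t, y, x) by average pooling and doubles the
    filter count; decoding upsamples (nearest neighbour), concatenates
    the skip and convolves.  The head is a linear 1x1x1 convolution.
    """

    def __init__(
        self,
        n_scales: int = 2,
        init_filters: int = 8,
        blocks_per_scale: int = 2,
        in_channels: int = 2,
        out_channels: int = 2,
        seed: int = 0,
        dtype=np.float32,
    ):
        if n_scales < 1 or init_filters < 4:
            raise ValueError("need n_scales >= 1 and init_filters >= 4")
        rng = np.random.default_rng(seed)
        self.n_scales = n_scales
        f = [init_filters * 2**s for s in range(n_scales)]
        self.enc = []
        c = in_channels
        for s in range(n_scales):
            self.enc.append(_ConvStack(c, f[s], blocks_per_scale, rng, dtype))
            c = f[s]
        self.pools = [AvgPool3d((2, 2, 2)) for _ in range(n_scales - 1)]
        self.ups = [Upsample3d((2, 2, 2)) for _ in range(n_scales - 1)]
        self.dec = []
        for s in range(n_scales - 2, -1, -1):
            self.dec.append(_ConvStack(f[s + 1] + f[s], f[s], blocks_per_scale, rng, dtype))
        self.head = Conv3d(f[0], out_channels, kernel=(1, 1, 1), rng=rng, dtype=dtype)

    def params(self):
        ps = []
        for l in self.enc + self.dec + [self.head]:
            ps += l.params()
        return ps

    @property
    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def _check(self, x):
        _, T, H, W = x.shape
        d = 2 ** (self.n_scales - 1)
        if T % d or H % d or W % d:
            raise ValueError(
                f"input (t={T}, y={H}, x={W}) not divisible by 2^(n_scales-1)={d}"
            )

    def forward(self, x):
        self._check(x)
        skips = []
        for s in range(self.n_scales - 1):
            x = self.enc[s].forward(x)
            skips.append(x)
            x = self.pools[s].forward(x)
        x = self.enc[-1].forward(x)
        self._split = []
        for i, s in enumerate(range(self.n_scales - 2, -1, -1)):
            x = self.ups[i].forward(x)
            skip = skips[s]
            self._split.append(x.shape[0])
            x = np.concatenate([x, skip], axis=0)
            x = self.dec[i].forward(x)
        return self.head.forward(x)

    def backward(self, g):
        g = self.head.backward(g)
        skip_grads = {}
        for i in range(len(self.dec) - 1, -1, -1):
            s = self.n_scales - 2 - i
            g = self.dec[i].backward(g)
            n_up = self._split[i]
            g_up, g_skip = g[:n_up], g[n_up:]
            skip_grads[s] = g_skip
            g = self.ups[i].backward(g_up)
        g = self.enc[-1].backward(g)
        for s in range(self.n_scales - 2, -1, -1):
            g = self.pools[s].backward(g)
            g = g + skip_grads[s]
            g = self.enc[s].backward(g)
        return g

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_state_dict(self, state: list[np.ndarray]):
        ps = self.params()
        if len(ps) != len(state):
            raise ValueError("state length mismatch")
        for p, s in zip(ps, state):
            if p.data.shape != s.shape:
                raise ValueError("state shape mismatch")
            p.data = s.astype(p.data.dtype).copy()
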