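"""Gridding nonuniform FFT (type 1/2) on a Cartesian image grid.

Conventions
-----------
* Image pixel ``(y, x)`` sits at position ``(y - H/2, x - W/2)`` in voxel
  units; DC is therefore at the grid centre after an ``fftshift``.
* Nonuniform frequencies are given per axis in *normalized* units
  ``kappa = k_cycles_per_mm * voxel_mm``, valid on ``[-0.5, 0.5]``.
* The transforms are unnormalized:

  - type 2 (forward):  ``s_j = sum_p f[p] exp(-2i pi kappa_j . p)``
  - type 1 (adjoint):  ``f[p] = sum_j s_j exp(+2i pi kappa_j . p)``

  so a constant image ``c`` yields ``c * H * W`` at DC, and the pair is an
  exact numerical adjoint (the spreader is the transpose of the
  interpolator by construction).

The interpolation kernel is the exponential-of-semicircle kernel
``phi(z) = exp(beta (sqrt(1 - (2 z / w)^2) - 1))`` with ``beta = 2.30 w``
at 2x oversampling, which reaches ~1e-7 relative accuracy at width 8.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss

__all__ = ["NufftPlan", "nufft2", "nufft1"]

_DEF_WIDTH = 8
_DEF_OVERSAMP = 2.0


def _es_kernel(z: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Exponential-of-semicircle kernel, compactly supported on |z| <= w/2."""
    arg = 1.0 - (2.0 * z / width) ** 2
    out = np.zeros_like(z, dtype=float)
    inside = arg > 0
    out[inside] = np.exp(beta * (np.sqrt(arg[inside]) - 1.0))
    return out


def _kernel_ft(nu: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Continuous Fourier transform of the kernel at frequencies ``nu``.

    Computed by Gauss-Legendre quadrature; the kernel is smooth on its
    support so 96 nodes are far beyond machine precision.
    """
    nodes, wts = leggauss(96)
    z = 0.5 * width * nodes  # map [-1,1] -> [-w/2, w/2]
    phi = _es_kernel(z, width, beta)
    # psi_hat(nu) = int phi(z) exp(2i pi nu z) dz ; real and even
    return 0.5 * width * (phi * wts) @ np.cos(2.0 * np.pi * np.outer(z, np.atleast_1d(nu)))


class NufftPlan:
    """Precomputed gridding plan for a fixed image shape and sample set."""

    def __init__(
        self,
        kappa: np.ndarray,
        shape: tuple[int, int],
        width: int = _DEF_WIDTH,
        oversamp: float = _DEF_OVERSAMP,
    ):
        kappa = np.asarray(kappa, dtype=float)
        if kappa.ndim != 2 or kappa.shape[1] != 2:
            raise ValueError("kappa must be (n, 2) [ky, kx] in cycles/sample")
        if np.any(~np.isfinite(kappa)):
            raise ValueError("non-finite sample coordinates")
        if np.any(np.abs(kappa) > 0.5 + 1e-12):
            raise ValueError(
                "sample coordinates beyond +-0.5 cycles/sample (out of band)"
            )
        H, W = shape
        self.shape = (H, W)
        self.width = int(width)
        self.beta = 2.30 * self.width * (oversamp / 2.0) ** 0  # tuned for 2x
        self.Hg = int(round(H * oversamp / 2.0)) * 2
        self.Wg = int(round(W * oversamp / 2.0)) * 2
        self.n = kappa.shape[0]

        offs = np.arange(self.width)
        self._tabs = []
        for ax, Ng in ((0, self.Hg), (1, self.Wg)):
            c = kappa[:, ax] * Ng  # continuous grid coordinate of each sample
            m0 = np.ceil(c - self.width / 2.0).astype(int)
            m = m0[:, None] + offs[None, :]  # (n, w) integer grid lines
            vals = _es_kernel(c[:, None] - m, self.width, self.beta)
            # frequency line m lives at index (m + Ng/2) mod Ng of the
            # fftshift-centred spectrum (periodic in m with period Ng)
            self._tabs.append((np.mod(m + Ng // 2, Ng), vals))

        # separable deapodization on the (unpadded) image grid
        dy = _kernel_ft((np.arange(H) - H // 2) / self.Hg, self.width, self.beta)
        dx = _kernel_ft((np.arange(W) - W // 2) / self.Wg, self.width, self.beta)
        self._deapod = 1.0 / np.outer(dy, dx)

        My, ky = self._tabs[0]
        Mx, kx = self._tabs[1]
        self._flat_idx = (My[:, :, None] * self.Wg + Mx[:, None, :]).reshape(self.n, -1)
        self._sep_vals = (ky[:, :, None] * kx[:, None, :]).reshape(self.n, -1)

    # -- type 2: image -> nonuniform samples ------------------------------
    def forward(self, image: np.ndarray) -> np.ndarray:
        H, W = self.shape
        if image.shape != (H, W):
            raise ValueError(f"image shape {image.shape} != plan shape {self.shape}")
        work = np.zeros((self.Hg, self.Wg), dtype=complex)
        y0 = self.Hg // 2 - H // 2
        x0 = self.Wg // 2 - W // 2
        work[y0 : y0 + H, x0 : x0 + W] = image * self._deapod
        spec = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(work)))
        return (spec.ravel()[self._flat_idx] * self._sep_vals).sum(axis=1)

    # -- type 1: nonuniform samples -> image (exact adjoint of forward) ---
    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        samples = np.asarray(samples)
        if samples.shape != (self.n,):
            raise ValueError("sample vector length mismatch")
        grid = np.zeros(self.Hg * self.Wg, dtype=complex)
        contrib = samples[:, None] * self._sep_vals
        np.add.at(grid.real, self._flat_idx, contrib.real)
        np.add.at(grid.imag, self._flat_idx, contrib.imag)
        grid = grid.reshape(self.Hg, self.Wg)
        img = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(grid))) * (self.Hg * self.Wg)
        H, W = self.shape
        y0 = self.Hg // 2 - H // 2
        x0 = self.Wg // 2 - W // 2
        return img[y0 : y0 + H, x0 : x0 + W] * self._deapod

    # -- kernel-domain spread/interp used by Pipe-Menon density estimation
    def spread_interp(self, weights: np.ndarray) -> np.ndarray:
        """Return (P^T P) w: spread weights to the grid, read them back."""
        grid = np.zeros(self.Hg * self.Wg)
        np.add.at(grid, self._flat_idx, weights[:, None] * self._sep_vals)
        return (grid[self._flat_idx] * self._sep_vals).sum(axis=1)


def nufft2(image: np.ndarray, kappa: np.ndarray, **kw) -> np.ndarray:
    """One-shot type-2 NUFFT (image to nonuniform samples)."""
    return NufftPlan(kappa, image.shape, **kw).forward(image)


def nufft1(samples: np.ndarray, kappa: np.ndarray, shape: tuple[int, int], **kw) -> np.ndarray:
    """One-shot type-1 (adjoint) NUFFT (nonuniform samples to image)."""
    return NufftPlan(kappa, shape, **kw).adjoint(samples)
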