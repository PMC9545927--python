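"""Structural similarity (Wang et al. windowed form) with exact gradient.

SSIM per 2D frame uses Gaussian windows (11x11, sigma 1.5 by default),
population statistics and stabilization constants K1=0.01, K2=0.03; the
map is cropped by the window radius before averaging, so boundary
handling does not enter the value.  The gradient with respect to the
first argument is derived analytically through the three filtered
moments (mu_x, E[x^2], E[xy]); Gaussian smoothing with zero padding is
self-adjoint, which keeps the adjoint pass a plain re-smoothing.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate1d

__all__ = ["ssim", "ssim_pair_loss"]


def _gauss_kernel(sigma: float, truncate: float) -> np.ndarray:
    r = int(truncate * sigma + 0.5)
    t = np.arange(-r, r + 1)
    k = np.exp(-0.5 * (t / sigma) ** 2)
    return k / k.sum()


def _smooth(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    out = correlate1d(x, k, axis=-1, mode="constant")
    return correlate1d(out, k, axis=-2, mode="constant")


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    data_range: float = 1.0,
    sigma: float = 1.5,
    truncate: float = 3.5,
    grad: bool = False,
):
    """Mean SSIM between images (leading axes are averaged over).

    Returns the scalar mean SSIM, or ``(value, d value / d x)`` when
    ``grad`` is requested.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    k = _gauss_kernel(sigma, truncate)
    r = (len(k) - 1) // 2
    if x.shape[-1] < 2 * r + 1 or x.shape[-2] < 2 * r + 1:
        raise ValueError("image smaller than the SSIM window")
    C1 = (0.01 * data_range) ** 2
    C2 = (0.03 * data_range) ** 2

    mu_x = _smooth(x, k)
    mu_y = _smooth(y, k)
    mxx = _smooth(x * x, k)
    myy = _smooth(y * y, k)
    mxy = _smooth(x * y, k)
    vx = mxx - mu_x**2
    vy = myy - mu_y**2
    cov = mxy - mu_x * mu_y

    A1 = 2.0 * mu_x * mu_y + C1
    A2 = 2.0 * cov + C2
    B1 = mu_x**2 + mu_y**2 + C1
    B2 = vx + vy + C2
    S = (A1 * A2) / (B1 * B2)

    crop = (slice(None),) * (x.ndim - 2) + (slice(r, -r), slice(r, -r))
    value = float(S[crop].mean())
    if not grad:
        return value

    w = np.zeros_like(S)
    w[crop] = 1.0 / S[crop].size
    dS_dmu = w * (
        2.0 * mu_y * (A2 - A1) / (B1 * B2) + 2.0 * mu_x * S * (1.0 / B2 - 1.0 / B1)
    )
    dS_dmxx = w * (-S / B2)
    dS_dmxy = w * (2.0 * A1 / (B1 * B2))
    gx = _smooth(dS_dmu, k) + 2.0 * x * _smooth(dS_dmxx, k) + y * _smooth(dS_dmxy, k)
    return value, gx


def ssim_pair_loss(
    pred: np.ndarray,
    truth: np.ndarray,
    grad: bool = False,
    sigma: float = 1.5,
    truncate: float = 3.5,
):
    """Complex-pair SSIM loss on two-channel (real, imag) blocks.

    Inputs are ``(2, T, H, W)`` arrays with channel values in [-1, 1];
    each channel is mapped to [0, 1] via ``(x + 1) / 2`` and compared
    frame-wise with SSIM, and the loss is
    ``L = 1 - (SSIM_real + SSIM_imag) / 2``, in [0, 2], zero only at
    channel-wise perfect similarity.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.shape[0] != 2:
        raise ValueError("expected matching (2, T, H, W) blocks")
    vals = []
    grads = []
    for c in range(2):
        out = ssim(
            (pred[c] + 1.0) / 2.0,
            (truth[c] + 1.0) / 2.0,
            data_range=1.0,
            sigma=sigma,
            truncate=truncate,
            grad=grad,
        )
        if grad:
            v, g = out
            grads.append(g * 0.5)  # chain through (x+1)/2
        else:
            v = out
        vals.append(v)
    loss = 1.0 - 0.5 * (vals[0] + vals[1])
    if not grad:
        return loss
    gx = np.stack([-0.5 * g for g in grads])
    return loss, gx
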