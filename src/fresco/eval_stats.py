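"""Imaging, segmentation, and method-agreement metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .nn.ssim import ssim as _ssim

__all__ = ["AgreementReport", "image_metrics", "seg_metrics", "bland_altman"]

_EPS = 1e-7
_PSNR_CAP_DB = 100.0


@dataclass
class AgreementReport:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    p_paired_t: float
    n: int


def image_metrics(truth: np.ndarray, pred: np.ndarray) -> dict:
    """MAE, PSNR and mean SSIM between normalized magnitude images.

    Inputs are magnitude images (frames or single images) scaled to
    [0, 1]; PSNR uses that unit data range and is capped at 100 dB.
    """
    t = np.asarray(truth, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape:
        raise ValueError("shape mismatch")
    mae = float(np.abs(t - p).mean())
    mse = float(((t - p) ** 2).mean())
    psnr = _PSNR_CAP_DB if mse == 0 else min(_PSNR_CAP_DB, 10.0 * np.log10(1.0 / mse))
    return {"mae": mae, "psnr": float(psnr), "ssim": _ssim(p, t, data_range=1.0)}


def seg_metrics(truth_mask: np.ndarray, prob: np.ndarray, threshold: float = 0.5) -> dict:
    """Binary cross-entropy (clipped probabilities) and hard Dice at 0.5."""
    g = np.asarray(truth_mask, dtype=float)
    p = np.asarray(prob, dtype=float)
    if g.shape != p.shape:
        raise ValueError("shape mismatch")
    pc = np.clip(p, _EPS, 1 - _EPS)
    bce = float(-(g * np.log(pc) + (1 - g) * np.log(1 - pc)).mean())
    hard = p >= threshold
    inter = float(np.logical_and(hard, g > 0.5).sum())
    denom = float(hard.sum() + (g > 0.5).sum())
    dice = 1.0 if denom == 0 else 2.0 * inter / denom
    return {"bce": bce, "dice": dice}


def bland_altman(a, b) -> AgreementReport:
    """Bland-Altman agreement between paired per-subject measurements.

    bias = mean(a - b); 95% limits of agreement = bias +- 1.96 sd of the
    differences (sample sd, ddof=1); p from a two-sided paired t test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need paired 1D samples")
    if len(a) < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.allclose(d, d[0]):
        p = 1.0 if np.isclose(d[0], 0.0) else 0.0
    else:
        p = float(stats.ttest_rel(a, b).pvalue)
    return AgreementReport(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        p_paired_t=p,
        n=len(a),
    )
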