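"""Automatic aortic segmentation over complex phase-contrast blocks.

The segmentation input is the combined phase-contrast block with its
magnitude CLAHE-equalized (contrast-limited adaptive histogram
equalization) and recombined with the subtracted phase, presented to the
U-Net as real/imaginary channels.  Training minimizes a configurable
loss (binary cross-entropy, soft Dice, or their sum — the default).
"""

from __future__ import annotations

import numpy as np
from skimage.exposure import equalize_adapthist
from skimage.measure import label as cc_label

from .nn import Adam, UNet3D
from .recon_net import UNetSpec, build_unet

__all__ = [
    "clahe_equalize",
    "clahe_complex_block",
    "seg_loss",
    "train_segmenter",
    "segment",
]

_EPS = 1e-7


def clahe_equalize(
    magnitude: np.ndarray, clip_limit: float = 0.02, tile_grid: tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Per-frame CLAHE on magnitude images normalized to [0, 1]."""
    mag = np.asarray(magnitude, dtype=float)
    if not np.all(np.isfinite(mag)):
        raise ValueError("non-finite magnitude input")
    if mag.min() < -1e-9 or mag.max() > 1 + 1e-9:
        raise ValueError("magnitude must be normalized to [0, 1]")
    single = mag.ndim == 2
    frames = mag[None] if single else mag
    H, W = frames.shape[-2:]
    kernel = (max(1, H // tile_grid[0]), max(1, W // tile_grid[1]))
    out = np.empty_like(frames)
    for i, f in enumerate(frames):
        if f.max() - f.min() < 1e-12:
            out[i] = f  # constant frame: equalization is a no-op
        else:
            out[i] = equalize_adapthist(
                np.clip(f, 0, 1), kernel_size=kernel, clip_limit=clip_limit
            )
    return out[0] if single else out


def clahe_complex_block(
    pc_block: np.ndarray, clip_limit: float = 0.02, tile_grid=(8, 8)
) -> np.ndarray:
    """CLAHE the magnitude of a complex block, keep the subtracted phase."""
    mag = np.abs(pc_block)
    top = mag.max()
    if top <= 0:
        return pc_block.copy()
    eq = clahe_equalize(mag / top, clip_limit, tile_grid)
    return eq * np.exp(1j * np.angle(pc_block))


def _bce(prob, g):
    p = np.clip(prob, _EPS, 1 - _EPS)
    return float(-(g * np.log(p) + (1 - g) * np.log(1 - p)).mean())


def _soft_dice(prob, g):
    eps = 1.0
    num = 2.0 * (prob * g).sum() + eps
    den = prob.sum() + g.sum() + eps
    return float(1.0 - num / den)


def seg_loss(name: str, truth_mask: np.ndarray, prob: np.ndarray) -> float:
    """Segmentation loss by name: 'bce', 'dice', or 'bce_dice'."""
    g = np.asarray(truth_mask, dtype=float)
    p = np.asarray(prob, dtype=float)
    if g.shape != p.shape:
        raise ValueError("shape mismatch")
    if name == "bce":
        return _bce(p, g)
    if name == "dice":
        return _soft_dice(p, g)
    if name == "bce_dice":
        return _bce(p, g) + _soft_dice(p, g)
    raise ValueError(f"unknown segmentation loss {name!r}")


def _loss_and_grad_logits(z: np.ndarray, g: np.ndarray, name: str):
    """Loss and gradient w.r.t. logits (numerically stable sigmoid form)."""
    p = 1.0 / (1.0 + np.exp(-z))
    loss = seg_loss(name, g, p)
    grad = np.zeros_like(z)
    if name in ("bce", "bce_dice"):
        grad += (p - g) / g.size
    if name in ("dice", "bce_dice"):
        eps = 1.0
        num = 2.0 * (p * g).sum() + eps
        den = p.sum() + g.sum() + eps
        d_dp = -(2.0 * g * den - num) / den**2
        grad += d_dp * p * (1.0 - p)
    return loss, grad, p


def train_segmenter(
    pairs,
    spec: UNetSpec | None = None,
    epochs: int = 5,
    seed: int = 0,
    loss: str = "bce_dice",
    val_pairs=None,
    clip_limit: float = 0.02,
):
    """Train the segmentation U-Net on (complex PC block, mask) pairs.

    ``pairs`` are :class:`~fresco.datagen.TrainingPair` whose ``truth``
    holds the combined phase-contrast block and ``masks`` the boolean
    labels.  CLAHE is applied to the magnitudes before the complex
    channels are formed.  Returns (model, history).
    """
    if len(pairs) < 1:
        raise ValueError("need at least one training pair")
    spec = spec or UNetSpec(n_scales=2, init_filters=8, blocks_per_scale=2, out_channels=1)
    if spec.out_channels != 1:
        raise ValueError("segmentation head must have one output channel")
    rng = np.random.default_rng(seed)
    model = build_unet(spec, seed=seed)
    opt = Adam(model.params(), lr=spec.lr)

    def prep(ps):
        data = []
        for p in ps:
            if p.masks is None:
                raise ValueError("segmentation pairs need masks")
            src = p.pc_truth if p.pc_truth is not None else p.truth
            x = clahe_complex_block(src, clip_limit)
            data.append(
                (
                    np.stack([x.real, x.imag]).astype(np.float32),
                    p.masks.astype(np.float64)[None],
                )
            )
        return data

    train_data = prep(pairs)
    val_data = prep(val_pairs) if val_pairs else None
    history = []
    for ep in range(epochs):
        losses = []
        for i in rng.permutation(len(train_data)):
            x, g = train_data[i]
            z = model.forward(x).astype(np.float64)
            l, gz, _ = _loss_and_grad_logits(z, g, loss)
            if not np.isfinite(l):
                raise FloatingPointError(f"non-finite loss at pair {i}")
            model.zero_grad()
            model.backward(gz.astype(np.float32))
            opt.step()
            losses.append(l)
        rec = {"epoch": ep, "train_loss": float(np.mean(losses))}
        if val_data:
            vs = []
            for x, g in val_data:
                z = model.forward(x).astype(np.float64)
                l, _, _ = _loss_and_grad_logits(z, g, loss)
                vs.append(l)
            rec["val_loss"] = float(np.mean(vs))
        history.append(rec)
    return model, history


def segment(
    model: UNet3D,
    pc_block: np.ndarray,
    threshold: float = 0.5,
    largest_component: bool = False,
    apply_clahe: bool = True,
    clip_limit: float = 0.02,
):
    """Probability map and thresholded mask for a complex PC block."""
    x = clahe_complex_block(pc_block, clip_limit) if apply_clahe else pc_block
    ch = np.stack([x.real, x.imag]).astype(np.float32)
    z = model.forward(ch).astype(np.float64)
    prob = 1.0 / (1.0 + np.exp(-z))[0]
    mask = prob >= threshold
    if largest_component:
        out = np.zeros_like(mask)
        for t in range(mask.shape[0]):
            lab = cc_label(mask[t])
            if lab.max() > 0:
                sizes = np.bincount(lab.ravel())[1:]
                out[t] = lab == (1 + int(np.argmax(sizes)))
        mask = out
    return prob, mask
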