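"""Deep artifact suppression: 2D+time U-Net with the complex SSIM loss.

The network maps aliased complex blocks (real/imaginary channels) to
artifact-free blocks, trained with
``L = 1 - [SSIM((re y + 1)/2, (re y_hat + 1)/2)
          + SSIM((im y + 1)/2, (im y_hat + 1)/2)] / 2``
where SSIM is averaged over 2D frames.  Blocks are normalized to
[-1, 1] by their 99th-percentile magnitude before entering the model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import Adam, UNet3D
from .nn.ssim import ssim_pair_loss

__all__ = [
    "UNetSpec",
    "build_unet",
    "ssim_pair_loss",
    "block_to_channels",
    "channels_to_block",
    "normalize_pair_block",
    "train_suppressor",
    "suppress",
    "successive_halving_search",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class UNetSpec:
    n_scales: int = 3
    init_filters: int = 16
    blocks_per_scale: int = 2
    lr: float = 1e-3
    in_channels: int = 2
    out_channels: int = 2
    #: predict a correction added to the input (identity at init); keeps
    #: the inter-encoding phase difference intact from the first step
    residual: bool = True

    def __post_init__(self):
        if self.n_scales < 1 or self.init_filters < 4:
            raise ValueError("need n_scales >= 1 and init_filters >= 4")


def build_unet(spec: UNetSpec, seed: int = 0) -> UNet3D:
    return UNet3D(
        n_scales=spec.n_scales,
        init_filters=spec.init_filters,
        blocks_per_scale=spec.blocks_per_scale,
        in_channels=spec.in_channels,
        out_channels=spec.out_channels,
        seed=seed,
    )


def block_to_channels(block: np.ndarray) -> np.ndarray:
    """Complex (T, H, W) -> float32 (2, T, H, W) [real, imag]."""
    return np.stack([block.real, block.imag]).astype(np.float32)


def channels_to_block(ch: np.ndarray) -> np.ndarray:
    return ch[0].astype(np.float64) + 1j * ch[1].astype(np.float64)


def normalize_pair_block(
    corrupted: np.ndarray,
    truth: np.ndarray | None = None,
    q: float = 99.0,
    level: float = 0.5,
):
    """Scale a block (and optionally its truth) by the corrupted member's
    99th-percentile magnitude, clipping channels to [-1, 1].

    The percentile is mapped to ``level`` (0.5), leaving headroom so the
    truth member — whose bright vessel is smeared (hence dimmed) in the
    aliased input — stays inside [-1, 1] without clipping.  Returns
    ``(corrupted_n, truth_n, scale)``; the scale inverts the mapping
    before flow quantification.
    """
    scale = float(np.percentile(np.abs(corrupted), q)) / level
    if scale <= 0:
        raise ValueError("all-zero block")
    cn = np.clip(block_to_channels(corrupted / scale), -1.0, 1.0)
    tn = None
    if truth is not None:
        tn = np.clip(block_to_channels(truth / scale), -1.0, 1.0)
    return cn, tn, scale


def _epoch(model, opt, pairs, rng, train: bool, residual: bool = False):
    losses = []
    order = rng.permutation(len(pairs)) if train else np.arange(len(pairs))
    for i in order:
        x, y = pairs[i]
        out = model.forward(x)
        if residual:
            out = x + out
        if train:
            loss, g = ssim_pair_loss(out, y, grad=True)
            model.zero_grad()
            model.backward(g.astype(np.float32))
            opt.step()
        else:
            loss = ssim_pair_loss(out, y)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss {loss} at pair {i}")
        losses.append(loss)
    return float(np.mean(losses))


def _prep(pairs):
    out = []
    for p in pairs:
        cn, tn, _ = normalize_pair_block(p.corrupted, p.truth)
        out.append((cn, tn))
    return out


def train_suppressor(
    pairs,
    spec: UNetSpec,
    epochs: int = 5,
    seed: int = 0,
    val_pairs=None,
    model: UNet3D | None = None,
):
    """Train the artifact-suppression U-Net with Adam on the SSIM loss.

    ``pairs`` are :class:`~fresco.datagen.TrainingPair`; each block is
    normalized by its own corrupted 99th-percentile magnitude.  Returns
    ``(model, history)`` with per-epoch train/val losses; deterministic
    under ``seed``.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one training pair")
    rng = np.random.default_rng(seed)
    model = model or build_unet(spec, seed=seed)
    model.residual = spec.residual  # recorded so inference matches training
    opt = Adam(model.params(), lr=spec.lr)
    train_data = _prep(pairs)
    val_data = _prep(val_pairs) if val_pairs else None
    history = []
    for ep in range(epochs):
        tr = _epoch(model, opt, train_data, rng, train=True, residual=spec.residual)
        rec = {"epoch": ep, "train_loss": tr}
        if val_data:
            rec["val_loss"] = _epoch(
                model, opt, val_data, rng, train=False, residual=spec.residual
            )
        history.append(rec)
    return model, history


def suppress(
    model: UNet3D,
    comp_block: np.ndarray,
    enc_block: np.ndarray,
    residual: bool | None = None,
):
    """Run both encodings independently through the trained model.

    Blocks are already normalized (channel values in [-1, 1]); outputs
    keep the same shape and scale.  ``residual`` defaults to the mode
    the model was trained with.
    """
    if residual is None:
        residual = getattr(model, "residual", True)
    outs = []
    for ch in (comp_block, enc_block):
        if ch.ndim != 4 or ch.shape[0] != 2:
            raise ValueError("expected normalized (2, T, H, W) channel blocks")
        x = ch.astype(np.float32)
        out = model.forward(x)
        outs.append(x + out if residual else out)
    return outs[0], outs[1]


def successive_halving_search(space, evaluate, max_rounds: int | None = None, eta: int = 3, base_epochs: int = 1):
    """Reduced successive-halving hyperparameter search (keep 1/eta).

    ``evaluate(spec, n_epochs) -> val_loss``; each round multiplies the
    epoch budget by ``eta`` and keeps the best ``1/eta`` of the
    survivors.  Returns ``(best_spec, log)`` where the log records every
    evaluation and the total epoch budget spent.
    """
    specs = list(space)
    if not specs:
        raise ValueError("empty search space")
    log = {"rounds": [], "epochs_spent": 0}
    epochs = base_epochs
    rnd = 0
    while len(specs) > 1 and (max_rounds is None or rnd < max_rounds):
        scores = [evaluate(s, epochs) for s in specs]
        log["epochs_spent"] += epochs * len(specs)
        order = np.argsort(scores)
        keep = max(1, len(specs) // eta)
        log["rounds"].append(
            {"n": len(specs), "epochs": epochs, "best": float(np.min(scores))}
        )
        specs = [specs[i] for i in order[:keep]]
        epochs *= eta
        rnd += 1
    return specs[0], log


def save_model(path, model: UNet3D, spec: UNetSpec):
    """Checkpoint: npz of parameters + JSON sidecar with the spec."""
    path = Path(path)
    np.savez(path, *[p.data for p in model.params()])
    path.with_suffix(".json").write_text(json.dumps(asdict(spec)))


def load_model(path) -> tuple[UNet3D, UNetSpec]:
    path = Path(path)
    spec = UNetSpec(**json.loads(path.with_suffix(".json").read_text()))
    model = build_unet(spec)
    model.residual = getattr(spec, "residual", False)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
        model.load_state_dict([z[k] for k in z.files])
    return model, spec
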