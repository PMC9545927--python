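"""Desk-scale training-set assembly from synthetic phantoms.

The acquisition geometry is scaled with the phantom grid (FOV =
grid x voxel) while the density profile keeps its printed per-arm
acceleration plateaus, so the per-frame undersampling severity (the
8.7x/21.7x inner/outer regime) is preserved at any grid size.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .datagen import TrainingPair, build_training_pairs
from .phantom import PhantomConfig, generate_phantom
from .trajectory import AcquisitionParams

__all__ = ["desk_acquisition", "make_phantoms", "make_phantom_pairs"]


def desk_acquisition(grid: int = 64, voxel_mm: float = 2.1) -> AcquisitionParams:
    """Acquisition parameters for a reduced grid at unchanged voxel size."""
    return AcquisitionParams(fov_mm=grid * voxel_mm, voxel_mm=voxel_mm)


def make_phantoms(
    n_phantoms: int,
    seed: int = 0,
    grid: int = 64,
    n_blocks: int = 1,
    block: int = 24,
    frame_ms: float = 35.0,
    noise_sd: float = 0.02,
):
    """Short rest-only phantoms with varied physiology for training.

    Heart rate, stroke volume, vessel size and position are drawn per
    phantom so the networks see anatomical and temporal variety.
    """
    rng = np.random.default_rng(seed)
    phantoms = []
    dur = n_blocks * block * frame_ms / 1000.0
    for i in range(n_phantoms):
        hr = float(rng.uniform(60, 95))
        sv = float(rng.uniform(65, 95))
        r_mm = float(rng.uniform(11, 16))
        fov_mm = grid * 2.1
        r_px = r_mm / 2.1
        cy = float(rng.uniform(0.30, 0.60) * grid)
        cx = float(rng.uniform(0.40, 0.70) * grid)
        cy = float(np.clip(cy, r_px + 2, grid - r_px - 2))
        cx = float(np.clip(cx, r_px + 2, grid - r_px - 2))
        cfg = PhantomConfig(
            grid=grid,
            duration_s=dur,
            hr_bpm=hr,
            hr_ramp=(dur + 1, dur + 2, hr),  # flat: ramp after the end
            sv_ml=sv,
            sv_peak_ml=sv,
            vessel_center=(cy, cx),
            vessel_radius_mm=r_mm,
            frame_ms=frame_ms,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        phantoms.append(generate_phantom(cfg))
    return phantoms


def make_phantom_pairs(
    cfg=None,
    n_phantoms: int = 4,
    seed: int = 0,
    with_masks: bool = True,
    grid: int = 64,
    n_blocks: int = 1,
    augment: bool = True,
    n_samples_per_arm: int = 512,
) -> list[TrainingPair]:
    """Phantoms -> paired (aliased, truth[, masks]) training blocks."""
    density = cfg.density if cfg is not None else None
    crop = cfg.crop if cfg is not None else grid
    phantoms = make_phantoms(n_phantoms, seed=seed, grid=grid, n_blocks=n_blocks)
    params = desk_acquisition(grid)
    pairs = build_training_pairs(
        phantoms,
        params,
        spec=density,
        crop=min(crop, grid),
        n_samples_per_arm=n_samples_per_arm,
        augment=augment,
        seed=seed + 1,
    )
    if not with_masks:
        pairs = [dataclasses.replace(p, masks=None) for p in pairs]
    return pairs


def restored_pc_block(pair: TrainingPair, recon_model, venc_cm_s: float = 200.0):
    """Combined phase-contrast block after deep artifact suppression of
    the pair's two aliased encodings (the segmentation input domain of
    the running pipeline)."""
    from .encoding import EncodingPair, combine_pair
    from .recon_net import channels_to_block, suppress
    from .stream import normalize_block

    if pair.corrupted_comp is None:
        raise ValueError("pair lacks the aliased compensated encoding")
    enc_pair = EncodingPair(
        comp=pair.corrupted_comp, enc=pair.corrupted, venc_cm_s=venc_cm_s
    )
    cn, en, _ = normalize_block(enc_pair)
    cs, es = suppress(recon_model, cn, en)
    sup = EncodingPair(
        comp=channels_to_block(cs), enc=channels_to_block(es), venc_cm_s=venc_cm_s
    )
    return combine_pair(sup)


def make_seg_pairs(pairs, recon_model=None):
    """Segmentation training set: clean phase-subtracted blocks plus —
    when a trained suppressor is given — the same blocks restored from
    their aliased encodings, so the segmenter sees both domains."""
    out = list(pairs)
    if recon_model is not None:
        for p in pairs:
            out.append(
                dataclasses.replace(p, pc_truth=restored_pc_block(p, recon_model))
            )
    return out
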