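"""Paired corrupted/truth training data via synthetic undersampling.

Training pairs mimic the acquisition: truth cine frames are sampled onto
the variable-density spiral trajectory, density-compensated and gridded
back, producing the aliased "corrupted" member.  Augmentations (flips,
right-angle rotations, time roll, smooth phase offsets, translational
drift on half of the cases) are applied identically to both members —
by default to the truth series *before* undersampling, so the aliasing
pattern of the corrupted member stays physically consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import shift as nd_shift

from .containers import CineSeries
from .trajectory import (
    AcquisitionParams,
    DensitySpec,
    density_compensation,
    design_vd_arm,
    frame_trajectory,
)

__all__ = [
    "TrainingPair",
    "synth_undersample",
    "augment_pair",
    "make_blocks",
    "split_ids",
    "build_training_pairs",
]


@dataclass
class TrainingPair:
    corrupted: np.ndarray  # (T, H, W) complex
    truth: np.ndarray  # (T, H, W) complex (with background phase)
    meta: dict = field(default_factory=dict)
    masks: np.ndarray | None = None  # optional (T, H, W) bool, for segmentation
    pc_truth: np.ndarray | None = None  # phase-subtracted block (seg input domain)
    corrupted_comp: np.ndarray | None = None  # aliased flow-compensated encoding


def synth_undersample(
    cine: CineSeries,
    trajs: list,
    dcfs: list,
    params: AcquisitionParams,
) -> CineSeries:
    """Aliased copy of a cine: per-frame NUFFT sample -> DCF -> adjoint grid."""
    from .encoding import grid_samples, sample_image

    if len(trajs) != cine.n_frames or len(dcfs) != cine.n_frames:
        raise ValueError("trajectory/frame count mismatch")
    shape = cine.shape
    out = np.empty_like(cine.frames)
    for i in range(cine.n_frames):
        s = sample_image(cine.frames[i], trajs[i], params)
        out[i] = grid_samples(s, dcfs[i], trajs[i], params, shape)
    return CineSeries(
        frames=out,
        voxel_mm=cine.voxel_mm,
        frame_ms=cine.frame_ms,
        venc_cm_s=cine.venc_cm_s,
    )


def _random_phase_poly(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Random 2nd-order polynomial phase with max |phase| <= pi/2."""
    H, W = shape
    y = (np.arange(H) - H / 2.0) / H
    x = (np.arange(W) - W / 2.0) / W
    ph = np.zeros((H, W))
    for i in range(3):
        for j in range(3 - i):
            ph += rng.uniform(-1, 1) * np.outer(y**i, x**j)
    m = np.abs(ph).max()
    if m > 0:
        ph *= rng.uniform(0.2, 1.0) * (np.pi / 2.0) / m
    return ph


def _apply_transform(block: np.ndarray, tf: dict) -> np.ndarray:
    """Apply a geometric/phase transform to a complex (T, H, W) block."""
    out = block
    if tf["flip"] == "h":
        out = out[:, :, ::-1]
    elif tf["flip"] == "v":
        out = out[:, ::-1, :]
    if tf["rot90"]:
        out = np.rot90(out, k=tf["rot90"], axes=(1, 2))
    if tf["roll"]:
        out = np.roll(out, tf["roll"], axis=0)
    if tf.get("phase") is not None and np.iscomplexobj(out):
        out = out * np.exp(1j * tf["phase"])
    drift = tf.get("drift")
    if drift is not None:
        moved = np.empty_like(out)
        for t in range(out.shape[0]):
            dy, dx = drift[t]
            if np.iscomplexobj(out):
                moved[t] = nd_shift(out[t].real, (dy, dx), order=1) + 1j * nd_shift(
                    out[t].imag, (dy, dx), order=1
                )
            else:
                moved[t] = nd_shift(out[t].astype(float), (dy, dx), order=1)
        out = moved
    return np.ascontiguousarray(out)


def draw_transform(
    shape: tuple[int, int],
    n_frames: int,
    rng: np.random.Generator,
    p_translate: float = 0.5,
    allow_any_rotation: bool = False,
) -> dict:
    """Sample one augmentation; rotations restricted to multiples of 90 deg
    unless ``allow_any_rotation`` (bilinear interpolation on real/imag)."""
    tf = {
        "flip": rng.choice(["none", "h", "v"]),
        "rot90": int(rng.integers(0, 4)),
        "roll": int(rng.integers(0, n_frames)),
        "phase": _random_phase_poly(shape, rng),
        "drift": None,
    }
    if rng.uniform() < p_translate:
        amp = rng.uniform(1.0, 4.0)
        per = rng.uniform(2.0, 6.0)  # drift period in seconds
        ang = rng.uniform(0, 2 * np.pi)
        t = np.arange(n_frames) * 0.035
        d = amp * np.sin(2 * np.pi * t / per)
        tf["drift"] = np.stack([d * np.sin(ang), d * np.cos(ang)], axis=1)
    return tf


def augment_pair(
    pair: TrainingPair,
    rng: np.random.Generator,
    p_translate: float = 0.5,
    allow_any_rotation: bool = False,
) -> TrainingPair:
    """Apply one random augmentation identically to both pair members."""
    tf = draw_transform(
        pair.truth.shape[-2:], pair.truth.shape[0], rng, p_translate, allow_any_rotation
    )
    masks = None
    if pair.masks is not None:
        mtf = dict(tf, phase=None)  # phase offsets do not touch masks
        masks = _apply_transform(pair.masks.astype(np.float32), mtf) >= 0.5
    pc = None
    if pair.pc_truth is not None:
        pc = _apply_transform(pair.pc_truth, dict(tf, phase=None))
    cc = None
    if pair.corrupted_comp is not None:
        cc = _apply_transform(pair.corrupted_comp, tf)
    return TrainingPair(
        corrupted=_apply_transform(pair.corrupted, tf),
        truth=_apply_transform(pair.truth, tf),
        meta=dict(pair.meta, augment={k: v for k, v in tf.items() if k != "phase"}),
        masks=masks,
        pc_truth=pc,
        corrupted_comp=cc,
    )


def make_blocks(
    series: CineSeries | np.ndarray,
    block: int = 24,
    crop: int = 128,
    extra: np.ndarray | None = None,
):
    """Non-overlapping center-cropped (T=block, crop, crop) sub-blocks.

    Returns a list of arrays (and a matching list for ``extra``, e.g.
    masks, when given).  A series shorter than one block yields an empty
    list with a warning.
    """
    frames = series.frames if isinstance(series, CineSeries) else np.asarray(series)
    T, H, W = frames.shape
    if T < block:
        warnings.warn(f"series of {T} frames shorter than block {block}; skipped")
        return ([], []) if extra is not None else []
    if crop > H or crop > W:
        raise ValueError("crop larger than frame")
    y0 = (H - crop) // 2
    x0 = (W - crop) // 2
    blocks, extras = [], []
    for s in range(0, T - block + 1, block):
        blocks.append(frames[s : s + block, y0 : y0 + crop, x0 : x0 + crop].copy())
        if extra is not None:
            extras.append(extra[s : s + block, y0 : y0 + crop, x0 : x0 + crop].copy())
    return (blocks, extras) if extra is not None else blocks


def split_ids(ids, fractions=(470, 30, 16), seed: int = 0):
    """Disjoint train/val/test split by id, deterministic under seed.

    ``fractions`` are relative weights (the cohort design used
    470/30/16 for artifact suppression and 70/10/16 for segmentation);
    counts are rounded, with the remainder assigned to training.
    """
    ids = list(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    w = np.asarray(fractions, dtype=float)
    n_val = int(round(len(ids) * w[1] / w.sum()))
    n_test = int(round(len(ids) * w[2] / w.sum()))
    n_train = len(ids) - n_val - n_test
    shuffled = [ids[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def build_training_pairs(
    phantoms,
    params: AcquisitionParams,
    spec: DensitySpec | None = None,
    block: int = 24,
    crop: int = 64,
    n_samples_per_arm: int = 512,
    augment: bool = True,
    p_translate: float = 0.5,
    augment_before_undersample: bool = True,
    seed: int = 0,
) -> list[TrainingPair]:
    """End-to-end training-set builder from phantom cines.

    For each phantom: (optionally augment the truth), synthetically
    undersample with the golden-angle schedule continuing across frames,
    block and crop.  Blocks are left unnormalized; normalization is the
    streaming stage's job and is applied by the trainers.
    """
    from .phantom import PhantomData

    spec = spec or DensitySpec()
    rng = np.random.default_rng(seed)
    arm = design_vd_arm(params, spec, n_samples_per_arm)
    pairs = []
    for pid, ph in enumerate(phantoms):
        cine = ph.cine() if isinstance(ph, PhantomData) else ph
        masks = ph.truth.masks if isinstance(ph, PhantomData) else None
        pc = ph.pc_cine().frames if isinstance(ph, PhantomData) else None
        comp_frames = None
        if isinstance(ph, PhantomData):
            # flow-compensated encoding: background phase only, no velocity
            comp_frames = ph.magnitude * np.exp(1j * np.broadcast_to(ph.phi0, ph.magnitude.shape))
        frames = cine.frames
        if augment and augment_before_undersample:
            tf = draw_transform(frames.shape[-2:], frames.shape[0], rng, p_translate)
            frames = _apply_transform(frames, tf)
            if masks is not None:
                masks = _apply_transform(masks.astype(np.float32), dict(tf, phase=None)) >= 0.5
            if pc is not None:
                pc = _apply_transform(pc, dict(tf, phase=None))
            if comp_frames is not None:
                comp_frames = _apply_transform(comp_frames, tf)
            cine = CineSeries(frames, cine.voxel_mm, cine.frame_ms, cine.venc_cm_s)
        trajs = [frame_trajectory(arm, i, params) for i in range(cine.n_frames)]
        # relative arm angles are identical in every frame (the schedule is
        # a rigid golden-angle rotation of frame 0), so one DCF serves all
        dcf0 = density_compensation(trajs[0], params)
        dcfs = [dcf0] * len(trajs)
        aliased = synth_undersample(cine, trajs, dcfs, params)
        comp_aliased = None
        if comp_frames is not None:
            comp_cine = CineSeries(comp_frames, cine.voxel_mm, cine.frame_ms, cine.venc_cm_s)
            comp_aliased = synth_undersample(comp_cine, trajs, dcfs, params)
        tr_blocks = make_blocks(cine, block, crop)
        al_blocks = make_blocks(aliased, block, crop)
        m_blocks = (
            make_blocks(masks.astype(np.float32), block, crop) if masks is not None else None
        )
        pc_blocks = make_blocks(pc, block, crop) if pc is not None else None
        ca_blocks = make_blocks(comp_aliased, block, crop) if comp_aliased is not None else None
        for bi, (tb, ab) in enumerate(zip(tr_blocks, al_blocks)):
            pair = TrainingPair(
                corrupted=ab,
                truth=tb,
                meta={"source": pid, "block": bi},
                masks=(m_blocks[bi] >= 0.5) if m_blocks is not None else None,
                pc_truth=pc_blocks[bi] if pc_blocks is not None else None,
                corrupted_comp=ca_blocks[bi] if ca_blocks is not None else None,
            )
            if augment and not augment_before_undersample:
                pair = augment_pair(pair, rng, p_translate)
            pairs.append(pair)
    return pairs
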