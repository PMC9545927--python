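"""Forward/adjoint nonuniform sampling, coils, and velocity encoding.

Phase-contrast MR encodes through-plane velocity in the image phase: two
readouts are acquired per spiral position, one flow-compensated and one
flow-encoded, and their phase difference is ``pi * v / VENC``.  This
module owns that arithmetic together with the k-space sampling model
(type-2/type-1 NUFFT at the trajectory coordinates), analytic and
estimated coil sensitivities, subtraction of a low-order background
(Maxwell-style) phase, and an iterative temporal-TV reconstruction used
as an internal comparison oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .nufft import NufftPlan
from .trajectory import AcquisitionParams, DensityWeights, FrameTrajectory

__all__ = [
    "CoilMaps",
    "EncodingPair",
    "MaxwellModel",
    "CSConfig",
    "sample_image",
    "grid_samples",
    "synth_coil_maps",
    "estimate_coil_maps",
    "coil_combine",
    "encode_velocity",
    "combine_pair",
    "phase_to_velocity",
    "velocity_to_phase",
    "wrap_phase",
    "cs_reconstruct",
]


@dataclass
class CoilMaps:
    maps: np.ndarray  # (n_coils, H, W) complex; RSS ~ 1 inside support

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]


@dataclass
class EncodingPair:
    """Flow-compensated and flow-encoded complex frames (same shape)."""

    comp: np.ndarray
    enc: np.ndarray
    venc_cm_s: float

    def __post_init__(self):
        if self.comp.shape != self.enc.shape:
            raise ValueError("comp/enc shape mismatch")
        if self.venc_cm_s <= 0:
            raise ValueError("venc must be positive")


@dataclass
class MaxwellModel:
    """Low-order 2D polynomial background phase phi(y, x) in radians.

    ``coeffs[i, j]`` multiplies ``(y/H)^i (x/W)^j`` with centred, unit-
    normalized coordinates; degree <= 2 in each axis.
    """

    coeffs: np.ndarray

    def __post_init__(self):
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        if self.coeffs.shape[0] > 3 or self.coeffs.shape[1] > 3:
            raise ValueError("background phase polynomial degree must be <= 2")

    def evaluate(self, shape: tuple[int, int]) -> np.ndarray:
        H, W = shape
        y = (np.arange(H) - H / 2.0) / H
        x = (np.arange(W) - W / 2.0) / W
        out = np.zeros((H, W))
        for i in range(self.coeffs.shape[0]):
            for j in range(self.coeffs.shape[1]):
                out += self.coeffs[i, j] * np.outer(y**i, x**j)
        return out


@dataclass
class CSConfig:
    lambda_t: float = 5e-4
    n_iters: int = 40
    step: float | None = None  # None -> 1/L with L estimated by power iteration

    def __post_init__(self):
        if self.lambda_t <= 0:
            raise ValueError("lambda_t must be positive")


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phase), 2.0 * np.pi)


def _plan_for(traj: FrameTrajectory, params: AcquisitionParams, shape) -> NufftPlan:
    return NufftPlan(np.asarray(traj.k_coords) * params.voxel_mm, shape)


def sample_image(
    image: np.ndarray, traj: FrameTrajectory, params: AcquisitionParams
) -> np.ndarray:
    """Nonuniform Fourier samples of an image at the trajectory (type 2)."""
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    return _plan_for(traj, params, image.shape).forward(np.asarray(image, dtype=complex))


def grid_samples(
    samples: np.ndarray,
    weights: DensityWeights | np.ndarray,
    traj: FrameTrajectory,
    params: AcquisitionParams,
    shape: tuple[int, int],
) -> np.ndarray:
    """Density-weighted adjoint NUFFT of k-samples onto an H x W grid."""
    w = weights.weights if isinstance(weights, DensityWeights) else np.asarray(weights)
    samples = np.asarray(samples)
    if w.shape != samples.shape:
        raise ValueError("weight/sample length mismatch")
    return _plan_for(traj, params, shape).adjoint(samples * w)


def synth_coil_maps(n_coils: int, shape: tuple[int, int], seed: int = 0) -> CoilMaps:
    """Smooth synthetic sensitivities: Gaussian lobes on the FOV perimeter.

    Root-sum-of-squares normalized to 1 everywhere, with a mild smooth
    phase per coil; one coil degenerates to a uniform map.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    H, W = shape
    if n_coils == 1:
        return CoilMaps(maps=np.ones((1, H, W), dtype=complex))
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:H, 0:W]
    maps = np.empty((n_coils, H, W), dtype=complex)
    for c in range(n_coils):
        ang = 2.0 * np.pi * c / n_coils + rng.uniform(-0.2, 0.2)
        cy = H / 2.0 + 0.55 * H * np.sin(ang)
        cx = W / 2.0 + 0.55 * W * np.cos(ang)
        mag = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * (0.45 * H) ** 2)))
        ph = (
            rng.uniform(-1, 1) * (yy - H / 2) / H
            + rng.uniform(-1, 1) * (xx - W / 2) / W
        ) * np.pi / 4
        maps[c] = mag * np.exp(1j * ph)
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    return CoilMaps(maps=maps / rss)


def estimate_coil_maps(first_frames: np.ndarray, smooth_sigma: float = 2.0) -> CoilMaps:
    """Coil sensitivities from the temporal average of early frames.

    ``first_frames`` is (n_frames, n_coils, H, W).  The per-coil temporal
    average is divided by its root-sum-of-squares, lightly smoothed, and
    re-normalized.
    """
    frames = np.asarray(first_frames)
    if frames.ndim != 4 or frames.shape[0] < 1:
        raise ValueError("need (n_frames, n_coils, H, W) with >= 1 frame")
    avg = frames.mean(axis=0)
    rss = np.sqrt((np.abs(avg) ** 2).sum(axis=0))
    if not np.any(rss > 0):
        raise ValueError("degenerate all-zero input")
    floor = 1e-6 * rss.max()
    maps = avg / np.maximum(rss, floor)
    if smooth_sigma > 0:
        maps = gaussian_filter(maps.real, sigma=(0, smooth_sigma, smooth_sigma)) + 1j * gaussian_filter(
            maps.imag, sigma=(0, smooth_sigma, smooth_sigma)
        )
    rss2 = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    maps = maps / np.maximum(rss2, 1e-12)
    return CoilMaps(maps=maps)


def coil_combine(multi_coil_image: np.ndarray, maps: CoilMaps) -> np.ndarray:
    """Conjugate-weighted (Roemer) combination: sum conj(m) img / sum |m|^2."""
    img = np.asarray(multi_coil_image)
    if img.shape != maps.maps.shape:
        raise ValueError("image/maps shape mismatch")
    num = (np.conj(maps.maps) * img).sum(axis=0)
    den = (np.abs(maps.maps) ** 2).sum(axis=0)
    out = np.zeros_like(num)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def encode_velocity(
    magnitude: np.ndarray,
    velocity_cm_s: np.ndarray,
    phi0: np.ndarray | float,
    venc_cm_s: float,
) -> EncodingPair:
    """Build the (compensated, encoded) pair for a magnitude/velocity map.

    One-sided encoding: the compensated readout carries only the
    background phase ``phi0``, the encoded readout adds
    ``pi * v / VENC``.  Velocities beyond VENC wrap, as on the scanner.
    """
    if venc_cm_s <= 0:
        raise ValueError("venc must be positive")
    mag = np.asarray(magnitude, dtype=float)
    phi0 = np.broadcast_to(np.asarray(phi0, dtype=float), mag.shape)
    enc_phase = wrap_phase(phi0 + np.pi * np.asarray(velocity_cm_s) / venc_cm_s)
    return EncodingPair(
        comp=mag * np.exp(1j * wrap_phase(phi0)),
        enc=mag * np.exp(1j * enc_phase),
        venc_cm_s=venc_cm_s,
    )


def combine_pair(pair: EncodingPair, maxwell: MaxwellModel | None = None) -> np.ndarray:
    """Phase-contrast frame: average magnitude, phase subtraction.

    Returns ``mag * exp(i phase)`` with ``mag = (|comp| + |enc|) / 2`` and
    ``phase = angle(enc * conj(comp))`` minus the background-phase
    polynomial when a Maxwell model is supplied.
    """
    mag = 0.5 * (np.abs(pair.comp) + np.abs(pair.enc))
    phase = np.angle(pair.enc * np.conj(pair.comp))
    if maxwell is not None:
        bg = maxwell.evaluate(pair.comp.shape[-2:])
        phase = wrap_phase(phase - bg)
    return mag * np.exp(1j * phase)


def phase_to_velocity(phase: np.ndarray, venc_cm_s: float) -> np.ndarray:
    """v = VENC * phase / pi (cm/s)."""
    return venc_cm_s * np.asarray(phase) / np.pi


def velocity_to_phase(velocity_cm_s: np.ndarray, venc_cm_s: float) -> np.ndarray:
    """Inverse map; wraps into (-pi, pi], i.e. v into (-VENC, VENC]."""
    return wrap_phase(np.pi * np.asarray(velocity_cm_s) / venc_cm_s)


# ---------------------------------------------------------------------------
# temporal-TV compressed-sensing oracle
# ---------------------------------------------------------------------------


def _tv_t(x: np.ndarray) -> float:
    return float(np.abs(np.diff(x, axis=0)).sum())


def _prox_tv_t(x: np.ndarray, lam: float, n_inner: int = 30) -> np.ndarray:
    """Proximal map of lam * ||D_t x||_1 via dual (Chambolle) ascent.

    Vectorized over all pixels; real and imaginary parts are denoised
    jointly through the complex-valued dual variable.
    """
    if lam <= 0:
        return x
    p = np.zeros((x.shape[0] - 1,) + x.shape[1:], dtype=x.dtype)
    tau = 0.25
    for _ in range(n_inner):
        # gradient of the dual objective: D (x - lam * D^T p)
        div = np.zeros_like(x)
        div[:-1] -= p
        div[1:] += p
        grad = np.diff(x - lam * div, axis=0)
        p = p + tau * grad
        mag = np.maximum(np.abs(p), 1.0)
        p = p / mag
    div = np.zeros_like(x)
    div[:-1] -= p
    div[1:] += p
    return x - lam * div


def cs_reconstruct(
    kspace_frames: list[np.ndarray],
    trajs: list[FrameTrajectory],
    weights: list[DensityWeights],
    params: AcquisitionParams,
    shape: tuple[int, int],
    cfg: CSConfig | None = None,
    maps: CoilMaps | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Temporal-total-variation regularized block reconstruction.

    Minimizes ``0.5 sum_t ||W^(1/2)(F_t x_t - y_t)||^2 + lambda ||D_t x||_1``
    by monotone FISTA, with the density weights acting as a diagonal
    preconditioner on the data term.  ``kspace_frames`` holds coil-combined
    single-coil k-samples per frame (multi-coil input is combined with
    ``maps`` first).  Returns (frames, objective trace); the trace is
    non-increasing by construction.
    """
    if len(kspace_frames) < 2:
        raise ValueError("need a block of >= 2 frames")
    cfg = cfg or CSConfig()
    T = len(kspace_frames)
    plans = [NufftPlan(np.asarray(t.k_coords) * params.voxel_mm, shape) for t in trajs]
    wts = [w.weights if isinstance(w, DensityWeights) else np.asarray(w) for w in weights]

    def A(x):
        return [plans[t].forward(x[t]) for t in range(T)]

    def At(y):
        return np.stack([plans[t].adjoint(wts[t] * y[t]) for t in range(T)])

    y = list(kspace_frames)

    def objective(x):
        resid = 0.0
        for t in range(T):
            r = plans[t].forward(x[t]) - y[t]
            resid += 0.5 * float(np.sum(wts[t] * np.abs(r) ** 2))
        return resid + cfg.lambda_t * _tv_t(x)

    if cfg.step is None:
        # Lipschitz constant of the weighted normal operator by power iteration
        rng = np.random.default_rng(0)
        v = rng.normal(size=(T,) + shape) + 1j * rng.normal(size=(T,) + shape)
        for _ in range(8):
            v = At(A(v))
            v = v / np.linalg.norm(v)
        L = float(np.linalg.norm(At(A(v))))
        step = 1.0 / max(L, 1e-12)
    else:
        step = cfg.step

    x = At(y)
    z = x.copy()
    t_acc = 1.0
    best = objective(x)
    trace = [best]
    for _ in range(cfg.n_iters):
        grad = At([a - b for a, b in zip(A(z), y)])
        x_new = _prox_tv_t(z - step * grad, cfg.lambda_t * step)
        f_new = objective(x_new)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2))
        if f_new <= best:  # monotone acceptance
            z = x_new + ((t_acc - 1.0) / t_new) * (x_new - x)
            x = x_new
            best = f_new
        else:
            z = x.copy()
            t_acc = 1.0
        t_acc = t_new
        trace.append(best)
    if trace[-1] > trace[0] * (1 + 1e-9):
        import warnings

        warnings.warn(f"CS objective did not decrease: {trace[:3]}...{trace[-1]:.3g}")
    return x, trace
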