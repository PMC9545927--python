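"""Synthetic dynamic phase-contrast phantom: pulsatile aortic flow.

Generates a circular vessel with a parabolic through-plane velocity
profile, pulsing with a systolic half-sinusoid waveform, beat-to-beat RR
jitter, a rest/exercise/recovery heart-rate ramp, respiratory stroke-
volume modulation and translation, over a static background of tissue
ellipses.  The ground truth (masks, flow curve, beat table) is carried
along and is the recovery target for every end-to-end test.

Default physiology: resting heart rate 68 bpm ramping to 94 bpm over a
40 s rest / 80 s exercise / 60 s recovery protocol, stroke volume in the
80s of mL, multiplicative lognormal RR jitter (sigma = 0.03) and a 4 s
respiratory cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CineSeries

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "PhantomData",
    "flow_waveform",
    "exercise_profile",
    "generate_phantom",
    "simulate_multicoil_kspace",
]

#: systole occupies the first 35% of the cycle
_SYSTOLE_FRAC = 0.35
#: constant diastolic pedestal as a fraction of peak velocity
_DIASTOLIC_FRAC = 0.05
#: beat-average of the waveform in units of v_peak
WAVEFORM_MEAN = _DIASTOLIC_FRAC + (2.0 / np.pi) * _SYSTOLE_FRAC


@dataclass(frozen=True)
class PhantomConfig:
    grid: int = 192
    voxel_mm: float = 2.1
    frame_ms: float = 35.0
    duration_s: float = 180.0
    hr_bpm: float = 68.0
    hr_ramp: tuple[float, float, float] = (40.0, 120.0, 94.0)  # (t_start, t_end, hr_peak)
    sv_ml: float = 85.0
    sv_peak_ml: float = 79.0
    resp_period_s: float = 4.0
    resp_sv_frac: float = 0.1
    vessel_center: tuple[float, float] | None = None  # (y, x) px; None -> offset from centre
    vessel_radius_mm: float = 15.0
    vessel_wall_mm: float = 2.0
    motion_amp_px: float = 2.0
    rr_jitter_sd: float = 0.03
    noise_sd: float = 0.02
    n_coils: int = 6
    venc_cm_s: float = 200.0
    #: peak amplitude of the smooth background (receiver/B0) phase common
    #: to both encodings; real compensated images are phase-rich, which
    #: is what forces the restoration network to be phase-faithful
    phi0_amp_rad: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.vessel_radius_mm <= 0:
            raise ValueError("vessel_radius_mm must be positive")
        if not (0.0 <= self.resp_sv_frac < 0.5):
            raise ValueError("resp_sv_frac must be in [0, 0.5)")
        if not (30.0 <= self.hr_bpm <= 220.0):
            raise ValueError("hr_bpm must be in [30, 220]")
        r_px = self.vessel_radius_mm / self.voxel_mm
        cy, cx = self.center_px
        if (
            cy - r_px < 1
            or cx - r_px < 1
            or cy + r_px > self.grid - 1
            or cx + r_px > self.grid - 1
        ):
            raise ValueError("vessel extends outside the FOV")

    @property
    def center_px(self) -> tuple[float, float]:
        if self.vessel_center is not None:
            return self.vessel_center
        return (self.grid * 0.42, self.grid * 0.58)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * 1000.0 / self.frame_ms))


@dataclass
class GroundTruth:
    masks: np.ndarray  # (T, H, W) bool
    flow_ml_s: np.ndarray  # (T,) from masks + velocity (self-consistent)
    velocity_cm_s: np.ndarray  # (T, H, W)
    beats: pd.DataFrame  # onset_ms, peak_time_ms, rr_ms, hr_bpm, sv_ml, co_l_min
    pixel_area_mm2: float = field(default=2.1**2)


@dataclass
class PhantomData:
    magnitude: np.ndarray  # (T, H, W) in [0, 1]
    velocity_cm_s: np.ndarray  # (T, H, W)
    truth: GroundTruth
    config: PhantomConfig
    phi0: np.ndarray | float = 0.0  # smooth background phase (H, W), radians

    def cine(self, phi0: np.ndarray | float | None = None) -> CineSeries:
        """Complex cine with velocity phase plus the background phase.

        ``phi0=None`` uses the phantom's own background; pass 0 for the
        phase-subtracted (background-free) series.
        """
        if phi0 is None:
            phi0 = self.phi0
        phase = np.pi * self.velocity_cm_s / self.config.venc_cm_s + phi0
        return CineSeries(
            frames=self.magnitude * np.exp(1j * phase),
            voxel_mm=self.config.voxel_mm,
            frame_ms=self.config.frame_ms,
            venc_cm_s=self.config.venc_cm_s,
        )

    def pc_cine(self) -> CineSeries:
        """Phase-subtracted series (velocity phase only) — the
        segmentation-network input domain."""
        return self.cine(phi0=0.0)


def flow_waveform(t_in_beat: np.ndarray, v_peak: float) -> np.ndarray:
    """Mean through-plane velocity (cm/s) at cycle fraction ``t_in_beat``.

    Systolic half-sinusoid over the first 35% of the cycle on top of a
    constant diastolic pedestal of 5% of ``v_peak``; continuous at both
    ends of systole.
    """
    t = np.asarray(t_in_beat, dtype=float)
    if np.any((t < 0) | (t >= 1)):
        raise ValueError("t_in_beat must be in [0, 1)")
    sys_part = np.where(t < _SYSTOLE_FRAC, np.sin(np.pi * np.minimum(t, _SYSTOLE_FRAC) / _SYSTOLE_FRAC), 0.0)
    return v_peak * (_DIASTOLIC_FRAC + sys_part)


def exercise_profile(t_s: float | np.ndarray, config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear (HR, SV) at time ``t_s`` for the three-phase protocol.

    Rest until ``hr_ramp[0]``, linear ramp to the peak at ``hr_ramp[1]``,
    linear recovery back to rest values by ``duration_s``.
    """
    t = np.asarray(t_s, dtype=float)
    t0, t1, hr_peak = config.hr_ramp
    t2 = config.duration_s
    up = np.clip((t - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
    down = np.clip((t - t1) / max(t2 - t1, 1e-9), 0.0, 1.0)
    frac = np.where(t <= t1, up, 1.0 - down)
    hr = config.hr_bpm + (hr_peak - config.hr_bpm) * frac
    sv = config.sv_ml + (config.sv_peak_ml - config.sv_ml) * frac
    return hr, sv


def _make_beats(config: PhantomConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    t = 0.0
    dur_ms = config.duration_s * 1000.0
    while t < dur_ms:
        hr, sv = exercise_profile(t / 1000.0, config)
        jitter = float(np.exp(rng.normal(0.0, config.rr_jitter_sd)))
        rr = 60000.0 / float(hr) * jitter
        resp = 1.0 + config.resp_sv_frac * np.sin(2.0 * np.pi * t / (config.resp_period_s * 1000.0))
        sv_beat = float(sv) * float(resp)
        hr_beat = 60000.0 / rr
        rows.append(
            dict(
                onset_ms=t,
                peak_time_ms=t + 0.5 * _SYSTOLE_FRAC * rr,
                rr_ms=rr,
                hr_bpm=hr_beat,
                sv_ml=sv_beat,
                co_l_min=sv_beat * hr_beat / 1000.0,
            )
        )
        t += rr
    return pd.DataFrame(rows)


def generate_phantom(config: PhantomConfig) -> PhantomData:
    """Build the dynamic phantom and its ground truth.

    Deterministic under ``config.seed``; two identical configs produce
    bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    beats = _make_beats(config, rng)
    N = config.grid
    T = config.n_frames
    area_mm2 = np.pi * config.vessel_radius_mm**2
    r_px = config.vessel_radius_mm / config.voxel_mm
    wall_px = config.vessel_wall_mm / config.voxel_mm
    cy0, cx0 = config.center_px

    # static background: soft body ellipse + a few tissue ellipses
    bg_rng = np.random.default_rng(config.seed + 1)
    yy, xx = np.mgrid[0:N, 0:N].astype(float)
    background = 0.25 * (
        ((yy - N / 2) / (0.46 * N)) ** 2 + ((xx - N / 2) / (0.46 * N)) ** 2 < 1.0
    ).astype(float)
    for _ in range(3):
        ey, ex = bg_rng.uniform(0.25 * N, 0.75 * N, size=2)
        ra = bg_rng.uniform(0.06, 0.16) * N
        rb = bg_rng.uniform(0.06, 0.16) * N
        background += 0.2 * (
            (((yy - ey) / ra) ** 2 + ((xx - ex) / rb) ** 2) < 1.0
        ).astype(float)
    background = np.clip(background, 0.0, 0.6)

    onsets = beats["onset_ms"].to_numpy()
    rrs = beats["rr_ms"].to_numpy()
    v_peaks = beats["sv_ml"].to_numpy() / (WAVEFORM_MEAN * area_mm2 * 0.01 * rrs / 1000.0)

    magnitude = np.empty((T, N, N), dtype=float)
    velocity = np.zeros((T, N, N), dtype=float)
    masks = np.zeros((T, N, N), dtype=bool)
    t_mid = (np.arange(T) + 0.5) * config.frame_ms
    beat_idx = np.clip(np.searchsorted(onsets, t_mid, side="right") - 1, 0, len(onsets) - 1)
    for i in range(T):
        b = beat_idx[i]
        tau = (t_mid[i] - onsets[b]) / rrs[b]
        tau = min(max(tau, 0.0), 1.0 - 1e-9)
        v_mean = float(flow_waveform(tau, v_peaks[b]))
        # respiratory in-plane translation of the vessel
        shift = config.motion_amp_px * np.sin(2.0 * np.pi * t_mid[i] / (config.resp_period_s * 1000.0))
        cy, cx = cy0 + shift, cx0
        rr2 = (yy - cy) ** 2 + (xx - cx) ** 2
        mask = rr2 <= r_px**2  # pixel centre-in-circle
        lumen = np.zeros((N, N))
        lumen[mask] = 2.0 * v_mean * (1.0 - rr2[mask] / r_px**2)
        wall = (rr2 <= (r_px + wall_px) ** 2) & ~mask
        frame = background.copy()
        frame[wall] = 0.45
        frame[mask] = 1.0
        magnitude[i] = frame
        velocity[i] = lumen
        masks[i] = mask

    pixel_area = config.voxel_mm**2
    flow = (velocity * masks).sum(axis=(1, 2)) * pixel_area * 0.01  # cm/s*mm^2 -> mL/s
    truth = GroundTruth(
        masks=masks,
        flow_ml_s=flow,
        velocity_cm_s=velocity,
        beats=beats,
        pixel_area_mm2=pixel_area,
    )
    # smooth random polynomial background phase, common to both encodings
    phi0 = 0.0
    if config.phi0_amp_rad > 0:
        yn = (np.arange(N) - N / 2.0) / N
        ph0 = np.zeros((N, N))
        for i in range(3):
            for j in range(3 - i):
                if i == 0 and j == 0:
                    continue
                ph0 += rng.uniform(-1, 1) * np.outer(yn**i, yn**j)
        phi0 = ph0 / max(np.abs(ph0).max(), 1e-12) * rng.uniform(0.5, 1.0) * config.phi0_amp_rad
    return PhantomData(
        magnitude=magnitude, velocity_cm_s=velocity, truth=truth, config=config, phi0=phi0
    )


def simulate_multicoil_kspace(
    phantom: PhantomData,
    trajs,
    params,
    maps,
    phi0: np.ndarray | float | None = None,
    rng: np.random.Generator | None = None,
):
    """Sample both encodings of the phantom through coils and trajectories.

    Returns ``(comp, enc)`` as lists over frames of (n_coils, n_samples)
    complex sample arrays, with i.i.d. complex Gaussian noise of standard
    deviation ``config.noise_sd`` (relative to the DC-normalized signal)
    added per coil.
    """
    from .encoding import encode_velocity, sample_image

    cfg = phantom.config
    if phi0 is None:
        phi0 = phantom.phi0
    rng = rng or np.random.default_rng(cfg.seed + 2)
    out_comp, out_enc = [], []
    # noise scaled to a typical k-sample magnitude so noise_sd is relative
    ref = float(np.abs(phantom.magnitude[0]).sum()) * 0.01
    for i, traj in enumerate(trajs):
        pair = encode_velocity(
            phantom.magnitude[i], phantom.velocity_cm_s[i], phi0, cfg.venc_cm_s
        )
        cc, ee = [], []
        for c in range(maps.n_coils):
            for block, store in ((pair.comp, cc), (pair.enc, ee)):
                s = sample_image(maps.maps[c] * block, traj, params)
                if cfg.noise_sd > 0:
                    s = s + cfg.noise_sd * ref * (
                        rng.normal(size=s.shape) + 1j * rng.normal(size=s.shape)
                    )
                store.append(s)
        out_comp.append(np.stack(cc))
        out_enc.append(np.stack(ee))
    return out_comp, out_enc
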