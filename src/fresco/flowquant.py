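"""Flow curves, beat detection, and beat-to-beat HR/SV/CO.

Units are explicit throughout: velocity in cm/s, pixel area in mm^2,
flow in mL/s (cm/s * mm^2 = 0.01 mL/s), stroke volume in mL and cardiac
output in L/min.  Beats are delimited peak-to-peak, so the summed
per-beat volumes conserve the integral of the flow curve exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "FlowCurve",
    "flow_curve",
    "detect_beats",
    "beat_metrics",
    "smooth_display",
]

#: cm/s times mm^2 gives 10 mm^3/s = 0.01 mL/s
CMS_MM2_TO_ML_S = 0.01


@dataclass
class FlowCurve:
    t_ms: np.ndarray  # frame mid-times, uniform spacing
    q_ml_s: np.ndarray

    def __post_init__(self):
        if len(self.t_ms) != len(self.q_ml_s):
            raise ValueError("time/flow length mismatch")
        if len(self.t_ms) > 1:
            dt = np.diff(self.t_ms)
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("frame times must be uniformly spaced")
        if not (np.all(np.isfinite(self.t_ms)) and np.all(np.isfinite(self.q_ml_s))):
            raise ValueError("non-finite flow curve")

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0]) if len(self.t_ms) > 1 else 0.0


def flow_curve(
    velocity_cm_s: np.ndarray,
    masks: np.ndarray,
    pixel_area_mm2: float,
    frame_ms: float = 35.0,
    t0_ms: float = 0.0,
) -> FlowCurve:
    """Per-frame flow: mask-summed velocity times pixel area.

    Frames with an empty mask contribute zero flow (with a warning).
    """
    v = np.asarray(velocity_cm_s, dtype=float)
    m = np.asarray(masks, dtype=bool)
    if v.shape != m.shape:
        raise ValueError("velocity/mask shape mismatch")
    empty = ~m.any(axis=(1, 2))
    if np.any(empty):
        warnings.warn(f"{int(empty.sum())} frames have an empty mask; flow set to 0")
    q = (v * m).sum(axis=(1, 2)) * pixel_area_mm2 * CMS_MM2_TO_ML_S
    t = t0_ms + (np.arange(v.shape[0]) + 0.5) * frame_ms
    return FlowCurve(t_ms=t, q_ml_s=q)


def detect_beats(
    curve: FlowCurve,
    hr_max_bpm: float = 220.0,
    prominence_frac: float = 0.2,
) -> np.ndarray:
    """Indices of systolic peaks in the flow curve.

    Peaks are constrained to a minimum spacing of ``60000 / hr_max_bpm``
    ms and must rise by at least ``prominence_frac`` of the median peak
    prominence of a permissive first pass — making detection invariant
    to rescaling of the curve.
    """
    q = curve.q_ml_s
    if len(q) < 2 or curve.dt_ms <= 0:
        return np.array([], dtype=int)
    if curve.t_ms[-1] - curve.t_ms[0] < 2000.0:
        raise ValueError("need at least 2 s of data for beat detection")
    spread = float(q.max() - q.min())
    if spread <= 0:
        return np.array([], dtype=int)
    min_dist = max(1, int(round(60000.0 / hr_max_bpm / curve.dt_ms)))
    loose, props = find_peaks(q, distance=min_dist, prominence=1e-9 * spread)
    if len(loose) == 0:
        return loose
    thresh = prominence_frac * float(np.median(props["prominences"]))
    peaks, _ = find_peaks(q, distance=min_dist, prominence=thresh)
    return peaks


def beat_metrics(curve: FlowCurve, peaks: np.ndarray) -> pd.DataFrame:
    """Beat table from consecutive peak-to-peak intervals.

    Per beat: SV is the trapezoidal integral of the flow between the two
    peaks (shared boundary samples, so beat volumes sum exactly to the
    integral over the spanned interval), HR = 60000/RR, CO = SV*HR/1000.
    """
    peaks = np.asarray(peaks, dtype=int)
    if len(peaks) < 2:
        return pd.DataFrame(
            columns=["peak_time_ms", "rr_ms", "hr_bpm", "sv_ml", "co_l_min", "flagged"]
        )
    t_s = curve.t_ms / 1000.0
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (curve.q_ml_s[1:] + curve.q_ml_s[:-1]) * np.diff(t_s))])
    rows = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        rr = curve.t_ms[b] - curve.t_ms[a]
        sv = cum[b] - cum[a]
        hr = 60000.0 / rr
        rows.append(
            dict(
                peak_time_ms=float(curve.t_ms[a]),
                rr_ms=float(rr),
                hr_bpm=hr,
                sv_ml=float(sv),
                co_l_min=float(sv) * hr / 1000.0,
                flagged=bool(sv < 0),
            )
        )
    df = pd.DataFrame(rows)
    if df.flagged.any():
        warnings.warn("negative stroke volume detected (check velocity sign convention)")
    return df


def smooth_display(series: np.ndarray, window_beats: int = 5) -> np.ndarray:
    """Running median for display; edge-truncated, window 1 = identity."""
    x = np.asarray(series, dtype=float)
    if window_beats <= 1 or len(x) == 0:
        return x.copy()
    if len(x) < window_beats:
        raise ValueError("series shorter than the median window")
    half = window_beats // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo = max(0, i - half)
        hi = min(len(x), i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out
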