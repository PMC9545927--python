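"""Shared in-memory containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CineSeries:
    """Time-ordered complex image frames — the universal image currency.

    ``frames`` is (T, H, W) complex; ``frame_ms`` is the frame duration
    (temporal resolution), ``voxel_mm`` the in-plane pixel spacing and
    ``venc_cm_s`` the velocity-encoding limit the phase scale refers to.
    """

    frames: np.ndarray
    voxel_mm: float
    frame_ms: float
    venc_cm_s: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[-2:]

    @property
    def t_mid_ms(self) -> np.ndarray:
        """Mid-acquisition time of each frame in ms."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_ms

    @property
    def pixel_area_mm2(self) -> float:
        return self.voxel_mm**2
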