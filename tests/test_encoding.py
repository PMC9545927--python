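"""Velocity encoding/decoding, coil handling, background-phase removal."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fresco.encoding import (
    EncodingPair,
    MaxwellModel,
    coil_combine,
    combine_pair,
    encode_velocity,
    estimate_coil_maps,
    phase_to_velocity,
    synth_coil_maps,
    velocity_to_phase,
    wrap_phase,
)


class TestVelocityPhase:
    def test_known_phase_values(self):
        assert velocity_to_phase(100.0, 200.0) == pytest.approx(np.pi / 2)
        assert phase_to_velocity(np.pi / 2, 200.0) == pytest.approx(100.0)
        assert phase_to_velocity(0.0, 200.0) == 0.0

    def test_zero_velocity_gives_identical_encodings(self):
        mag = np.ones((6, 6))
        pair = encode_velocity(mag, np.zeros((6, 6)), 0.3, 200.0)
        assert np.allclose(pair.comp, pair.enc)

    def test_beyond_venc_aliases(self):
        pair = encode_velocity(np.ones((4, 4)), np.full((4, 4), 250.0), 0.0, 200.0)
        v = phase_to_velocity(np.angle(combine_pair(pair)), 200.0)
        assert np.allclose(v, -150.0)

    @given(
        v=st.floats(-199.0, 199.0),
        phi0=st.floats(-10.0, 10.0),
    )
    def test_encode_combine_decode_identity(self, v, phi0):
        """Exact round trip for |v| < VENC with arbitrary background phase."""
        mag = np.full((4, 4), 0.7)
        pair = encode_velocity(mag, np.full((4, 4), v), phi0, 200.0)
        rec = phase_to_velocity(np.angle(combine_pair(pair)), 200.0)
        assert np.allclose(rec, v, atol=1e-9)

    @given(shift=st.integers(-3, 3))
    def test_wrap_safety_under_2pi_shifts(self, shift):
        """Adding multiples of 2 pi to any input phase changes nothing."""
        v = np.full((4, 4), 55.0)
        base = encode_velocity(np.ones((4, 4)), v, 0.4, 200.0)
        shifted = EncodingPair(
            comp=base.comp * np.exp(2j * np.pi * shift),
            enc=base.enc * np.exp(2j * np.pi * shift),
            venc_cm_s=200.0,
        )
        assert np.allclose(combine_pair(shifted), combine_pair(base), atol=1e-9)

    def test_invalid_venc_rejected(self):
        with pytest.raises(ValueError):
            encode_velocity(np.ones((2, 2)), np.zeros((2, 2)), 0.0, -1.0)

    def test_wrap_phase_range(self, rng):
        ph = wrap_phase(rng.uniform(-20, 20, size=100))
        assert np.all(ph > -np.pi - 1e-12) and np.all(ph <= np.pi + 1e-12)


class TestCombine:
    def test_magnitude_is_average(self):
        pair = EncodingPair(
            comp=2.0 * np.ones((3, 3), dtype=complex),
            enc=4.0 * np.ones((3, 3), dtype=complex),
            venc_cm_s=200.0,
        )
        assert np.allclose(np.abs(combine_pair(pair)), 3.0)

    def test_quadratic_background_removed_exactly(self):
        mm = MaxwellModel(np.array([[0.0, 0.2, 0.3], [0.1, 0.5, 0.0], [0.2, 0.0, 0.15]]))
        bg = mm.evaluate((8, 8))
        v = np.full((8, 8), 60.0)
        enc_phase = np.pi * v / 200.0 + bg
        pair = EncodingPair(
            comp=np.ones((8, 8), dtype=complex),
            enc=np.exp(1j * enc_phase),
            venc_cm_s=200.0,
        )
        phase = np.angle(combine_pair(pair, maxwell=mm))
        assert np.max(np.abs(phase - np.pi * v / 200.0)) < 1e-6

    def test_cubic_background_model_rejected(self):
        with pytest.raises(ValueError):
            MaxwellModel(np.zeros((4, 4)))


class TestCoils:
    def test_single_coil_is_identity(self, rng):
        maps = synth_coil_maps(1, (8, 8))
        img = rng.normal(size=(1, 8, 8)) + 1j * rng.normal(size=(1, 8, 8))
        assert np.allclose(coil_combine(img, maps), img[0])

    def test_combination_inverts_maps_exactly(self, rng):
        maps = synth_coil_maps(6, (16, 16), seed=3)
        img = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        rec = coil_combine(maps.maps * img, maps)
        assert np.allclose(rec, img, atol=1e-12)

    def test_combination_linear(self, rng):
        maps = synth_coil_maps(4, (8, 8), seed=1)
        a = rng.normal(size=(4, 8, 8)) + 1j * rng.normal(size=(4, 8, 8))
        b = rng.normal(size=(4, 8, 8)) + 1j * rng.normal(size=(4, 8, 8))
        lhs = coil_combine(a + 2.0 * b, maps)
        rhs = coil_combine(a, maps) + 2.0 * coil_combine(b, maps)
        assert np.allclose(lhs, rhs)

    def test_rss_normalized(self):
        maps = synth_coil_maps(5, (32, 32), seed=2)
        rss = np.sqrt((np.abs(maps.maps) ** 2).sum(axis=0))
        assert np.allclose(rss, 1.0, atol=1e-10)

    def test_reproducible_under_seed(self):
        a = synth_coil_maps(4, (8, 8), seed=7)
        b = synth_coil_maps(4, (8, 8), seed=7)
        assert np.array_equal(a.maps, b.maps)

    def test_estimated_maps_recover_truth(self, rng):
        truth = synth_coil_maps(6, (32, 32), seed=9)
        obj = np.exp(-(((np.arange(32) - 16) ** 2)[:, None] + ((np.arange(32) - 16) ** 2)[None, :]) / 100.0)
        frames = np.stack(
            [truth.maps * (obj * np.exp(0.2j * k)) for k in range(10)]
        )
        est = estimate_coil_maps(frames)
        support = obj > 0.1
        a = np.abs(est.maps)[:, support].ravel()
        b = np.abs(truth.maps)[:, support].ravel()
        corr = np.corrcoef(a, b)[0, 1]
        assert corr >= 0.95

    def test_identical_frames_average_idempotent(self, rng):
        truth = synth_coil_maps(3, (16, 16), seed=4)
        frame = truth.maps * (rng.normal(size=(16, 16)) + 2.0)
        one = estimate_coil_maps(frame[None])
        ten = estimate_coil_maps(np.repeat(frame[None], 10, axis=0))
        assert np.allclose(one.maps, ten.maps)

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_coil_maps(np.zeros((2, 3, 8, 8), dtype=complex))
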