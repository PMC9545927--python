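"""Pulsatile-flow phantom: waveform, ground-truth consistency, physiology."""

import numpy as np
import pytest
from scipy.integrate import quad

from fresco.phantom import (
    WAVEFORM_MEAN,
    PhantomConfig,
    exercise_profile,
    flow_waveform,
    generate_phantom,
)


def rest_config(**kw):
    base = dict(
        grid=64,
        duration_s=20.0,
        hr_bpm=75.0,
        hr_ramp=(21.0, 22.0, 75.0),
        sv_ml=80.0,
        sv_peak_ml=80.0,
        seed=3,
    )
    base.update(kw)
    return PhantomConfig(**base)


class TestWaveform:
    def test_diastolic_pedestal_at_cycle_start(self):
        assert flow_waveform(0.0, 100.0) == pytest.approx(5.0)

    def test_peak_at_mid_systole(self):
        assert flow_waveform(0.175, 100.0) == pytest.approx(105.0)
        t = np.linspace(0, 0.999, 2000)
        assert flow_waveform(t, 100.0).max() == pytest.approx(105.0, rel=1e-5)

    def test_beat_integral_matches_closed_form(self):
        val, _ = quad(lambda t: flow_waveform(t, 123.0), 0.0, 1.0, points=[0.35], limit=200)
        assert val == pytest.approx(123.0 * WAVEFORM_MEAN, rel=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            flow_waveform(1.2, 10.0)


class TestExerciseProfile:
    def test_rest_and_peak_heart_rates(self):
        cfg = PhantomConfig(grid=64, duration_s=180.0)
        hr0, sv0 = exercise_profile(0.0, cfg)
        hrp, svp = exercise_profile(120.0, cfg)
        hr_end, _ = exercise_profile(180.0, cfg)
        assert hr0 == pytest.approx(68.0)  # cohort rest mean
        assert hrp == pytest.approx(94.0)  # cohort peak mean
        assert hr_end == pytest.approx(68.0)  # recovered by the end
        assert sv0 == pytest.approx(85.0) and svp == pytest.approx(79.0)

    def test_mid_ramp_linear(self):
        cfg = PhantomConfig(grid=64, duration_s=180.0)
        hr, _ = exercise_profile(80.0, cfg)
        assert hr == pytest.approx(68.0 + (94.0 - 68.0) * 0.5)


@pytest.fixture(scope="module")
def phantom():
    return generate_phantom(rest_config())


class TestGroundTruth:
    def test_flat_hr_cardiac_output(self):
        ph = generate_phantom(rest_config(rr_jitter_sd=0.0, resp_sv_frac=0.0))
        assert ph.truth.beats.co_l_min.mean() == pytest.approx(6.0, rel=1e-6)

    def test_flow_self_consistency(self, phantom):
        q = (
            (phantom.truth.velocity_cm_s * phantom.truth.masks).sum(axis=(1, 2))
            * phantom.truth.pixel_area_mm2
            * 0.01
        )
        ref = np.abs(phantom.truth.flow_ml_s).max()
        assert np.max(np.abs(q - phantom.truth.flow_ml_s)) <= 1e-9 * ref

    def test_parabolic_profile_matches_analytic_flow(self, phantom):
        """Discretized flow vs pi R^2 v_peak / 2 at the systolic peak."""
        i = int(np.argmax(phantom.truth.flow_ml_s))
        v_centre = phantom.truth.velocity_cm_s[i].max()
        analytic = 0.5 * v_centre * np.pi * phantom.config.vessel_radius_mm**2 * 0.01
        assert phantom.truth.flow_ml_s[i] == pytest.approx(analytic, rel=0.05)

    def test_stroke_volume_recovered_from_flow_curve(self, phantom):
        t = (np.arange(len(phantom.truth.flow_ml_s)) + 0.5) * phantom.config.frame_ms
        beats = phantom.truth.beats
        svs = []
        for i in range(1, len(beats) - 1):
            sel = (t >= beats.onset_ms[i]) & (t < beats.onset_ms[i] + beats.rr_ms[i])
            svs.append(np.trapezoid(phantom.truth.flow_ml_s[sel], t[sel]) / 1000.0)
        assert np.mean(svs) == pytest.approx(80.0, rel=0.05)

    def test_deterministic_under_seed(self):
        a = generate_phantom(rest_config(seed=42))
        b = generate_phantom(rest_config(seed=42))
        assert np.array_equal(a.magnitude, b.magnitude)
        assert np.array_equal(a.velocity_cm_s, b.velocity_cm_s)
        assert a.truth.beats.equals(b.truth.beats)

    def test_masks_static_without_motion(self):
        ph = generate_phantom(rest_config(motion_amp_px=0.0, rr_jitter_sd=0.0, duration_s=5.0))
        assert np.all(ph.truth.masks == ph.truth.masks[0])

    def test_background_phase_bounded(self, phantom):
        assert np.abs(np.asarray(phantom.phi0)).max() <= phantom.config.phi0_amp_rad + 1e-9


@pytest.mark.parametrize(
    "kw",
    [
        dict(vessel_radius_mm=-1.0),
        dict(resp_sv_frac=0.7),
        dict(hr_bpm=300.0),
        dict(vessel_center=(2.0, 2.0), vessel_radius_mm=15.0),
    ],
)
def test_invalid_configs_rejected(kw):
    with pytest.raises(ValueError):
        rest_config(**kw)
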