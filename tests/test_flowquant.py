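"""Flow curves, beat detection, and stroke-volume/cardiac-output math."""

import numpy as np
import pytest

from fresco.flowquant import FlowCurve, beat_metrics, detect_beats, flow_curve, smooth_display
from fresco.phantom import flow_waveform


def synthetic_curve(n_beats=10, rr_ms=800.0, dt_ms=35.0, v_peak=100.0, area_mm2=441.0):
    """Noise-free flow curve built from the phantom waveform."""
    total_ms = n_beats * rr_ms
    t = np.arange(dt_ms / 2, total_ms, dt_ms)
    frac = (t % rr_ms) / rr_ms
    q = flow_waveform(frac, v_peak) * area_mm2 * 0.01
    return FlowCurve(t_ms=t, q_ml_s=q)


class TestFlowCurve:
    def test_uniform_velocity_value(self):
        """100 cm/s over 100 pixels of 2.1 mm squared is 441 mL/s."""
        v = np.zeros((1, 20, 20))
        m = np.zeros((1, 20, 20), dtype=bool)
        m[0, :10, :10] = True
        v[0, :10, :10] = 100.0
        fc = flow_curve(v, m, pixel_area_mm2=2.1**2)
        assert fc.q_ml_s[0] == pytest.approx(441.0, rel=1e-12)

    def test_zero_velocity_zero_flow(self):
        fc = flow_curve(np.zeros((3, 8, 8)), np.ones((3, 8, 8), dtype=bool), 4.41)
        assert np.all(fc.q_ml_s == 0.0)

    def test_parabolic_profile_matches_analytic(self):
        """pi R^2 v_peak / 2 for a discretized parabola, R = 15 mm."""
        R_mm, vox = 15.0, 1.0
        N = 64
        yy, xx = np.mgrid[0:N, 0:N]
        r2 = ((yy - N / 2) ** 2 + (xx - N / 2) ** 2) * vox**2
        mask = r2 <= R_mm**2
        v = np.where(mask, 120.0 * (1.0 - r2 / R_mm**2), 0.0)
        fc = flow_curve(v[None], mask[None], pixel_area_mm2=vox**2)
        analytic = 0.5 * 120.0 * np.pi * R_mm**2 * 0.01  # 424.1 mL/s
        assert analytic == pytest.approx(424.1, abs=0.1)
        assert fc.q_ml_s[0] == pytest.approx(analytic, rel=0.05)

    def test_empty_mask_warns_and_zeroes(self):
        v = np.ones((2, 4, 4))
        m = np.zeros((2, 4, 4), dtype=bool)
        m[0, 0, 0] = True
        with pytest.warns(UserWarning, match="empty mask"):
            fc = flow_curve(v, m, 1.0)
        assert fc.q_ml_s[1] == 0.0

    def test_unit_chain_has_no_hidden_factors(self):
        """cm/s x mm^2 -> mL/s and mL x bpm -> L/min with unit constants."""
        v = np.full((1, 1, 1), 1.0)  # 1 cm/s
        fc = flow_curve(v, np.ones((1, 1, 1), dtype=bool), 1.0)  # 1 mm^2
        assert fc.q_ml_s[0] == pytest.approx(0.01)  # 10 mm^3/s
        curve = FlowCurve(t_ms=np.array([0.0, 500.0, 1000.0]), q_ml_s=np.array([80.0, 80.0, 80.0]))
        beats = beat_metrics(curve, np.array([0, 2]))
        assert beats.sv_ml[0] == pytest.approx(80.0)  # 80 mL/s for 1 s
        assert beats.hr_bpm[0] == pytest.approx(60.0)
        assert beats.co_l_min[0] == pytest.approx(80.0 * 60.0 / 1000.0)


class TestDetectBeats:
    def test_ten_clean_beats_give_nine_intervals(self):
        curve = synthetic_curve(n_beats=10)
        peaks = detect_beats(curve)
        assert len(peaks) == 10
        assert len(beat_metrics(curve, peaks)) == 9

    def test_constant_curve_has_no_peaks(self):
        curve = FlowCurve(t_ms=np.arange(0, 3000, 35.0), q_ml_s=np.full(86, 5.0))
        assert len(detect_beats(curve)) == 0

    def test_detection_invariant_to_amplitude(self):
        curve = synthetic_curve()
        doubled = FlowCurve(t_ms=curve.t_ms, q_ml_s=2.0 * curve.q_ml_s)
        assert np.array_equal(detect_beats(curve), detect_beats(doubled))

    def test_too_short_curve_rejected(self):
        short = FlowCurve(t_ms=np.arange(0, 1000, 35.0), q_ml_s=np.zeros(29))
        with pytest.raises(ValueError, match="2 s"):
            detect_beats(short)


class TestBeatMetrics:
    def test_rate_arithmetic(self):
        curve = synthetic_curve(n_beats=4, rr_ms=800.0)
        peaks = detect_beats(curve)
        beats = beat_metrics(curve, peaks)
        assert beats.hr_bpm.mean() == pytest.approx(75.0, rel=0.02)
        assert np.allclose(beats.co_l_min, beats.sv_ml * beats.hr_bpm / 1000.0)

    def test_volume_conserved_across_beat_boundaries(self):
        curve = synthetic_curve(n_beats=8)
        peaks = detect_beats(curve)
        beats = beat_metrics(curve, peaks)
        t_s = curve.t_ms / 1000.0
        a, b = peaks[0], peaks[-1]
        total = np.trapezoid(curve.q_ml_s[a : b + 1], t_s[a : b + 1])
        assert beats.sv_ml.sum() == pytest.approx(total, rel=1e-9)

    def test_fewer_than_two_peaks_gives_empty_table(self):
        curve = synthetic_curve(n_beats=4)
        assert len(beat_metrics(curve, np.array([3]))) == 0

    def test_phantom_truth_beats_recovered_within_two_percent(self):
        """Noise-free truth flow through detect/metrics vs the generator's
        own beat table."""
        from fresco.phantom import PhantomConfig, generate_phantom

        ph = generate_phantom(
            PhantomConfig(
                grid=64, duration_s=20.0, hr_bpm=75.0, hr_ramp=(21.0, 22.0, 75.0),
                sv_ml=80.0, sv_peak_ml=80.0, resp_sv_frac=0.0, rr_jitter_sd=0.0,
                motion_amp_px=0.0, seed=2,
            )
        )
        curve = flow_curve(
            ph.truth.velocity_cm_s, ph.truth.masks, ph.truth.pixel_area_mm2, ph.config.frame_ms
        )
        beats = beat_metrics(curve, detect_beats(curve))
        gt = ph.truth.beats
        assert beats.co_l_min.mean() == pytest.approx(gt.co_l_min.mean(), rel=0.02)
        # per-beat agreement is limited by the 35 ms frame quantization of
        # the peak-to-peak boundaries (about one frame on an 800 ms beat)
        inner = beats.iloc[1:-1]
        assert np.all(np.abs(inner.co_l_min - gt.co_l_min.mean()) / gt.co_l_min.mean() < 0.12)


class TestSmoothDisplay:
    def test_constant_unchanged(self):
        x = np.full(10, 3.0)
        assert np.array_equal(smooth_display(x, 5), x)

    def test_single_outlier_removed(self):
        x = np.full(11, 2.0)
        x[5] = 50.0
        assert smooth_display(x, 5)[5] == 2.0

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=8)
        assert np.array_equal(smooth_display(x, 1), x)
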