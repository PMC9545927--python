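"""Spiral design, golden-angle schedule, and acceleration audit."""

import numpy as np
import pytest
from scipy.integrate import quad

from fresco.trajectory import (
    AcquisitionParams,
    DensitySpec,
    InvalidSpecError,
    acceleration_audit,
    design_vd_arm,
    frame_trajectory,
    golden_angle_schedule,
    load_trajectories,
    save_trajectories,
)

PARAMS = AcquisitionParams()
SPEC = DensitySpec()


def expected_turns(params, spec):
    """Independent quadrature of the pitch ODE: turns = FOV k_max int d rho / R."""
    val, _ = quad(lambda r: 1.0 / spec.accel(r), 0.0, 1.0, points=[spec.r_inner_frac, spec.r_outer_frac])
    return params.fov_mm * params.k_max * val


class TestDesign:
    def test_total_turns_match_quadrature(self):
        arm = design_vd_arm(PARAMS, SPEC, 2048)
        assert arm.turns == pytest.approx(expected_turns(PARAMS, SPEC), rel=1e-4)
        # the printed design makes about two and a half turns
        assert arm.turns == pytest.approx(2.45, abs=0.01)

    def test_uniform_spec_is_archimedean(self):
        spec = DensitySpec(arm_accel_inner=26.0, arm_accel_outer=26.0)
        arm = design_vd_arm(PARAMS, spec, 2048)
        audit = acceleration_audit(arm, PARAMS, spec=spec)
        assert audit["per_arm_inner"] == pytest.approx(26.0, rel=1e-3)
        assert audit["per_arm_outer"] == pytest.approx(26.0, rel=1e-3)

    def test_max_radius_is_k_max(self):
        arm = design_vd_arm(PARAMS, SPEC, 1024)
        r = np.hypot(arm.k_coords[:, 0], arm.k_coords[:, 1])
        assert r.max() == pytest.approx(1.0 / (2.0 * 2.1), rel=1e-9)
        assert np.allclose(arm.k_coords[0], 0.0)
        assert np.all(np.diff(r) > -1e-12)  # radius monotone non-decreasing

    @pytest.mark.parametrize(
        "kw",
        [
            dict(r_inner_frac=0.9, r_outer_frac=0.2),
            dict(arm_accel_inner=-3.0),
            dict(arm_accel_inner=65.0, arm_accel_outer=26.0),
            dict(transition="cubic"),
        ],
    )
    def test_invalid_density_specs_rejected(self, kw):
        with pytest.raises(InvalidSpecError):
            DensitySpec(**kw)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            design_vd_arm(PARAMS, SPEC, 32)


class TestGoldenAngle:
    def test_first_angles(self):
        ang = golden_angle_schedule(3)
        assert ang[0] == 0.0
        assert ang[1] == pytest.approx(2.0 * np.pi * (1.0 - 2.0 / (1.0 + np.sqrt(5.0))), rel=1e-12)
        assert ang[1] == pytest.approx(2.39996, abs=1e-5)

    def test_no_exact_repeats_over_100_arms(self):
        ang = golden_angle_schedule(100)
        assert len(np.unique(np.round(ang, 12))) == 100

    def test_schedule_stateless_prefix(self):
        a, b = golden_angle_schedule(40), golden_angle_schedule(100)
        assert np.array_equal(a, b[:40])

    def test_frames_continue_sequence(self):
        arm = design_vd_arm(PARAMS, SPEC, 256)
        t1 = frame_trajectory(arm, 1, PARAMS)
        sched = golden_angle_schedule(6)
        assert np.allclose(t1.arm_angles, sched[3:6])


@pytest.fixture(scope="module")
def audit():
    arm = design_vd_arm(PARAMS, SPEC, 2048)
    return acceleration_audit(arm, PARAMS, spec=SPEC)


class TestAudit:
    def test_per_arm_plateaus(self, audit):
        assert audit["per_arm_inner"] == pytest.approx(26.0, rel=0.05)
        assert audit["per_arm_outer"] == pytest.approx(65.0, rel=0.05)

    def test_per_frame_accelerations(self, audit):
        assert audit["per_frame_inner"] == pytest.approx(8.7, rel=0.05)
        assert audit["per_frame_outer"] == pytest.approx(21.7, rel=0.05)

    def test_density_ratio(self, audit):
        assert audit["density_ratio"] == pytest.approx(2.5, rel=0.05)

    def test_uniform_three_arm_frame(self):
        spec = DensitySpec(arm_accel_inner=9.0, arm_accel_outer=9.0)
        arm = design_vd_arm(PARAMS, spec, 1024)
        audit = acceleration_audit(arm, PARAMS, arms_per_frame=3, spec=spec)
        assert audit["per_frame_inner"] == pytest.approx(3.0, rel=0.01)
        assert audit["per_frame_outer"] == pytest.approx(3.0, rel=0.01)

    def test_denser_sampling_tightens_audit(self):
        arm = design_vd_arm(PARAMS, SPEC, 4096)
        audit = acceleration_audit(arm, PARAMS, spec=SPEC)
        assert audit["per_arm_inner"] == pytest.approx(26.0, rel=0.02)


def test_trajectory_hdf5_roundtrip(tmp_path):
    from fresco.trajectory import density_compensation

    arm = design_vd_arm(PARAMS, SPEC, 256)
    trajs = [frame_trajectory(arm, i, PARAMS) for i in range(2)]
    dcf = density_compensation(trajs[0], PARAMS, calibrate_gain=False)
    path = tmp_path / "traj.h5"
    save_trajectories(path, trajs, [dcf, dcf], PARAMS)
    loaded, dcfs, attrs = load_trajectories(path)
    assert len(loaded) == 2
    assert np.allclose(loaded[1].k_coords, trajs[1].k_coords)
    assert np.allclose(dcfs[0].weights, dcf.weights)
    assert attrs["fov_mm"] == PARAMS.fov_mm
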