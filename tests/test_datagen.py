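"""Synthetic undersampling, augmentation and block assembly."""

import numpy as np
import pytest

from fresco.containers import CineSeries
from fresco.datagen import (
    TrainingPair,
    augment_pair,
    draw_transform,
    make_blocks,
    split_ids,
    synth_undersample,
)
from fresco.eval_stats import image_metrics
from fresco.phantom import PhantomConfig, generate_phantom
from fresco.trajectory import (
    AcquisitionParams,
    DensitySpec,
    density_compensation,
    design_vd_arm,
    frame_trajectory,
)
from fresco.training import desk_acquisition


def _aliasing_setup(spec, n_samples, n_frames=4, arms=3):
    base = desk_acquisition(48)
    params = AcquisitionParams(fov_mm=base.fov_mm, voxel_mm=base.voxel_mm, arms_per_frame=arms)
    arm = design_vd_arm(params, spec, n_samples)
    trajs = [frame_trajectory(arm, i, params) for i in range(n_frames)]
    dcf = density_compensation(trajs[0], params)
    return params, trajs, [dcf] * n_frames


def _phantom_cine(n_frames=4, grid=48):
    ph = generate_phantom(
        PhantomConfig(
            grid=grid,
            duration_s=n_frames * 0.035,
            hr_bpm=75.0,
            hr_ramp=(5.0, 6.0, 75.0),
            vessel_radius_mm=12.0,
            seed=5,
        )
    )
    return ph.pc_cine()


def _mag_ssim(a, b):
    am, bm = np.abs(a), np.abs(b)
    top = max(am.max(), bm.max())
    return image_metrics(am / top, bm / top)["ssim"]


class TestSynthUndersample:
    def test_nyquist_dense_trajectory_is_near_identity(self):
        """A 2x-oversampled spiral reproduces the disk-band-limited input
        (the spiral never samples the corner frequencies of k-space, so
        the comparison is against the disk-limited reference)."""
        params, trajs, dcfs = _aliasing_setup(
            DensitySpec(arm_accel_inner=0.5, arm_accel_outer=0.5), 36000, arms=1
        )
        cine = _phantom_cine()
        N = cine.shape[0]
        spec_f = np.fft.fftshift(
            np.fft.fft2(np.fft.ifftshift(cine.frames, axes=(1, 2))), axes=(1, 2)
        )
        ky = (np.arange(N) - N // 2) / N
        disk = (ky[:, None] ** 2 + ky[None, :] ** 2) <= 0.25
        ref = np.fft.fftshift(
            np.fft.ifft2(np.fft.ifftshift(spec_f * disk, axes=(1, 2))), axes=(1, 2)
        )
        out = synth_undersample(cine, trajs, dcfs, params)
        assert _mag_ssim(out.frames, ref) >= 0.98

    def test_printed_design_visibly_aliases(self):
        params, trajs, dcfs = _aliasing_setup(DensitySpec(), 512)
        cine = _phantom_cine()
        out = synth_undersample(cine, trajs, dcfs, params)
        assert _mag_ssim(out.frames, cine.frames) < 0.95

    def test_zero_image_stays_zero(self):
        params, trajs, dcfs = _aliasing_setup(DensitySpec(), 256)
        cine = CineSeries(np.zeros((4, 48, 48), dtype=complex), 2.1, 35.0, 200.0)
        out = synth_undersample(cine, trajs, dcfs, params)
        assert np.allclose(out.frames, 0.0)

    def test_frame_count_mismatch_rejected(self):
        params, trajs, dcfs = _aliasing_setup(DensitySpec(), 256)
        cine = CineSeries(np.zeros((7, 48, 48), dtype=complex), 2.1, 35.0, 200.0)
        with pytest.raises(ValueError):
            synth_undersample(cine, trajs, dcfs, params)


class TestAugment:
    def _pair(self, rng):
        c = rng.normal(size=(6, 16, 16)) + 1j * rng.normal(size=(6, 16, 16))
        t = rng.normal(size=(6, 16, 16)) + 1j * rng.normal(size=(6, 16, 16))
        m = rng.uniform(size=(6, 16, 16)) > 0.7
        return TrainingPair(corrupted=c, truth=t, masks=m, pc_truth=t.copy())

    def test_double_horizontal_flip_identity(self, rng):
        x = rng.normal(size=(3, 8, 8)) + 0j
        assert np.array_equal(x[:, :, ::-1][:, :, ::-1], x)

    def test_phase_offset_preserves_magnitudes(self, rng):
        pair = self._pair(rng)
        out = augment_pair(pair, np.random.default_rng(2), p_translate=0.0)
        assert np.allclose(np.sort(np.abs(out.truth).ravel()), np.sort(np.abs(pair.truth).ravel()), atol=1e-9)

    def test_translation_frequency_is_half(self):
        rng = np.random.default_rng(7)
        n = 10_000
        hits = sum(
            draw_transform((8, 8), 4, rng, p_translate=0.5)["drift"] is not None
            for _ in range(n)
        )
        assert abs(hits / n - 0.5) <= 0.02

    def test_same_geometry_applied_to_both_members_and_masks(self, rng):
        """Transform a coordinate tag through corrupted/truth/masks and
        check they stay aligned (augmentations commute with pairing)."""
        tag = np.zeros((6, 16, 16))
        tag[:, 3, 5] = 1.0
        pair = TrainingPair(
            corrupted=tag.astype(complex),
            truth=tag.astype(complex),
            masks=tag > 0.5,
            pc_truth=tag.astype(complex),
        )
        out = augment_pair(pair, np.random.default_rng(5), p_translate=1.0)
        assert np.allclose(np.abs(out.corrupted), np.abs(out.truth), atol=1e-9)
        got = np.abs(out.truth) >= 0.5
        assert np.array_equal(got, out.masks)


class TestBlocks:
    def test_48_frames_give_two_blocks(self):
        series = np.arange(48 * 9 * 9).reshape(48, 9, 9).astype(complex)
        blocks = make_blocks(series, block=24, crop=8)
        assert len(blocks) == 2
        assert blocks[0].shape == (24, 8, 8)

    def test_short_series_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="shorter than block"):
            blocks = make_blocks(np.zeros((23, 8, 8), dtype=complex), block=24, crop=8)
        assert blocks == []

    def test_center_crop_indices(self):
        series = np.zeros((24, 192, 192), dtype=complex)
        series[:, 32, 32] = 1.0
        series[:, 159, 159] = 2.0
        series[:, 31, 100] = 3.0  # outside the crop
        blocks = make_blocks(series, block=24, crop=128)
        b = blocks[0]
        assert b[0, 0, 0] == 1.0 and b[0, 127, 127] == 2.0
        assert not np.any(np.abs(b) == 3.0)


def test_split_ids_disjoint_and_proportional():
    tr, va, te = split_ids(range(516), fractions=(470, 30, 16), seed=1)
    assert len(tr) + len(va) + len(te) == 516
    assert len(va) == 30 and len(te) == 16
    assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))
    tr2, _, _ = split_ids(range(516), fractions=(470, 30, 16), seed=1)
    assert tr == tr2
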