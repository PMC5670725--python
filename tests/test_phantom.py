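"""Digital phantom rasterization, phase binning and free-breathing scans."""

import math

import numpy as np
import pytest

from itvsim import (
    AcquisitionConfig,
    MotionTrajectory,
    PhantomSpec,
    ScanModel,
    generate_virtual_patient,
    rasterize_phantom,
    segment_gtv,
    simulate_free_breathing,
    simulate_phase_stack,
)

SPHERE_CC = 4.0 / 3.0 * math.pi * 1.5**3  # 14.137


class TestRasterization:
    def test_static_sphere_volume_matches_analytic(self, static_spec, static_image):
        mask = static_image.values >= -350.0
        vol = mask.sum() * static_image.voxel_volume_cc
        assert vol == pytest.approx(SPHERE_CC, rel=0.02)

    def test_volume_converges_with_resolution(self):
        spec = PhantomSpec(
            grid_spacing=(0.05, 0.05, 0.05),
            grid_extent=(75, 75, 75),
        )
        img = rasterize_phantom(spec)
        vol = (img.values >= -350.0).sum() * img.voxel_volume_cc
        assert vol == pytest.approx(SPHERE_CC, rel=0.01)

    def test_translation_equivariance(self):
        # 2 cm displacement on a 0.1 cm isotropic grid is exactly 20 voxels.
        spec = PhantomSpec(grid_spacing=(0.1, 0.1, 0.1), grid_extent=(41, 41, 101))
        a = rasterize_phantom(spec, (0.0, 0.0, 0.0))
        b = rasterize_phantom(spec, (0.0, 0.0, 2.0))
        assert np.array_equal(np.roll(a.values, 20, axis=2), b.values)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError, match="target_radius"):
            PhantomSpec(target_radius=0.0)

    def test_target_outside_grid_names_displacement(self, static_spec):
        with pytest.raises(ValueError, match=r"\(0.0, 0.0, 5.0\)"):
            rasterize_phantom(static_spec, (0.0, 0.0, 5.0))

    def test_partial_volume_preserves_volume_at_half_threshold(self, static_spec):
        img = rasterize_phantom(static_spec, partial_volume=True)
        vol = (img.values >= -350.0).sum() * img.voxel_volume_cc
        assert vol == pytest.approx(SPHERE_CC, rel=0.02)


class TestTrajectory:
    def test_cosine_position(self):
        traj = MotionTrajectory(amplitude_si=1.5, period=4.0)
        assert traj.displacement(0.0)[2] == pytest.approx(1.5)
        assert traj.displacement(2.0)[2] == pytest.approx(-1.5)
        assert traj.displacement(1.0)[2] == pytest.approx(0.0, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            MotionTrajectory(period=0.0)
        with pytest.raises(ValueError):
            MotionTrajectory(amplitude_si=-1.0)

    def test_jitter_reproducible_and_seed_sensitive(self):
        base = dict(amplitude_si=1.0, period_jitter_sd=0.3, amplitude_jitter_sd=0.1)
        a = MotionTrajectory(**base, seed=7)
        b = MotionTrajectory(**base, seed=7)
        c = MotionTrajectory(**base, seed=8)
        ts = np.linspace(0.0, 20.0, 50)
        za = [a.displacement(t)[2] for t in ts]
        zb = [b.displacement(t)[2] for t in ts]
        zc = [c.displacement(t)[2] for t in ts]
        assert za == zb
        assert za != zc


class TestPhaseStack:
    def test_zero_amplitude_all_phases_static(self, static_spec, static_image):
        stack = simulate_phase_stack(
            static_spec, MotionTrajectory(amplitude_si=0.0), AcquisitionConfig()
        )
        assert len(stack) == 10
        for phase in stack:
            assert np.array_equal(phase.values, static_image.values)

    @pytest.mark.parametrize("amplitude", [0.5, 1.0])
    def test_extreme_phase_centroids_at_amplitude(self, amplitude):
        traj = MotionTrajectory(amplitude_si=amplitude)
        spec = PhantomSpec.for_motion(traj)
        stack = simulate_phase_stack(spec, traj, AcquisitionConfig())
        half_voxel = spec.grid_spacing[2] / 2
        z0 = segment_gtv(stack.phase_by_label("0%")).centroid_cm()[2]
        z50 = segment_gtv(stack.phase_by_label("50%")).centroid_cm()[2]
        assert abs(z0 - amplitude) < half_voxel
        assert abs(z50 + amplitude) < half_voxel

    def test_intra_bin_blur_bounded(self):
        # The 50%-threshold target in the extreme bin may exceed the static
        # 3 cm SI extent by at most the intra-bin excursion A(1 - cos(pi/10)).
        traj = MotionTrajectory(amplitude_si=2.0)
        spec = PhantomSpec.for_motion(traj)
        stack = simulate_phase_stack(spec, traj, AcquisitionConfig())
        extent = segment_gtv(stack.phase_by_label("0%")).extent_cm(2)
        bound = 2.0 * (1.0 - math.cos(math.pi / 10.0))
        sz = spec.grid_spacing[2]
        assert 3.0 - sz <= extent <= 3.0 + bound + sz

    def test_bin_center_mode_is_sharp(self):
        traj = MotionTrajectory(amplitude_si=1.0)
        spec = PhantomSpec.for_motion(traj)
        stack = simulate_phase_stack(spec, traj, AcquisitionConfig(mode="center"))
        # single-snapshot bins are binary images
        assert set(np.unique(stack[0].values)) == {-700.0, 0.0}

    def test_nonstandard_bin_count_warns(self):
        with pytest.warns(UserWarning, match="10 phase bins"):
            AcquisitionConfig(n_bins=8)


class TestFreeBreathing:
    def test_zero_amplitude_equals_static(self, static_spec, static_image):
        fb = simulate_free_breathing(
            static_spec, MotionTrajectory(amplitude_si=0.0), ScanModel()
        )
        assert np.array_equal(fb.values, static_image.values)

    def test_interplay_truncates_fast_target(self):
        traj = MotionTrajectory(amplitude_si=2.0)
        spec = PhantomSpec.for_motion(traj)
        fb = simulate_free_breathing(spec, traj, ScanModel())
        gtv = segment_gtv(fb)
        assert 0 < gtv.volume_cc < SPHERE_CC

    def test_invalid_couch_speed_rejected(self):
        with pytest.raises(ValueError, match="couch speed"):
            ScanModel(slab_time_s=0.0)
        with pytest.raises(ValueError, match="couch speed"):
            ScanModel(slab_thickness_cm=-1.0)


class TestVirtualPatient:
    def test_pythagorean_ground_truth_motion_vector(self):
        traj = MotionTrajectory(
            amplitude_si=1.2, lateral_amplitude=0.3, ap_amplitude=0.4
        )
        vp = generate_virtual_patient(3, traj)
        assert vp.ground_truth_m == pytest.approx(1.3)
        hi, lo = vp.centroid_extrema
        assert hi == pytest.approx((0.3, 0.4, 1.2))
        assert lo == pytest.approx((-0.3, -0.4, -1.2))

    def test_reproducible_without_jitter(self):
        traj = MotionTrajectory(amplitude_si=0.8, lateral_amplitude=0.2)
        a = generate_virtual_patient(11, traj)
        b = generate_virtual_patient(11, traj)
        for pa, pb in zip(a.stack, b.stack):
            assert np.array_equal(pa.values, pb.values)
        assert np.array_equal(a.free_breathing.values, b.free_breathing.values)

    def test_pure_si_motion_matches_phase_stack(self):
        traj = MotionTrajectory(amplitude_si=0.6)
        vp = generate_virtual_patient(5, traj)
        spec = PhantomSpec.for_motion(traj)
        ref = simulate_phase_stack(spec, traj, AcquisitionConfig())
        for pa, pb in zip(vp.stack, ref):
            assert np.array_equal(pa.values, pb.values)

    def test_motionless_trajectory_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            generate_virtual_patient(1, MotionTrajectory(amplitude_si=0.0))
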