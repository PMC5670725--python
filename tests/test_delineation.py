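"""Segmentation, Boolean ITV construction and margin expansion."""

import numpy as np
import pytest

from itvsim import (
    EmptyMaskWarning,
    ImageVolume,
    MarginSpec,
    MotionTrajectory,
    PhantomSpec,
    ScanModel,
    Strategy,
    StructureMask,
    build_itv_fb_aug,
    build_itv_gold,
    capsule_volume,
    expand_margin,
    run_strategy,
    segment_gtv,
    simulate_free_breathing,
)
from itvsim.delineation import FB_MARGIN, ITV_MARGIN

SPHERE_CC = capsule_volume(1.5, 0.0)


class TestSegmentation:
    def test_static_sphere_volume(self, static_image):
        gtv = segment_gtv(static_image)
        assert gtv.volume_cc == pytest.approx(SPHERE_CC, rel=0.02)

    def test_uniform_image_yields_empty_mask_with_warning(self, static_spec):
        flat = ImageVolume(
            np.full(static_spec.grid_extent, -700.0),
            static_spec.grid_spacing,
        )
        with pytest.warns(EmptyMaskWarning):
            gtv = segment_gtv(flat)
        assert gtv.volume_cc == 0.0

    def test_largest_component_kept(self):
        values = np.full((30, 10, 10), -700.0)
        values[2:8, 2:8, 2:8] = 0.0  # 216 voxels
        values[20:23, 2:5, 2:5] = 0.0  # 27 voxels
        img = ImageVolume(values, (0.1, 0.1, 0.1))
        gtv = segment_gtv(img)
        assert gtv.mask[4, 4, 4]
        assert not gtv.mask[21, 3, 3]
        assert int(gtv.mask.sum()) == 216

    def test_absolute_threshold(self, static_image):
        rel = segment_gtv(static_image)
        abs_ = segment_gtv(static_image, absolute_threshold=-350.0)
        assert np.array_equal(rel.mask, abs_.mask)


class TestBooleanItv:
    def test_gold_requires_ten_phases(self, static_image):
        gtv = segment_gtv(static_image)
        with pytest.raises(ValueError, match="10"):
            build_itv_gold([gtv] * 9)

    def test_union_of_identical_masks_is_identity(self, static_image):
        gtv = segment_gtv(static_image)
        itv = build_itv_gold([gtv] * 10)
        assert np.array_equal(itv.mask, gtv.mask)
        assert itv.label == "ITV"

    def test_union_dominates_each_phase(self, stack_a10):
        gtvs = [segment_gtv(p) for p in stack_a10]
        itv = build_itv_gold(gtvs)
        assert itv.volume_cc >= max(g.volume_cc for g in gtvs)
        for g in gtvs:
            assert np.all(itv.mask >= g.mask)

    def test_itv_matches_capsule_oracle(self, stack_a10):
        # SI-swept sphere: analytic spherocylinder with L = peak-to-peak range
        itv = build_itv_gold([segment_gtv(p) for p in stack_a10])
        assert itv.volume_cc == pytest.approx(capsule_volume(1.5, 2.0), rel=0.05)

    def test_fb_aug_union_properties(self, static_image):
        gtv = segment_gtv(static_image)
        empty = StructureMask(
            np.zeros(gtv.shape, bool), gtv.spacing, gtv.origin
        )
        itv = build_itv_fb_aug(empty, gtv, gtv)
        assert np.array_equal(itv.mask, gtv.mask)
        for part in (empty, gtv):
            assert np.all(itv.mask >= part.mask)


class TestMarginExpansion:
    def test_sphere_grows_to_analytic_volume(self, static_image):
        ptv = expand_margin(segment_gtv(static_image), ITV_MARGIN)
        assert ptv.volume_cc == pytest.approx(capsule_volume(2.0, 0.0), rel=0.03)

    def test_zero_margin_is_identity(self, static_image):
        gtv = segment_gtv(static_image)
        out = expand_margin(gtv, MarginSpec(0.0, 0.0))
        assert np.array_equal(out.mask, gtv.mask)

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            MarginSpec(-1.0, 5.0)

    def test_single_voxel_anisotropic_extents(self):
        mask = np.zeros((41, 41, 41), bool)
        mask[20, 20, 20] = True
        sv = StructureMask(mask, (0.1, 0.1, 0.125))
        grown = expand_margin(sv, FB_MARGIN)
        assert grown.extent_cm(2) == pytest.approx(2.0, abs=0.2)
        assert grown.extent_cm(0) == pytest.approx(1.0, abs=0.15)

    def test_dilation_monotone_in_margin(self, static_image):
        gtv = segment_gtv(static_image)
        small = expand_margin(gtv, MarginSpec.iso(3.0))
        large = expand_margin(gtv, MarginSpec.iso(6.0))
        assert np.all(large.mask >= small.mask)
        assert np.all(small.mask >= gtv.mask)

    def test_dilation_covers_union_of_dilations(self, stack_a10):
        a = segment_gtv(stack_a10.phase_by_label("0%"))
        b = segment_gtv(stack_a10.phase_by_label("50%"))
        union = StructureMask(a.mask | b.mask, a.spacing, a.origin)
        both = expand_margin(union, ITV_MARGIN)
        separate = expand_margin(a, ITV_MARGIN).mask | expand_margin(b, ITV_MARGIN).mask
        assert np.all(both.mask >= separate)
        # near-distributivity: any excess is confined to the contact region
        excess = int(both.mask.sum() - separate.sum())
        assert excess <= 0.01 * separate.sum()


class TestStrategies:
    def test_missing_input_named(self, stack_a10):
        with pytest.raises(ValueError, match="fb_image"):
            run_strategy(Strategy.FB)
        with pytest.raises(ValueError, match="mip"):
            run_strategy(Strategy.MIP)
        with pytest.raises(ValueError, match="stack"):
            run_strategy(Strategy.GS)

    def test_fb_margin_rule_on_static_image(self, static_spec, static_image):
        fb = simulate_free_breathing(
            static_spec, MotionTrajectory(amplitude_si=0.0), ScanModel()
        )
        gtv = segment_gtv(fb)
        ptv = run_strategy(Strategy.FB, fb_image=fb)
        sz = static_spec.grid_spacing[2]
        assert ptv.extent_cm(2) == pytest.approx(gtv.extent_cm(2) + 2.0, abs=2 * sz)
        sx = static_spec.grid_spacing[0]
        assert ptv.extent_cm(0) == pytest.approx(gtv.extent_cm(0) + 1.0, abs=2 * sx)

    def test_gold_standard_matches_grown_capsule(self, stack_a10):
        ptv = run_strategy(Strategy.GS, stack=stack_a10)
        assert ptv.volume_cc == pytest.approx(capsule_volume(2.0, 2.0), rel=0.05)
        assert ptv.strategy is Strategy.GS
        assert ptv.label == "PTV"

    def test_gs_itv_volume_nondecreasing_in_amplitude(self):
        from itvsim import AcquisitionConfig, simulate_phase_stack

        vols = []
        for amp in (0.5, 1.0, 1.5, 2.0):
            traj = MotionTrajectory(amplitude_si=amp)
            spec = PhantomSpec.for_motion(traj, spacing=(0.2, 0.2, 0.25))
            stack = simulate_phase_stack(spec, traj, AcquisitionConfig(samples_per_bin=4))
            itv = build_itv_gold([segment_gtv(p) for p in stack])
            vols.append(itv.volume_cc)
        assert vols == sorted(vols)
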