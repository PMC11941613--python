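"""Shape descriptors against analytic oracles, plus the composed
per-NMJ measurement on synthetic stacks."""

import numpy as np
import pytest

from nmjmorph import (
    BinaryMask2D,
    BinaryVolume,
    END_PLATE,
    FULLY_DENERVATED,
    INNERVATED,
    ImageStack,
    MorphometryConfig,
    PARTIALLY_DENERVATED,
    PRE_SYNAPTIC,
    apposition_percent,
    classify_denervation,
    max_intensity_projection,
    measure_nmj,
    orthogonal_axes_area,
    planar_area,
    relative_planar_area,
)


def _mask2d(mask):
    return BinaryMask2D(mask, pixel_size=(0.5, 0.5))


def _rect(rows=20, cols=30, pad=10):
    m = np.zeros((rows + 2 * pad, cols + 2 * pad), bool)
    m[pad : pad + rows, pad : pad + cols] = True
    return m


class TestProjection:
    def test_single_slice_projection_is_the_slice(self):
        img = np.random.default_rng(0).integers(0, 4096, (2, 1, 6, 7)).astype(np.uint16)
        stack = ImageStack(voxels=img)
        assert np.array_equal(max_intensity_projection(stack, PRE_SYNAPTIC), img[0, 0])

    def test_projection_dominates_every_slice(self, rendered_nmj):
        _, stack, _ = rendered_nmj
        mip = max_intensity_projection(stack, END_PLATE)
        assert (mip[None] >= stack.channel(END_PLATE)).all()

    def test_noiseless_projection_equals_the_mask_shadow(self, noiseless_nmj):
        _, stack, truth = noiseless_nmj
        mip = max_intensity_projection(stack, END_PLATE)
        assert np.array_equal(mip >= 1500, truth.endplate_mask.any(axis=0))


class TestPlanarArea:
    def test_rectangle_arithmetic(self):
        assert planar_area(_mask2d(_rect())) == pytest.approx(150.0)

    def test_empty_mask_is_zero(self):
        assert planar_area(_mask2d(np.zeros((5, 5), bool))) == 0.0

    def test_filled_disk_matches_the_closed_form(self):
        y, x = np.ogrid[-50:51, -50:51]
        disk = y**2 + x**2 <= 40**2  # r = 40 px = 20 µm
        area = planar_area(_mask2d(disk))
        expected = np.pi * 20.0**2
        assert abs(area - expected) / expected < 0.02


class TestAxesArea:
    def test_axis_aligned_rectangle_is_its_own_axes_box(self):
        m = _mask2d(_rect())
        axes = orthogonal_axes_area(m)
        assert axes == pytest.approx(150.0, rel=1e-6)
        assert relative_planar_area(planar_area(m), axes) == pytest.approx(100.0, rel=1e-6)

    def test_rotation_invariance_up_to_discretization(self):
        # a 15 × 22.5 µm rectangle rotated 45°, via analytic membership;
        # the one-pixel box padding biases rotated shapes upward by at
        # most one pixel width per axis, so the bound tightens with size
        yy, xx = np.mgrid[0:160, 0:160]
        y = (yy - 80) * 0.5
        x = (xx - 80) * 0.5
        c = s = np.sqrt(0.5)
        u, v = c * x + s * y, -s * x + c * y
        rot = (np.abs(u) <= 11.25) & (np.abs(v) <= 7.5)
        axes = orthogonal_axes_area(_mask2d(rot))
        expected = 22.5 * 15.0
        assert abs(axes - expected) / expected < 0.05

    def test_filled_ellipse_matches_the_discretized_closed_form(self):
        # semi-axes 40 × 20 px (20 × 10 µm): the axes box carries the
        # one-pixel-width padding, so the exact ratio is
        # πab / ((2a + px)(2b + px)); it converges to π/4 from below
        y, x = np.ogrid[-30:31, -50:51]
        ell = (y / 20.0) ** 2 + (x / 40.0) ** 2 <= 1.0
        m = _mask2d(ell)
        rpa = relative_planar_area(planar_area(m), orthogonal_axes_area(m))
        closed = 100.0 * np.pi * 20.0 * 10.0 / (40.5 * 20.5)
        assert abs(rpa - closed) < 2.0
        assert rpa < 100.0 * np.pi / 4.0  # padded box always under π/4

    def test_collinear_mask_gets_one_pixel_minor_extent(self):
        line = np.zeros((10, 10), bool)
        line[4, 1:9] = True
        axes = orthogonal_axes_area(_mask2d(line))
        assert axes == pytest.approx((7 * 0.5 + 0.5) * 0.5)

    def test_relative_planar_area_arithmetic(self):
        assert relative_planar_area(75.0, 150.0) == pytest.approx(50.0)
        with pytest.raises(ValueError):
            relative_planar_area(75.0, 0.0)


class TestApposition:
    def _vol(self, mask):
        return BinaryVolume(mask)

    def test_identical_masks_are_fully_apposed(self):
        m = np.random.default_rng(0).random((4, 8, 8)) > 0.5
        assert apposition_percent(self._vol(m), self._vol(m)) == 100.0

    def test_disjoint_masks_have_zero_apposition(self):
        a = np.zeros((4, 8, 8), bool)
        b = np.zeros_like(a)
        a[0, :2], b[3, 6:] = True, True
        assert apposition_percent(self._vol(a), self._vol(b)) == 0.0

    def test_partial_overlap_arithmetic(self):
        pre = np.zeros((5, 10, 10), bool)
        post = np.zeros_like(pre)
        pre.ravel()[:200] = True
        post.ravel()[80:280] = True  # 120 of pre's 200 voxels inside post
        assert apposition_percent(self._vol(pre), self._vol(post)) == pytest.approx(60.0)

    def test_empty_pre_mask_scores_zero(self):
        empty = np.zeros((4, 8, 8), bool)
        full = np.ones_like(empty)
        assert apposition_percent(self._vol(empty), self._vol(full)) == 0.0

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            apposition_percent(
                self._vol(np.zeros((4, 8, 8), bool)), self._vol(np.zeros((4, 8, 9), bool))
            )


class TestClassification:
    def test_covering_projection_is_innervated(self):
        post = _mask2d(_rect())
        pre = _mask2d(post.mask.copy())
        assert classify_denervation(pre, post) == INNERVATED

    def test_empty_pre_projection_is_fully_denervated(self):
        post = _mask2d(_rect())
        assert classify_denervation(_mask2d(np.zeros_like(post.mask)), post) == FULLY_DENERVATED

    def test_half_overlap_is_partial_under_defaults(self):
        post = _mask2d(_rect(rows=20, cols=30))
        pre = np.zeros_like(post.mask)
        pre[10:30, 10:25] = True  # covers half the rectangle
        assert classify_denervation(_mask2d(pre), post) == PARTIALLY_DENERVATED

    def test_boundary_fraction_classifies_upward(self):
        post = np.zeros((10, 10), bool)
        post[0, :5] = True
        pre = np.zeros_like(post)
        pre[0, :4] = True  # f = 0.8 exactly
        assert classify_denervation(_mask2d(pre), _mask2d(post)) == INNERVATED

    @pytest.mark.parametrize(
        "thresholds,expected",
        [((0.10, 0.80), PARTIALLY_DENERVATED), ((0.10, 0.45), INNERVATED), ((0.55, 0.80), FULLY_DENERVATED)],
    )
    def test_threshold_sensitivity_sweep(self, thresholds, expected):
        # f = 0.5: category moves consistently as the cutpoints move
        post = np.zeros((10, 10), bool)
        post[:, :8] = True
        pre = np.zeros_like(post)
        pre[:, :4] = True
        assert classify_denervation(_mask2d(pre), _mask2d(post), thresholds) == expected


class TestMeasureNMJ:
    def test_noiseless_measurement_is_exact(self, noiseless_nmj):
        _, stack, truth = noiseless_nmj
        rec = measure_nmj(stack, nmj_id="exact")
        assert rec.pre_volume == truth.true_pre_volume
        assert rec.endplate_volume == truth.true_endplate_volume
        assert rec.apposition_pct == pytest.approx(truth.true_apposition_pct)

    def test_noisy_measurement_recovers_volumes_and_apposition(self, rendered_nmj):
        _, stack, truth = rendered_nmj
        rec = measure_nmj(stack, nmj_id="noisy")
        assert abs(rec.pre_volume - truth.true_pre_volume) / truth.true_pre_volume < 0.10
        assert (
            abs(rec.endplate_volume - truth.true_endplate_volume) / truth.true_endplate_volume
            < 0.10
        )
        assert abs(rec.apposition_pct - truth.true_apposition_pct) < 5.0

    def test_blank_stack_yields_an_invalid_record(self, caplog):
        vox = np.full((2, 4, 16, 16), 100, dtype=np.uint16)
        with caplog.at_level("WARNING"):
            rec = measure_nmj(ImageStack(voxels=vox), MorphometryConfig(threshold=3000))
        assert not rec.valid
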