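from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lensroi import (
    AlgorithmParams,
    FrameStack,
    ROI,
    adaptive_binarize,
    area_opening,
    average_binary,
    compute_dff,
    determine_rois,
    label_rois,
    morphological_opening,
    roi_trace,
)
from lensroi.roi import local_gaussian_threshold

from oracles import (
    area_opening_bf,
    dff_bf,
    gaussian_threshold_bf,
    opening_bf,
    roi_trace_bf,
)


class TestComputeDff:
    def test_equal_to_baseline_gives_zero(self):
        stack = np.full((6, 2, 2), 50.0)
        dff = compute_dff(stack, 3)
        assert np.allclose(dff.data, 0.0)

    def test_fifty_percent_rise(self):
        stack = np.full((4, 1, 1), 50.0)
        stack[2:] = 75.0
        dff = compute_dff(stack, 2)
        assert np.allclose(dff.data[2:], 50.0)

    def test_matches_elementwise_oracle(self, rng):
        stack = rng.random((10, 4, 4)) * 100 + 1
        dff = compute_dff(stack, 4)
        assert np.allclose(dff.data, dff_bf(stack, 4), atol=1e-3)

    def test_zero_baseline_pixels_guarded(self):
        stack = np.ones((5, 2, 2))
        stack[:, 0, 0] = 0.0
        dff = compute_dff(stack, 2)
        assert dff.n_zero_baseline_pixels == 1
        assert np.all(dff.data[:, 0, 0] == 0)
        assert np.all(np.isfinite(dff.data))

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            compute_dff(np.empty((0, 4, 4)), 1)

    def test_baseline_longer_than_stack_rejected(self):
        with pytest.raises(ValueError):
            compute_dff(np.ones((3, 2, 2)), 5)


class TestAdaptiveBinarize:
    def test_constant_image_all_zero(self):
        assert not adaptive_binarize(np.full((20, 20), 7.3), sigma=1.5).any()

    def test_single_hot_pixel_detected(self):
        image = np.zeros((15, 15))
        image[7, 7] = 10.0
        mask = adaptive_binarize(image, sigma=1.5)
        assert mask[7, 7] == 1

    @pytest.mark.parametrize("sigma,block", [(0.5, 7), (1.5, 15), (2.5, 9)])
    def test_threshold_matches_bruteforce(self, sigma, block, rng):
        for _ in range(10):
            image = rng.random((12, 12))
            ours = local_gaussian_threshold(image, sigma, block)
            theirs = gaussian_threshold_bf(image, sigma, block)
            assert np.allclose(ours, theirs, atol=1e-5)

    def test_mask_matches_bruteforce(self, rng):
        for _ in range(10):
            image = rng.random((16, 16))
            mask = adaptive_binarize(image, sigma=1.5, block_size=9)
            expected = image > gaussian_threshold_bf(image, 1.5, 9)
            assert np.array_equal(mask.astype(bool), expected)

    def test_even_block_size_rejected(self):
        with pytest.raises(ValueError):
            adaptive_binarize(np.zeros((5, 5)), sigma=1.0, block_size=8)

    def test_stack_is_framewise(self, rng):
        stack = rng.random((4, 10, 10))
        whole = adaptive_binarize(stack, sigma=1.5, block_size=7)
        for t in range(4):
            single = adaptive_binarize(stack[t], sigma=1.5, block_size=7)
            assert np.array_equal(whole[t], single)


class TestMorphologicalOpening:
    def test_isolated_pixel_removed(self):
        image = np.zeros((9, 9), dtype=np.uint8)
        image[4, 4] = 1
        assert not morphological_opening(image, 3).any()

    def test_all_ones_preserved(self):
        image = np.ones((8, 8), dtype=np.uint8)
        assert np.array_equal(
            morphological_opening(image, 3), opening_bf(image, 3)
        )

    def test_footprint_one_is_identity(self, rng):
        image = (rng.random((10, 10)) < 0.5).astype(np.uint8)
        assert np.array_equal(morphological_opening(image, 1), image)

    @pytest.mark.parametrize("side", [2, 3, 5])
    def test_matches_bruteforce(self, side, rng):
        for _ in range(10):
            image = (rng.random((12, 12)) < 0.45).astype(np.uint8)
            assert np.array_equal(
                morphological_opening(image, side), opening_bf(image, side)
            )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        arrays(np.uint8, (12, 12), elements=st.integers(0, 1)),
        st.sampled_from([2, 3, 5]),
    )
    def test_idempotent_and_antiextensive(self, image, side):
        once = morphological_opening(image, side)
        twice = morphological_opening(once, side)
        assert np.array_equal(once, twice)
        assert np.all(once <= image)


class TestAreaOpening:
    def test_min_area_zero_is_identity(self, rng):
        image = (rng.random((10, 10)) < 0.5).astype(np.uint8)
        assert np.array_equal(area_opening(image, 0), image)

    def test_small_component_removed_large_kept(self):
        image = np.zeros((12, 12), dtype=np.uint8)
        image[1:3, 1:3] = 1  # area 4
        image[6:10, 6:10] = 1  # area 16
        out = area_opening(image, 9)
        assert not out[1:3, 1:3].any()
        assert out[6:10, 6:10].all()

    def test_component_at_threshold_retained(self):
        image = np.zeros((8, 8), dtype=np.uint8)
        image[2:4, 2:4] = 1  # area exactly 4
        assert area_opening(image, 4).sum() == 4

    def test_diagonal_pixels_form_one_component(self):
        image = np.zeros((6, 6), dtype=np.uint8)
        image[2, 2] = image[3, 3] = 1
        # 8-connectivity: the pair has area 2 and survives min_area=2
        assert area_opening(image, 2).sum() == 2
        # 4-connectivity: two singletons, both removed
        assert not area_opening(image, 2, connectivity=4).any()

    def test_matches_floodfill_oracle(self, rng):
        for min_area in (2, 4, 7):
            for _ in range(8):
                image = (rng.random((14, 14)) < 0.4).astype(np.uint8)
                assert np.array_equal(
                    area_opening(image, min_area), area_opening_bf(image, min_area)
                )

    def test_stack_components_do_not_span_frames(self):
        stack = np.zeros((2, 6, 6), dtype=np.uint8)
        stack[0, 2:4, 2:4] = 1
        stack[1, 2:4, 2:4] = 1
        # each frame's component has area 4 and is removed at min_area=5
        # even though the 3-D blob would have 8 voxels
        assert not area_opening(stack, 5).any()


class TestAverageBinary:
    def test_identical_frames_unchanged(self, rng):
        frame = (rng.random((6, 6)) < 0.5).astype(np.uint8)
        stack = np.stack([frame] * 5)
        assert np.allclose(average_binary(stack), frame)

    def test_fractional_mean(self):
        stack = np.zeros((10, 3, 3), dtype=np.uint8)
        stack[:3, 1, 1] = 1
        assert average_binary(stack)[1, 1] == pytest.approx(0.3)

    def test_matches_direct_sum(self, rng):
        stack = (rng.random((7, 5, 5)) < 0.5).astype(np.uint8)
        assert np.allclose(average_binary(stack), stack.sum(axis=0) / 7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_binary(np.empty((0, 4, 4)))


class TestDetermineRois:
    def test_constant_stack_no_rois(self):
        mask = determine_rois(np.full((20, 30, 30), 5.0), AlgorithmParams())
        assert mask.n_rois == 0
        assert not mask.mask.any()
        assert mask.mean_roi_area == 0.0

    def test_simulated_dataset_yields_distributed_rois(self, small_dataset):
        dff = compute_dff(small_dataset.frames)
        mask = determine_rois(dff.post(), AlgorithmParams())
        assert mask.n_rois > 3
        rows = np.flatnonzero(mask.mask.any(axis=1))
        assert rows.max() - rows.min() > small_dataset.frames.shape[1] / 3

    def test_cleaning_steps_idempotent(self, small_dataset):
        dff = compute_dff(small_dataset.frames)
        mask = determine_rois(dff.post(), AlgorithmParams()).mask
        again = area_opening(morphological_opening(mask, 3), 0)
        assert np.array_equal(again, mask)

    def test_deterministic(self, small_dataset):
        dff = compute_dff(small_dataset.frames)
        a = determine_rois(dff.post(), AlgorithmParams())
        b = determine_rois(dff.post(), AlgorithmParams())
        assert np.array_equal(a.mask, b.mask)

    def test_time_frames_exceeding_stack_rejected(self):
        with pytest.raises(ValueError):
            determine_rois(
                np.zeros((5, 10, 10)), AlgorithmParams(time_frames=6)
            )

    def test_mean_area_consistency(self, small_dataset):
        dff = compute_dff(small_dataset.frames)
        mask = determine_rois(dff.post(), AlgorithmParams())
        if mask.n_rois:
            assert mask.mean_roi_area == pytest.approx(
                mask.mask.sum() / mask.n_rois
            )

    def test_mean_area_non_decreasing_in_sigma2(self, small_dataset):
        """A broader second-pass threshold kernel admits larger features."""
        dff = compute_dff(small_dataset.frames)
        areas = [
            determine_rois(dff.post(), AlgorithmParams(sigma2=s)).mean_roi_area
            for s in (0.5, 1.5, 2.5)
        ]
        assert np.all(np.diff(areas) >= 0)

    def test_foreground_non_increasing_in_fp2(self, small_dataset):
        """With the first pass fixed, opening the final mask with a
        nested larger footprint can only remove pixels."""
        dff = compute_dff(small_dataset.frames)
        foregrounds = [
            int(determine_rois(dff.post(), AlgorithmParams(fp2=f)).mask.sum())
            for f in (1, 2, 3, 5)
        ]
        assert np.all(np.diff(foregrounds) <= 0)


class TestLabelRois:
    def test_empty_mask_no_rois(self):
        assert label_rois(np.zeros((5, 5), dtype=np.uint8)) == []

    def test_diagonal_touch_is_one_roi(self):
        mask = np.zeros((5, 5), dtype=np.uint8)
        mask[1, 1] = mask[2, 2] = 1
        rois = label_rois(mask)
        assert len(rois) == 1
        assert rois[0].area == 2

    def test_areas_partition_foreground(self, small_dataset):
        dff = compute_dff(small_dataset.frames)
        mask = determine_rois(dff.post(), AlgorithmParams())
        rois = label_rois(mask)
        assert sum(r.area for r in rois) == int(mask.mask.sum())
        all_pixels = [p for r in rois for p in r.pixels]
        assert len(all_pixels) == len(set(all_pixels))


class TestRoiTrace:
    def test_constant_stack_zero_trace(self):
        stack = np.full((8, 4, 4), 3.0)
        roi = ROI(1, ((1, 1), (1, 2)), 2, (1.0, 1.5))
        assert np.allclose(roi_trace(stack, roi, 4), 0.0)

    def test_single_pixel_roi_equals_pixel_dff(self, rng):
        stack = rng.random((10, 4, 4)) + 0.5
        roi = ROI(1, ((2, 3),), 1, (2.0, 3.0))
        trace = roi_trace(stack, roi, 5)
        dff = compute_dff(stack, 5)
        assert np.allclose(trace, dff.data[:, 2, 3], atol=1e-4)

    def test_matches_formula_oracle(self, rng):
        stack = rng.random((12, 6, 6)) * 50 + 10
        pixels = ((0, 0), (1, 4), (2, 2), (5, 5), (3, 1))
        roi = ROI(1, pixels, 5, (0.0, 0.0))
        assert np.allclose(
            roi_trace(stack, roi, 6), roi_trace_bf(stack, pixels, 6)
        )

    def test_zero_baseline_rejected(self):
        stack = np.zeros((6, 3, 3))
        roi = ROI(1, ((1, 1),), 1, (1.0, 1.0))
        with pytest.raises(ValueError):
            roi_trace(stack, roi, 3)


class TestBinaryInvariants:
    def test_pipeline_intermediates_strictly_binary(self, small_dataset):
        params = AlgorithmParams()
        dff = compute_dff(small_dataset.frames)
        seg = dff.post()[:100]
        b1 = adaptive_binarize(seg, params.sigma1, params.block_size)
        b2 = morphological_opening(b1, params.fp1)
        b3 = area_opening(b2, params.area1)
        for b in (b1, b2, b3):
            assert set(np.unique(b)) <= {0, 1}
        avg = average_binary(b3)
        assert avg.min() >= 0.0 and avg.max() <= 1.0
        b5 = adaptive_binarize(avg, params.sigma2, params.block_size)
        b6 = morphological_opening(b5, params.fp2)
        b7 = area_opening(b6, params.area2)
        for b in (b5, b6, b7):
            assert set(np.unique(b)) <= {0, 1}
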