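"""Gaussian agglomeration, global/adaptive thresholding, and cluster metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dendroquant import (
    ClusterParams,
    SceneParams,
    adaptive_threshold_mask,
    gaussian_smooth,
    global_threshold_mask,
    grow_skeleton,
    label_clusters,
    make_puncta_image,
    normalize_timeseries,
    run_cluster_pipeline,
    straight_roi,
)
from dendroquant.roi import SkeletonCurve

from .conftest import flood_fill_components


def brute_force_window_mean(image, half):
    """Per-pixel loop over clipped rectangular windows (oracle)."""
    out = np.empty_like(image, dtype=float)
    rows, cols = image.shape
    for r in range(rows):
        for c in range(cols):
            window = image[
                max(r - half, 0) : min(r + half + 1, rows),
                max(c - half, 0) : min(c + half + 1, cols),
            ]
            out[r, c] = window.mean()
    return out


class TestGaussianSmooth:
    def test_constant_image_unchanged(self):
        img = np.full((30, 30), 0.3)
        assert np.allclose(gaussian_smooth(img, 51, 0.8), img)

    def test_impulse_reproduces_normalized_kernel(self):
        img = np.zeros((31, 31))
        img[15, 15] = 1.0
        out = gaussian_smooth(img, gauss_size=5, gauss_sigma=0.8)
        ax = np.arange(-2, 3)
        kernel = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * 0.8**2))
        kernel /= kernel.sum()
        assert np.allclose(out[13:18, 13:18], kernel)

    def test_interior_intensity_conserved(self):
        rng = np.random.default_rng(0)
        img = np.zeros((80, 80))
        img[30:50, 30:50] = rng.uniform(0, 1, (20, 20))
        out = gaussian_smooth(img, gauss_size=11, gauss_sigma=1.5)
        assert out.sum() == pytest.approx(img.sum())

    def test_even_kernel_size_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((5, 5)), gauss_size=4)


class TestGlobalThreshold:
    def test_uniform_half_above_04_all_true(self):
        assert global_threshold_mask(np.full((4, 4), 0.5), 0.4).all()

    def test_threshold_one_empty_when_max_below(self):
        assert not global_threshold_mask(np.full((4, 4), 0.99), 1.0).any()

    def test_inclusive_at_boundary(self):
        assert global_threshold_mask(np.array([[0.4]]), 0.4).all()

    def test_not_invariant_under_brightness_shift(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0.1, 0.5, (16, 16))
        assert not np.array_equal(
            global_threshold_mask(img, 0.4), global_threshold_mask(img + 0.2, 0.4)
        )


class TestAdaptiveThreshold:
    def test_constant_image_gives_empty_mask(self):
        assert not adaptive_threshold_mask(np.full((20, 20), 0.7), 10, 0.1).any()

    def test_matches_brute_force_window_mean(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 1, (5, 5))
        expected = img >= brute_force_window_mean(img, 2) + 0.05
        assert np.array_equal(adaptive_threshold_mask(img, 2, 0.05), expected)

    @settings(derandomize=True, max_examples=25)
    @given(
        img=hnp.arrays(float, (12, 12), elements=st.floats(0, 1)),
        shift=st.floats(-0.3, 0.3),
    )
    def test_invariant_under_additive_shift(self, img, shift):
        base = adaptive_threshold_mask(img, 3, 0.05)
        shifted = adaptive_threshold_mask(img + shift, 3, 0.05)
        assert np.array_equal(base, shifted)


class TestLabelClusters:
    @pytest.fixture
    def wide_roi(self, unit_calibration):
        mask = np.zeros((40, 40), dtype=bool)
        mask[20, 1:39] = True
        return grow_skeleton(SkeletonCurve(mask=mask, calibration=unit_calibration), 19)

    def test_two_separated_blobs(self, wide_roi):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:8, 5:8] = True
        mask[5:8, 12:15] = True
        result = label_clusters(mask, wide_roi)
        assert result.n_clusters == 2
        assert sorted(result.areas_px) == [9, 9]
        assert result.total_area_um2 == pytest.approx(18.0)  # 1 µm/px

    def test_blob_outside_roi_excluded(self, unit_calibration):
        skel = np.zeros((60, 60), dtype=bool)
        skel[10, 1:59] = True
        roi = grow_skeleton(SkeletonCurve(mask=skel, calibration=unit_calibration), 5)
        mask = np.zeros((60, 60), dtype=bool)
        mask[12:14, 20:22] = True  # inside band
        mask[50:53, 30:33] = True  # far below band
        result = label_clusters(mask, roi)
        assert result.n_clusters == 1
        assert result.areas_px.sum() == 4

    def test_labeled_pixels_inside_roi_and_areas_consistent(self, wide_roi):
        rng = np.random.default_rng(3)
        mask = rng.uniform(size=(40, 40)) > 0.7
        result = label_clusters(mask, wide_roi)
        assert np.all(wide_roi.mask[result.labels > 0])
        assert result.areas_px.sum() == np.count_nonzero(mask & wide_roi.mask)
        assert result.total_area_um2 == pytest.approx(result.areas_um2.sum())

    def test_areas_match_flood_fill_oracle(self, wide_roi):
        rng = np.random.default_rng(4)
        mask = rng.uniform(size=(40, 40)) > 0.6
        result = label_clusters(mask, wide_roi)
        oracle = flood_fill_components(mask & wide_roi.mask, connectivity=8)
        assert sorted(result.areas_px) == sorted(oracle)

    def test_4_connectivity_never_fewer_clusters(self, wide_roi):
        rng = np.random.default_rng(5)
        mask = rng.uniform(size=(40, 40)) > 0.6
        r8 = label_clusters(mask, wide_roi, connectivity=8)
        r4 = label_clusters(mask, wide_roi, connectivity=4)
        assert r4.n_clusters >= r8.n_clusters
        assert r4.areas_px.sum() == r8.areas_px.sum()


class TestPipeline:
    def test_area_per_length_is_total_over_length(self, cluster_calibration):
        params = SceneParams(n_puncta=5)
        image, _ = make_puncta_image(params, seed=1)
        roi = straight_roi(params.image_shape, cluster_calibration, 120)
        result = run_cluster_pipeline(image, roi, ClusterParams(mode="adaptive"))
        assert result.area_per_length == pytest.approx(result.total_area_um2 / roi.length_um)

    def test_empty_image_zero_clusters(self, cluster_calibration):
        image = np.zeros((64, 64))
        roi = straight_roi((64, 64), cluster_calibration, 30)
        result = run_cluster_pipeline(image, roi, ClusterParams(mode="global"))
        assert result.n_clusters == 0
        assert result.total_area_um2 == 0.0

    @pytest.mark.parametrize("mode", ["adaptive", "global"])
    @pytest.mark.parametrize("k", [0, 3, 12, 25])
    def test_planted_puncta_count_recovered(self, cluster_calibration, mode, k):
        params = SceneParams(n_puncta=k, min_center_distance_px=20)
        image, _ = make_puncta_image(params, seed=k + 1)
        roi = straight_roi(params.image_shape, cluster_calibration, 150)
        result = run_cluster_pipeline(image, roi, ClusterParams(mode=mode))
        assert result.n_clusters == k

    def test_global_misses_dim_gradient_puncta_adaptive_recovers(self, cluster_calibration):
        params = SceneParams(
            n_puncta=6, background="linear-gradient", punctum_peak=0.25
        )
        centers = [(128, 40 + 40 * i) for i in range(6)]
        image, _ = make_puncta_image(params, seed=1, centers=centers)
        roi = straight_roi(params.image_shape, cluster_calibration, 150)
        adaptive = run_cluster_pipeline(image, roi, ClusterParams(mode="adaptive"))
        global_ = run_cluster_pipeline(image, roi, ClusterParams(mode="global"))
        assert adaptive.n_clusters == 6
        # in the dim half the gradient keeps spot maxima below 0.4
        dim_centers = [c for c in centers if c[1] < 100]
        assert dim_centers
        assert all(global_.labels[r, c] == 0 for r, c in dim_centers)

    def test_total_area_monotone_in_global_threshold(self, cluster_calibration):
        params = SceneParams(n_puncta=10)
        image, _ = make_puncta_image(params, seed=2)
        roi = straight_roi(params.image_shape, cluster_calibration, 150)
        areas = [
            run_cluster_pipeline(
                image, roi, ClusterParams(mode="global", global_threshold=t)
            ).total_area_um2
            for t in (0.2, 0.4, 0.6, 0.8)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestNormalizeTimeseries:
    def test_baseline_relative_values(self):
        out = normalize_timeseries([2, 2, 2, 2, 1], n_baseline=4)
        assert out[-1] == pytest.approx(0.5)

    def test_all_equal_gives_ones(self):
        assert np.allclose(normalize_timeseries([3, 3, 3, 3, 3, 3]), 1.0)

    def test_nonuniform_baseline_mean(self):
        out = normalize_timeseries([1, 2, 3, 4, 5], n_baseline=4)
        assert out[4] == pytest.approx(2.0)  # 5 / mean(1..4)

    def test_zero_baseline_errors(self):
        with pytest.raises(ValueError):
            normalize_timeseries([0, 0, 0, 0, 1])

    def test_too_few_baseline_frames(self):
        with pytest.raises(ValueError):
            normalize_timeseries([1, 2], n_baseline=4, treatment_index=2)
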