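"""Segmentation stages against brute-force oracles and invariants."""

import math

import numpy as np
import pandas as pd
import pytest

import meisoquant as mq
from meisoquant.blobs import (
    compute_threshold,
    feret_diameter,
    foreground_image,
    gaussian_smooth,
    remove_bright_outliers,
    segment_blobs,
    summarize_morphometry,
)
from meisoquant.images import IntensityImage, RoiMask

from conftest import brute_feret, brute_remove_outliers


def _img(values, s=0.1):
    return IntensityImage(np.asarray(values, dtype=float), s)


class TestRemoveBrightOutliers:
    def test_constant_image_unchanged(self):
        img = _img(np.full((20, 20), 7.0))
        out = remove_bright_outliers(img, radius_px=3, threshold=5)
        np.testing.assert_array_equal(out.values, img.values)

    @pytest.mark.parametrize("peak,expected_replaced", [(100.0, True), (35.0, False)])
    def test_single_hot_pixel(self, peak, expected_replaced):
        values = np.full((15, 15), 10.0)
        values[7, 7] = peak
        out = remove_bright_outliers(_img(values), radius_px=2, threshold=30)
        if expected_replaced:
            assert out.values[7, 7] == 10.0  # replaced by the disc median
        else:
            assert out.values[7, 7] == peak  # deviation 25 <= 30: untouched
        # every other pixel is below its neighborhood median + threshold
        mask = np.ones_like(values, bool)
        mask[7, 7] = False
        np.testing.assert_array_equal(out.values[mask], values[mask])

    @pytest.mark.parametrize("radius", [2, 3])
    def test_matches_brute_force_disc_median(self, radius):
        rng = np.random.default_rng(0)
        values = np.round(rng.gamma(2.0, 10.0, size=(18, 14)))
        out = remove_bright_outliers(_img(values), radius_px=radius, threshold=5)
        expected = brute_remove_outliers(values, radius, 5)
        np.testing.assert_array_equal(out.values, expected)

    def test_radius_larger_than_image_errors(self):
        with pytest.raises(ValueError, match="radius"):
            remove_bright_outliers(_img(np.zeros((9, 9))), radius_px=10, threshold=1)


class TestForegroundImage:
    def test_raw_equals_background_gives_zero(self):
        img = _img(np.arange(16.0).reshape(4, 4))
        out = foreground_image(img, img)
        assert np.all(out.values == 0.0)

    def test_blob_over_background_is_isolated_exactly(self):
        bg = np.full((10, 10), 20.0)
        raw = bg.copy()
        raw[3:6, 3:6] += 90.0
        out = foreground_image(_img(raw), _img(bg))
        expected = np.zeros((10, 10))
        expected[3:6, 3:6] = 90.0
        np.testing.assert_array_equal(out.values, expected)

    def test_clamped_at_zero(self):
        out = foreground_image(_img(np.full((5, 5), 10.0)), _img(np.full((5, 5), 30.0)))
        assert np.all(out.values == 0.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            foreground_image(_img(np.zeros((4, 4))), _img(np.zeros((5, 5))))


class TestGaussianSmooth:
    def test_constant_unchanged(self):
        img = _img(np.full((11, 11), 4.2))
        np.testing.assert_allclose(gaussian_smooth(img, 1.0).values, 4.2)

    def test_impulse_centre_weight(self):
        values = np.zeros((21, 21))
        values[10, 10] = 1.0
        out = gaussian_smooth(_img(values), 1.0)
        # centre weight of the normalized discrete Gaussian, sigma = 1
        assert out.values[10, 10] == pytest.approx(0.1592, abs=1e-3)

    def test_total_intensity_conserved(self):
        values = np.zeros((31, 31))
        values[15, 15] = 7.0
        out = gaussian_smooth(_img(values), 1.0)
        assert out.values.sum() == pytest.approx(7.0, rel=1e-6)


class TestComputeThreshold:
    @pytest.mark.parametrize("mean,coef,expected", [(100, 2, 200), (12.5, 1.6, 20)])
    def test_product(self, mean, coef, expected):
        assert compute_threshold(mean, coef) == expected

    def test_zero_background_flagged(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert compute_threshold(0.0, 2.0) == 0.0


class TestFeretDiameter:
    def test_single_pixel(self):
        assert feret_diameter(np.array([[4, 7]]), 0.1) == pytest.approx(0.1 * math.sqrt(2))

    def test_three_by_one_bar(self):
        px = np.array([[5, 3], [5, 4], [5, 5]])
        assert feret_diameter(px, 0.1) == pytest.approx(math.sqrt(0.3**2 + 0.1**2))

    def test_rasterized_disc(self):
        s = 0.05
        rr, cc = np.mgrid[0:100, 0:100]
        inside = ((rr + 0.5) * s - 2.5) ** 2 + ((cc + 0.5) * s - 2.5) ** 2 <= 2.0**2
        px = np.column_stack([rr[inside], cc[inside]])
        d = feret_diameter(px, s)
        assert abs(d - 4.0) <= s * math.sqrt(2)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            feret_diameter(np.empty((0, 2)), 0.1)

    def test_matches_brute_force_on_random_shapes(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(1, 40)
            px = np.unique(rng.integers(0, 15, size=(n, 2)), axis=0)
            assert feret_diameter(px, 0.13) == pytest.approx(
                brute_feret(px, 0.13), rel=1e-12
            )


class TestSegmentBlobs:
    def _segment_squares(self, min_area):
        """Three squares of 0.10, 0.15 and 0.20 um^2 at 0.05 um pixels."""
        s = 0.05
        values = np.zeros((60, 60))
        values[5:10, 5:13] = 100.0     # 40 px  = 0.100 um^2
        values[25:31, 25:35] = 100.0   # 60 px  = 0.150 um^2
        values[45:53, 45:55] = 100.0   # 80 px  = 0.200 um^2
        img = IntensityImage(values, s)
        params = mq.SegmentationParams(min_area_um2=min_area)
        return segment_blobs(img, 50.0, RoiMask.full(values.shape, s), params)

    def test_area_filter_boundary_equality_survives(self):
        _, table = self._segment_squares(0.15)
        assert len(table) == 2
        assert sorted(table["area_um2"].round(3)) == [0.15, 0.2]

    def test_all_background_gives_empty_table(self):
        img = _img(np.zeros((30, 30)), 0.05)
        lab, table = segment_blobs(img, 10.0, RoiMask.full((30, 30), 0.05))
        assert table.empty and lab.max() == 0

    def test_filter_monotonicity(self):
        counts = [len(self._segment_squares(m)[1]) for m in (0.05, 0.10, 0.15, 0.20, 0.25)]
        assert counts == sorted(counts, reverse=True)

    def test_roi_restricts_detection(self):
        s = 0.05
        values = np.zeros((40, 40))
        values[5:15, 5:15] = 100.0
        values[25:35, 25:35] = 100.0
        roi = np.zeros((40, 40), bool)
        roi[:20, :20] = True
        _, table = segment_blobs(IntensityImage(values, s), 50.0, RoiMask(roi, s))
        assert len(table) == 1


class TestSummarize:
    def test_density_and_means(self):
        table = pd.DataFrame(
            {
                "label": range(1, 13),
                "area_um2": [0.2, 0.4] * 6,
                "feret_um": [1.0] * 12,
                "centroid_x_um": 0.0,
                "centroid_y_um": 0.0,
            }
        )
        s = summarize_morphometry(table, 400.0)
        assert s.density_per_um2 == pytest.approx(0.03)
        assert s.mean_area_um2 == pytest.approx(0.3)
        assert s.means_defined

    def test_empty_table_flagged(self):
        s = summarize_morphometry(pd.DataFrame(columns=["area_um2", "feret_um"]), 100.0)
        assert s.n_objects == 0
        assert s.density_per_um2 == 0.0
        assert not s.means_defined
        assert math.isnan(s.mean_area_um2)


class TestPipeline:
    def test_recovers_planted_object_count(self, small_scene, small_pipeline):
        _, gt = small_scene
        assert small_pipeline.summary.n_objects == gt.n_objects

    def test_shape_bound_feret_vs_area(self, small_pipeline):
        t = small_pipeline.blobs
        assert np.all(
            t["feret_um"] >= 2 * np.sqrt(t["area_um2"] / math.pi) - 1e-9
        )

    def test_threshold_monotonicity(self, small_scene):
        img, _ = small_scene
        counts = []
        for coef in (1.5, 2.0, 2.5, 3.0):
            params = mq.SegmentationParams(background_coefficient=coef)
            res = mq.run_pipeline(img, params=params)
            counts.append(int((res.label_image > 0).sum()))
        assert counts == sorted(counts, reverse=True)

    def test_noise_only_image_yields_no_objects(self):
        rng = np.random.default_rng(0)
        spec = mq.SceneSpec(roi_width_um=15, roi_height_um=10, n_objects=0, seed=0)
        values = np.clip(np.round(rng.normal(25.0, 5.0, spec.shape)), 0, None)
        res = mq.run_pipeline(IntensityImage(values, spec.pixel_size_um))
        assert res.summary.n_objects == 0

    def test_fragmented_scene_direction(self, small_pipeline, fragmented_scene):
        fimg, _ = fragmented_scene
        fres = mq.run_pipeline(fimg)
        assert fres.summary.mean_area_um2 < small_pipeline.summary.mean_area_um2
        assert fres.summary.mean_feret_um < small_pipeline.summary.mean_feret_um
        assert fres.summary.density_per_um2 > small_pipeline.summary.density_per_um2

    def test_audit_trail_logged(self, small_pipeline):
        assert small_pipeline.threshold == pytest.approx(
            small_pipeline.background_mean
            * small_pipeline.params.background_coefficient
        )
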