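import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsiprep.cube_io import BinaryMask, HyperCube, ValidationError
from hsiprep.quality import image_entropy
from hsiprep.segmentation import (BandScore, SegmentParams, apply_mask,
                                  band_spectral_angle, intersect_masks,
                                  mean_band_image, pca_decompose,
                                  segment_pipeline, select_band_by_entropy,
                                  select_top_bands, threshold_segment)


def _cube(data):
    data = np.asarray(data, dtype=float)
    return HyperCube(data, np.arange(data.shape[2], dtype=float) + 400)


class TestSpectralAngle:
    def test_band_parallel_to_reference_has_zero_angle(self):
        cube = _cube(np.full((3, 2, 1), 5.0))
        assert band_spectral_angle(cube, "ones")[0].score == pytest.approx(0.0, abs=1e-7)

    def test_zero_mean_band_orthogonal_to_ones(self):
        data = np.zeros((2, 1, 1))
        data[0, 0, 0], data[1, 0, 0] = 1.0, -1.0
        assert band_spectral_angle(_cube(data))[0].score == pytest.approx(np.pi / 2)

    def test_hand_worked_forty_five_degrees(self):
        """2-pixel band [1, 1] against basis axis [1, 0] -> arccos(1/sqrt(2))."""
        cube = _cube(np.ones((2, 1, 1)))
        score = band_spectral_angle(cube, "basis_axis")[0].score
        assert score == pytest.approx(np.pi / 4, abs=1e-12)

    def test_all_zero_band_warns_and_returns_right_angle(self):
        data = np.ones((2, 2, 2))
        data[:, :, 1] = 0.0
        with pytest.warns(UserWarning, match="all zero"):
            scores = band_spectral_angle(_cube(data))
        assert scores[1].score == pytest.approx(np.pi / 2)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 100))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        data = rng.uniform(0.1, 1.0, size=(5, 4, 3))
        base = band_spectral_angle(_cube(data))
        scaled = band_spectral_angle(_cube(scale * data))
        for a, b in zip(base, scaled):
            assert b.score == pytest.approx(a.score, abs=1e-9)


class TestBandSelection:
    def test_top_k_order_statistic(self):
        scores = [BandScore(i, 400.0 + i, s) for i, s in enumerate([3.0, 1.0, 2.0])]
        assert select_top_bands(scores, 2) == [0, 2]

    def test_k_equal_band_count_returns_all(self):
        scores = [BandScore(i, 400.0 + i, float(i)) for i in range(5)]
        assert select_top_bands(scores, 5) == [0, 1, 2, 3, 4]

    def test_ties_break_to_lower_index(self):
        scores = [BandScore(i, 400.0 + i, s) for i, s in enumerate([1.0, 1.0, 1.0])]
        assert select_top_bands(scores, 2) == [0, 1]

    def test_default_k_returns_twenty_bands(self, rng):
        cube = _cube(rng.uniform(0.1, 1.0, size=(6, 5, 270)))
        top = select_top_bands(band_spectral_angle(cube))
        assert len(top) == 20

    def test_invalid_k_rejected(self):
        with pytest.raises(ValidationError):
            select_top_bands([BandScore(0, 400.0, 1.0)], 0)

    def test_entropy_selects_structured_band(self, rng):
        data = np.full((16, 16, 4), 0.5)
        data[:, :, 2] = rng.uniform(0, 1, size=(16, 16))
        assert select_band_by_entropy(_cube(data)) == 2

    def test_entropy_selection_matches_exhaustive_recomputation(self, rng):
        cube = _cube(rng.uniform(0, 1, size=(12, 10, 8)) ** rng.uniform(0.5, 3))
        oracle = int(np.argmax([image_entropy(cube.band(b))
                                for b in range(cube.n_bands)]))
        assert select_band_by_entropy(cube) == oracle

    def test_single_band_cube(self, rng):
        assert select_band_by_entropy(_cube(rng.random((4, 4, 1)))) == 0


class TestMeanAndThreshold:
    def test_mean_of_single_band_is_identity(self, rng):
        cube = _cube(rng.random((5, 4, 3)))
        assert np.array_equal(mean_band_image(cube, [1]), cube.band(1))

    def test_mean_of_two_bands(self):
        data = np.zeros((1, 1, 2))
        data[0, 0] = [1.0, 3.0]
        assert mean_band_image(_cube(data), [0, 1])[0, 0] == 2.0

    def test_manual_threshold_below_polarity(self):
        mask = threshold_segment(np.array([[100.0, 200.0]]), "manual", 171, "below")
        assert mask.grid.tolist() == [[True, False]]

    def test_constant_image_all_foreground_below_high_threshold(self):
        mask = threshold_segment(np.full((3, 3), 5.0), "manual", 10, "below")
        assert mask.grid.all()

    def test_constant_image_with_otsu_advises_manual(self):
        with pytest.raises(ValidationError, match="manual"):
            threshold_segment(np.full((3, 3), 5.0), "otsu")

    def test_otsu_matches_exhaustive_intra_class_variance_sweep(self):
        rng = np.random.default_rng(7)
        labels = rng.random(10_000) < 0.4
        values = np.where(labels, rng.normal(200, 12, 10_000),
                          rng.normal(50, 12, 10_000))
        mask = threshold_segment(values.reshape(100, 100), "otsu",
                                 foreground="above")
        misclassified = np.mean(mask.grid.ravel() != labels)
        assert misclassified < 0.01

        # independent oracle: sweep thresholds minimizing within-class variance
        candidates = np.linspace(values.min(), values.max(), 512)
        best, best_t = np.inf, None
        for t in candidates:
            lo, hi = values[values <= t], values[values > t]
            if len(lo) == 0 or len(hi) == 0:
                continue
            score = len(lo) * lo.var() + len(hi) * hi.var()
            if score < best:
                best, best_t = score, t
        oracle_mask = values > best_t
        assert np.mean(mask.grid.ravel() != oracle_mask) < 0.005


class TestPCA:
    def test_rank_one_cube_fully_explained_by_first_component(self, rng):
        spectrum = rng.uniform(0.5, 1.0, size=6)
        scalars = rng.uniform(0.1, 2.0, size=(8, 7))
        cube = _cube(scalars[:, :, None] * spectrum[None, None, :])
        result = pca_decompose(cube, 3)
        assert result.explained_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_iid_noise_spreads_variance_evenly(self, rng):
        cube = _cube(rng.normal(size=(120, 120, 5)))
        result = pca_decompose(cube, 5)
        assert np.allclose(result.explained_ratio, 0.2, atol=0.02)

    def test_explained_ratios_sorted_and_normalized(self, rng):
        cube = _cube(rng.random((10, 9, 6)))
        result = pca_decompose(cube, 6)
        assert np.all(np.diff(result.explained_ratio) <= 1e-12)
        assert result.explained_ratio.sum() == pytest.approx(1.0, abs=1e-10)

    def test_full_reconstruction_of_centered_data(self, rng):
        cube = _cube(rng.random((8, 6, 5)))
        result = pca_decompose(cube, 5)
        centered = cube.data - result.mean_spectrum[None, None, :]
        rel_err = (np.linalg.norm(result.reconstruct() - centered)
                   / np.linalg.norm(centered))
        assert rel_err < 1e-8

    def test_component_images_have_nonnegative_skewness(self, rng):
        from scipy.stats import skew

        cube = _cube(rng.random((15, 12, 6)) ** 3)
        result = pca_decompose(cube, 4)
        for image in result.component_images:
            assert skew(image.ravel()) >= -1e-9


class TestMaskOps:
    def test_intersection_idempotent_and_identity(self, rng):
        a = BinaryMask(rng.random((6, 5)) > 0.5)
        full = BinaryMask(np.ones((6, 5), bool))
        assert intersect_masks(a, a) == a
        assert intersect_masks(a, full) == a
        complement = BinaryMask(~a.grid)
        assert intersect_masks(a, complement).count == 0

    def test_intersection_shape_mismatch(self):
        with pytest.raises(ValidationError):
            intersect_masks(BinaryMask(np.ones((2, 2), bool)),
                            BinaryMask(np.ones((3, 2), bool)))

    def test_apply_full_mask_is_identity(self, rng):
        cube = _cube(rng.random((4, 3, 2)))
        out = apply_mask(cube, BinaryMask(np.ones((4, 3), bool)))
        assert np.array_equal(out.data, cube.data)

    def test_apply_empty_mask_fills_everything(self, rng):
        cube = _cube(rng.random((4, 3, 2)))
        out = apply_mask(cube, BinaryMask(np.zeros((4, 3), bool)), fill=0.0)
        assert np.all(out.data == 0.0)

    def test_single_pixel_mask_preserves_one_spectrum(self, rng):
        cube = _cube(rng.random((4, 3, 2)))
        grid = np.zeros((4, 3), bool)
        grid[1, 2] = True
        out = apply_mask(cube, BinaryMask(grid), fill=-1.0)
        assert np.array_equal(out.data[1, 2], cube.data[1, 2])
        assert np.all(out.data[0, 0] == -1.0)


class TestPipeline:
    def test_recovers_phantom_foreground(self, corrected_sample):
        sample, _, truth_fg = corrected_sample
        mask, diag = segment_pipeline(sample)
        iou = (np.logical_and(mask.grid, truth_fg).sum()
               / np.logical_or(mask.grid, truth_fg).sum())
        assert iou >= 0.95
        assert diag["result3_count"] <= min(diag["result1_count"],
                                            diag["result2_count"])

    def test_deterministic(self, corrected_sample):
        sample, _, _ = corrected_sample
        mask_a, diag_a = segment_pipeline(sample)
        mask_b, diag_b = segment_pipeline(sample)
        assert mask_a == mask_b
        assert diag_a == diag_b

    def test_explicit_pc_index_respected(self, corrected_sample):
        sample, _, _ = corrected_sample
        params = SegmentParams(pc_index=1, pc_polarity="above")
        _, diag = segment_pipeline(sample, params)
        assert diag["pc_index"] == 1 and diag["pc_polarity"] == "above"

    def test_diagnostics_report_selected_wavelengths(self, corrected_sample):
        sample, _, _ = corrected_sample
        _, diag = segment_pipeline(sample)
        assert len(diag["selected_bands"]) == 20
        assert len(diag["selected_wavelengths"]) == 20
        assert diag["selected_bands"] == sorted(diag["selected_bands"])
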