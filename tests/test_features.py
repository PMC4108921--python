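"""Texture-feature unit and property tests: moments, GLCM, fractal dimension."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import ctexture as ct
from ctexture.features import DegenerateMomentError, quantize


def gimg(arr, levels=256):
    return ct.GrayImage(np.asarray(arr, dtype=np.int64), levels)


small_images = arrays(
    np.int64, st.tuples(st.integers(2, 8), st.integers(2, 8)),
    elements=st.integers(0, 255),
)


class TestMoments:
    @pytest.mark.parametrize(
        "pixels, func, expected",
        [
            ([[5, 5], [5, 5]], ct.intensity_mean, 5.0),
            ([[0, 2], [4, 6]], ct.intensity_mean, 3.0),
            ([[5, 5], [5, 5]], ct.intensity_variance, 0.0),
            ([[0, 2]], ct.intensity_variance, 1.0),
            ([[1, 2], [3, 4]], ct.intensity_variance, 1.25),
            ([[1, 2, 3]], ct.skewness, 0.0),
            ([[0, 0], [0, 1]], ct.skewness, 1.1547),
            ([[0, 1], [0, 1]], ct.excess_kurtosis, -2.0),
        ],
    )
    def test_small_image_values(self, pixels, func, expected):
        assert func(gimg(pixels)) == pytest.approx(expected, abs=1e-4)

    def test_uniform_random_mean_matches_direct_sum(self):
        rng = np.random.default_rng(0)
        img = gimg(rng.integers(0, 256, size=(256, 256)))
        m = ct.intensity_mean(img)
        assert m == pytest.approx(img.pixels.sum() / img.pixels.size)
        assert abs(m - 127.5) < 1.0

    @pytest.mark.parametrize("func", [ct.skewness, ct.excess_kurtosis])
    def test_constant_image_degenerate(self, func):
        with pytest.raises(DegenerateMomentError):
            func(gimg(np.full((4, 4), 9)))

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            ct.GrayImage(np.empty((0, 3), dtype=np.int64), 256)

    @given(small_images, st.integers(1, 50), st.integers(1, 4))
    def test_shape_moments_affine_invariant(self, arr, shift, scale):
        """Skewness/excess kurtosis ignore positive affine intensity maps;
        the variance picks up the squared scale and the mean the shift."""
        arr = arr - arr.min()
        if arr.std() == 0:
            return
        a = gimg(arr, levels=65536)
        b = gimg(arr * scale + shift, levels=65536)
        assert ct.skewness(b) == pytest.approx(ct.skewness(a), abs=1e-9)
        assert ct.excess_kurtosis(b) == pytest.approx(ct.excess_kurtosis(a), abs=1e-9)
        assert ct.intensity_variance(b) == pytest.approx(
            scale**2 * ct.intensity_variance(a), rel=1e-9
        )
        assert ct.intensity_mean(b) == pytest.approx(
            scale * ct.intensity_mean(a) + shift
        )


class TestGlcm:
    def test_single_level_single_pair(self):
        g = ct.compute_glcm(gimg([[3, 3], [3, 3]], 4), ct.GlcmSpec((1, 1), 4))
        assert g.pair_total == 1
        assert g.counts[3, 3] == 1
        assert g.probabilities[3, 3] == 1.0

    def test_antidiagonal_pair_enumeration(self):
        g = ct.compute_glcm(gimg([[0, 1], [1, 0]], 2), ct.GlcmSpec((1, 1), 2))
        assert g.pair_total == 1
        assert g.probabilities[0, 0] == 1.0

    def test_offset_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            ct.compute_glcm(gimg([[0, 1]], 2), ct.GlcmSpec((1, 1), 2))

    @given(small_images)
    def test_probabilities_sum_to_one(self, arr):
        g = ct.compute_glcm(gimg(arr), ct.GlcmSpec((1, 1), 8))
        assert g.probabilities.sum() == pytest.approx(1.0)
        assert (g.counts >= 0).all()

    @given(small_images)
    def test_transpose_image_transposes_glcm(self, arr):
        spec = ct.GlcmSpec((1, 0), 8)
        spec_t = ct.GlcmSpec((0, 1), 8)
        g = ct.compute_glcm(gimg(arr), spec)
        gt = ct.compute_glcm(gimg(arr.T), spec_t)
        np.testing.assert_array_equal(g.counts, gt.counts)
        assert ct.glcm_entropy(g) == pytest.approx(ct.glcm_entropy(gt))

    def test_matches_skimage_graycomatrix(self):
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(5)
        arr = rng.integers(0, 8, size=(31, 37))
        ours = ct.compute_glcm(gimg(arr, 8), ct.GlcmSpec((0, 1), 8))
        ref = graycomatrix(arr.astype(np.uint8), [1], [0], levels=8, symmetric=False)
        np.testing.assert_array_equal(ours.counts, ref[:, :, 0, 0])

    def test_quantization_bins_bit_range_uniformly(self):
        img = gimg(np.arange(256).reshape(16, 16))
        q = quantize(img, 32)
        assert q.min() == 0 and q.max() == 31
        assert np.bincount(q.ravel()).tolist() == [8] * 32


class TestEntropy:
    def test_single_cell_zero(self):
        g = ct.compute_glcm(gimg(np.zeros((4, 4), int), 2), ct.GlcmSpec((1, 1), 2))
        assert ct.glcm_entropy(g) == 0.0

    def test_uniform_probabilities_hit_log_bound(self):
        L = 8
        g = ct.Glcm(
            counts=np.ones((L, L), dtype=np.int64),
            probabilities=np.full((L, L), 1.0 / L**2),
            pair_total=L * L,
        )
        assert ct.glcm_entropy(g) == pytest.approx(math.log(L**2), abs=1e-10)

    def test_checkerboard_two_equal_cells(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        g = ct.compute_glcm(gimg(board, 2), ct.GlcmSpec((0, 1), 2))
        assert ct.glcm_entropy(g) == pytest.approx(math.log(2), abs=1e-10)

    @given(small_images)
    def test_entropy_within_bounds(self, arr):
        g = ct.compute_glcm(gimg(arr), ct.GlcmSpec((1, 1), 8))
        h = ct.glcm_entropy(g)
        assert 0.0 <= h <= math.log(64) + 1e-12


class TestBoxCounting:
    def test_single_pixel_one_box(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[7, 19] = True
        for r in (1, 2, 5, 16):
            assert ct.box_count(mask, r) == 1

    @pytest.mark.parametrize("r", [1, 2, 4, 8, 16])
    def test_full_square_grid_arithmetic(self, r):
        assert ct.box_count(np.ones((32, 32), dtype=bool), r) == (32 // r) ** 2

    @pytest.mark.parametrize("r", [1, 2, 4, 8])
    def test_line_counts(self, r):
        mask = np.zeros((32, 32), dtype=bool)
        mask[4, :] = True
        assert ct.box_count(mask, r) == 32 // r

    def test_counts_non_increasing_in_r(self):
        rng = np.random.default_rng(3)
        mask = rng.random((64, 64)) > 0.8
        counts = [ct.box_count(mask, r) for r in (1, 2, 4, 8, 16, 32)]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize(
        "kind, depth, expected, tol",
        [
            ("square", 0, 2.0, 0.05),
            ("line", 0, 1.0, 0.05),
            ("sierpinski", 6, math.log(3) / math.log(2), 0.15),
        ],
    )
    def test_fractal_dimension_oracles(self, kind, depth, expected, tol):
        mask = ct.generate_fractal_target(kind, 256, depth or 6)
        d, curve = ct.fractal_dimension(mask)
        assert abs(d - expected) < tol
        assert curve.box_counts == tuple(
            ct.box_count(mask, r) for r in curve.box_sizes
        )

    def test_empty_foreground_and_short_ladder_rejected(self):
        with pytest.raises(ValueError):
            ct.fractal_dimension(np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            ct.fractal_dimension(np.ones((8, 8), dtype=bool), sizes=(1, 2))


class TestExtractFeatures:
    def test_constant_window_flagged_degenerate(self):
        fv = ct.extract_features(gimg(np.full((32, 32), 7)))
        assert fv.degenerate
        assert fv.mean == 7.0 and fv.variance == 0.0
        assert fv.skewness == 0.0 and fv.excess_kurtosis == 0.0

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        img = gimg(rng.integers(0, 256, (48, 48)))
        a, b = ct.extract_features(img), ct.extract_features(img)
        np.testing.assert_array_equal(a.to_array(), b.to_array())

    def test_variance_feature_orders_textures(self):
        lo = ct.ClassTextureParams("lo", 128, 25)
        hi = ct.ClassTextureParams("hi", 128, 400)
        f_lo = ct.extract_features(ct.generate_class_texture(lo, (64, 64), 2))
        f_hi = ct.extract_features(ct.generate_class_texture(hi, (64, 64), 2))
        assert f_lo.variance < f_hi.variance

    def test_raw_kurtosis_recorded_in_debug(self):
        rng = np.random.default_rng(4)
        fv = ct.extract_features(gimg(rng.integers(0, 256, (32, 32))))
        assert fv.debug["raw_kurtosis"] == pytest.approx(fv.excess_kurtosis + 3.0)


class TestNormalization:
    def test_column_2_4_6_standardized(self):
        mat = np.tile([[2.0], [4.0], [6.0]], (1, 6)) * np.arange(1, 7)
        model = ct.fit_normalization(mat)
        z = ct.apply_normalization(model, mat)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-12)

    def test_constant_feature_maps_to_zero_with_warning(self):
        mat = np.column_stack([np.full(4, 3.0), np.arange(4.0)] * 3)
        model = ct.fit_normalization(mat)
        with pytest.warns(UserWarning, match="zero-spread"):
            z = ct.apply_normalization(model, mat)
        assert (z[:, 0] == 0.0).all()

    def test_training_mean_maps_to_origin(self):
        rng = np.random.default_rng(9)
        mat = rng.normal(size=(10, 6))
        model = ct.fit_normalization(mat)
        np.testing.assert_allclose(
            ct.apply_normalization(model, mat.mean(axis=0)), 0.0, atol=1e-12
        )

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError):
            ct.fit_normalization(np.ones((1, 6)))
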