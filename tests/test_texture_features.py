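import numpy as np
import pytest

from scarvss import (
    GLCM_FEATURE_NAMES,
    LBPConfig,
    compute_glcm,
    glcm_features,
    lbp_code,
    lbp_histogram,
    quantize,
    semivariogram,
    sv_features,
)
from scarvss.texture_features import lbp_codes

from _oracles import (
    oracle_glcm_counts,
    oracle_glcm_features,
    oracle_lbp_code,
    oracle_semivariogram,
)

FIDX = {name: k for k, name in enumerate(GLCM_FEATURE_NAMES)}


class TestQuantize:
    def test_constant_image_maps_to_level_one(self):
        assert (quantize(np.full((4, 4), 99)) == 1).all()

    def test_endpoints(self):
        q = quantize(np.array([[0, 255]]), 8)
        assert q.tolist() == [[1, 8]]

    def test_bin_boundary_value(self):
        # range 0..255 with 8 levels: width 31.875, so 32 lands in level 2
        img = np.array([[0, 31, 32, 255]])
        assert quantize(img, 8).tolist() == [[1, 1, 2, 8]]

    def test_rejects_single_level(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((3, 3)), 1)


class TestGLCM:
    def test_two_by_two_hand_example(self):
        g = compute_glcm(np.array([[1, 2], [3, 4]]), (0, 1), num_levels=4)
        assert g.n_pairs == 2
        assert g.counts[0, 1] == 1 and g.counts[2, 3] == 1
        assert g.counts.sum() == 2
        assert g.probs[0, 1] == pytest.approx(0.5)

    def test_constant_image_single_cell(self):
        g = compute_glcm(np.full((4, 4), 3), (0, 1), num_levels=4)
        assert g.probs[2, 2] == 1.0

    def test_no_pairs_raises_empty(self):
        with pytest.raises(ValueError, match="empty GLCM"):
            compute_glcm(np.array([[1]]), (0, 1), num_levels=1)

    def test_counts_match_pair_enumeration_oracle(self, rng):
        for _ in range(20):
            q = rng.integers(1, 9, size=(8, 8))
            dr, dc = rng.integers(-2, 3, size=2)
            if dr == 0 and dc == 0:
                dc = 1
            g = compute_glcm(q, (dr, dc), num_levels=8)
            counts, n = oracle_glcm_counts(q.tolist(), (dr, dc))
            assert g.counts.tolist() == counts
            assert g.n_pairs == n

    def test_probs_sum_to_one(self, rng):
        q = rng.integers(1, 9, size=(8, 8))
        g = compute_glcm(q, (0, 1), num_levels=8)
        assert g.probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestGLCMFeatures:
    def test_two_cell_hand_values(self):
        g = compute_glcm(np.array([[1, 2], [3, 4]]), (0, 1), num_levels=4)
        f = glcm_features(g)
        assert f[FIDX["energy"]] == pytest.approx(0.5)
        assert f[FIDX["entropy"]] == pytest.approx(np.log(2))
        assert f[FIDX["contrast"]] == pytest.approx(1.0)
        assert f[FIDX["dissimilarity"]] == pytest.approx(1.0)
        assert f[FIDX["homogeneity"]] == pytest.approx(0.5)
        assert f[FIDX["max_probability"]] == pytest.approx(0.5)

    def test_constant_image_degenerate_conventions(self):
        g = compute_glcm(np.full((6, 6), 1), (0, 1), num_levels=1)
        f = glcm_features(g)
        assert f[FIDX["energy"]] == 1.0
        assert f[FIDX["entropy"]] == 0.0
        assert f[FIDX["contrast"]] == 0.0
        assert f[FIDX["correlation"]] == 0.0  # sigma_x * sigma_y = 0 -> 0
        assert f[FIDX["max_probability"]] == 1.0

    def test_all_features_finite_and_bounded(self, rng):
        for _ in range(10):
            q = quantize(rng.integers(0, 256, size=(8, 8)), 8)
            f = glcm_features(compute_glcm(q, (0, 1), num_levels=8))
            assert np.isfinite(f).all()
            assert 0 < f[FIDX["energy"]] <= 1
            assert 0 < f[FIDX["max_probability"]] <= 1
            assert f[FIDX["entropy"]] >= 0


class TestSemivariogram:
    def test_constant_image_is_zero(self):
        prof = semivariogram(np.full((32, 32), 7), 10, "horizontal")
        assert (prof.gamma == 0).all()

    def test_horizontal_ramp_gives_half_h_squared(self):
        img = np.tile(np.arange(32.0), (32, 1))
        prof = semivariogram(img, 10, "horizontal")
        assert prof.gamma == pytest.approx([h**2 / 2 for h in range(1, 11)])
        vert = semivariogram(img, 10, "vertical")
        assert (vert.gamma == 0).all()

    def test_lag_exceeding_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            semivariogram(np.zeros((32, 10)), 10, "horizontal")

    def test_transpose_swaps_direction_blocks(self, rng):
        img = rng.integers(0, 256, size=(16, 20)).astype(float)
        f = sv_features(img)
        ft = sv_features(img.T)
        assert f[:10] == pytest.approx(ft[10:])
        assert f[10:] == pytest.approx(ft[:10])

    def test_shift_invariance_and_quadratic_scaling(self, rng):
        img = rng.integers(0, 200, size=(16, 16)).astype(float)
        base = sv_features(img)
        assert sv_features(img + 50.0) == pytest.approx(base)
        assert sv_features(3.0 * img) == pytest.approx(9.0 * base)


class TestLBP:
    def test_constant_image_code_255(self):
        # b(0) = 1: all eight zero differences set their bits
        assert lbp_code(np.full((5, 5), 7), (2, 2)) == 255

    def test_bright_center_code_zero(self):
        img = np.zeros((3, 3))
        img[1, 1] = 10
        assert lbp_code(img, (1, 1)) == 0

    def test_border_pixel_rejected(self):
        with pytest.raises(ValueError, match="border"):
            lbp_code(np.zeros((5, 5)), (0, 2))

    def test_histogram_of_constant_image(self):
        h = lbp_histogram(np.full((10, 10), 42))
        assert h[255] == 1.0
        assert h.sum() == pytest.approx(1.0)

    def test_histogram_normalization(self, rng):
        img = rng.integers(0, 256, size=(12, 12))
        h = lbp_histogram(img)
        assert h.shape == (256,)
        assert h.sum() == pytest.approx(1.0, abs=1e-12)

    def test_checkerboard_concentrates_on_two_codes(self):
        img = np.indices((6, 6)).sum(axis=0) % 2 * 255.0
        codes = lbp_codes(img)
        hist = np.bincount(codes.ravel(), minlength=256) / codes.size
        # two pixel roles -> at most two distinct codes, matching the oracle
        expected = {
            oracle_lbp_code(img.tolist(), r, c) for r in (1, 2) for c in (1, 2)
        }
        assert set(np.nonzero(hist)[0]) == expected
        assert len(expected) <= 2

    def test_codes_match_oracle_on_random_images(self, rng):
        for _ in range(25):
            img = rng.integers(0, 256, size=(5, 5)).astype(float)
            assert lbp_code(img, (2, 2)) == oracle_lbp_code(img.tolist(), 2, 2)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            LBPConfig(num_neighbors=0)
        with pytest.raises(ValueError):
            LBPConfig(radius=0)


class TestTranslationInvariance:
    def test_lbp_and_glcm_unchanged_by_shift_in_constant_border(self, rng):
        patch = rng.integers(0, 256, size=(6, 6))
        canvas1 = np.full((20, 20), 128)
        canvas2 = np.full((20, 20), 128)
        canvas1[4:10, 4:10] = patch
        canvas2[7:13, 9:15] = patch
        h1, h2 = lbp_histogram(canvas1), lbp_histogram(canvas2)
        assert h1 == pytest.approx(h2)
        g1 = glcm_features(compute_glcm(quantize(canvas1, 8), (0, 1), num_levels=8))
        g2 = glcm_features(compute_glcm(quantize(canvas2, 8), (0, 1), num_levels=8))
        assert g1 == pytest.approx(g2)
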