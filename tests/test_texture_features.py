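import numpy as np
import pytest

from phantomtex import (
    AcquisitionParams,
    FEATURE_FAMILIES,
    FEATURE_NAMES,
    EXTRA_NAMES,
    FeatureConfig,
    ImageSlice,
    ROIMask,
    extract_all,
    quantize,
)
from phantomtex.texture_features import (
    QuantizedROI,
    _glrl_direction_features,
    _glrl_matrix,
    glcm_features,
    glgm_features,
    glrl_features,
    histogram_features,
    laws_features,
)

from conftest import random_roi
from oracles import (
    naive_glcm_features,
    naive_glgm_features,
    naive_glrl_features,
    naive_laws_features,
)


def full_roi(levels, G):
    levels = np.asarray(levels, dtype=np.int32)
    return QuantizedROI(levels=levels, G=G, mask=ROIMask(np.ones(levels.shape, bool)))


class TestQuantize:
    def test_binary_extremes(self):
        mask = ROIMask(np.ones((1, 2), bool))
        roi = quantize(np.array([[0.0, 255.0]]), mask, G=2)
        assert roi.masked().tolist() == [0, 1]

    def test_constant_region_maps_to_zero(self):
        mask = ROIMask(np.ones((3, 3), bool))
        roi = quantize(np.full((3, 3), 42.0), mask, G=256)
        assert np.all(roi.levels == 0)

    def test_identity_on_full_range_8bit(self, rng):
        x = rng.integers(0, 256, (16, 16)).astype(float)
        x[0, 0], x[0, 1] = 0.0, 255.0  # pin the extremes
        roi = quantize(x, ROIMask(np.ones((16, 16), bool)), G=256)
        assert np.array_equal(roi.levels, x.astype(np.int32))


class TestHistogramFeatures:
    def test_hand_arithmetic_on_tiny_samples(self):
        roi = full_roi([[0, 1, 2]], G=3)
        f = histogram_features(roi, np.array([[1.0, 2.0, 3.0]]))
        assert f["hist_mean"] == pytest.approx(2.0)
        assert f["hist_median"] == pytest.approx(2.0)

        roi2 = full_roi([[0, 1]], G=2)
        f2 = histogram_features(roi2, np.array([[1.0, 4.0]]))
        assert f2["hist_geometric_mean"] == pytest.approx(2.0)

    def test_fourth_moment_of_gaussian(self, rng):
        x = rng.normal(250.0, 30.0, (200, 100))
        roi = quantize(x, ROIMask(np.ones(x.shape, bool)), G=256)
        f = histogram_features(roi, x)
        assert f["hist_fourth_moment"] == pytest.approx(3 * 30.0**4, rel=0.1)

    def test_uniform_histogram_entropy_is_8_bits(self):
        levels = np.arange(256).reshape(16, 16)
        f = histogram_features(full_roi(levels, 256), levels.astype(float))
        assert f["hist_entropy"] == pytest.approx(8.0)

    def test_local_statistics_on_constant_image(self):
        x = np.full((8, 8), 5.0)
        f = histogram_features(full_roi(np.zeros((8, 8)), 256), x)
        for name in ("hist_range", "hist_second_std", "hist_std5", "hist_std9"):
            assert f[name] == 0.0


class TestGlcmFeatures:
    def test_constant_roi_degenerate_values(self):
        with pytest.warns(RuntimeWarning, match="correlation"):
            f = glcm_features(full_roi(np.zeros((4, 4)), 4))
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_energy"] == 1.0
        assert f["glcm_homogeneity"] == 1.0
        assert f["glcm_entropy"] == 0.0
        assert np.isnan(f["glcm_correlation"])

    def test_alternating_row_by_hand(self):
        # single-row mask: only the horizontal direction contributes; every
        # adjacent pair is (0,1)/(1,0), so contrast 1 and homogeneity 0.5
        f = glcm_features(full_roi([[0, 1, 0, 1]], G=2))
        assert f["glcm_contrast"] == pytest.approx(1.0)
        assert f["glcm_homogeneity"] == pytest.approx(0.5)
        assert f["glcm_energy"] == pytest.approx(0.5)
        assert f["glcm_entropy"] == pytest.approx(np.log(2.0))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            roi = random_roi(rng)
            ours = glcm_features(roi)
            ref = naive_glcm_features(roi.levels, roi.mask.mask, roi.G)
            for k in FEATURE_FAMILIES["glcm"]:
                assert ours[k] == pytest.approx(ref[k], rel=1e-10, abs=1e-12)

    def test_matches_skimage_on_rectangular_roi(self, rng):
        # independent cross-check against scikit-image on a mask-free ROI
        from skimage.feature import graycomatrix, graycoprops

        levels = rng.integers(0, 8, (12, 12)).astype(np.uint8)
        roi = full_roi(levels, 8)
        ours = glcm_features(roi)
        glcm = graycomatrix(levels, [1], [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                            levels=8, symmetric=True, normed=True)
        p = glcm.mean(axis=3)[:, :, 0]
        assert ours["glcm_contrast"] == pytest.approx(
            float(np.mean(graycoprops(glcm, "contrast"))), rel=1e-8)
        assert ours["glcm_energy"] == pytest.approx(float(np.sum(p**2)), rel=1e-8)

    def test_rotation_invariance_on_square_mask(self, rng):
        levels = rng.integers(0, 6, (10, 10)).astype(np.int32)
        a = glcm_features(full_roi(levels, 6))
        b = glcm_features(full_roi(np.rot90(levels), 6))
        for k in FEATURE_FAMILIES["glcm"]:
            assert a[k] == pytest.approx(b[k], rel=1e-10)

    def test_noise_raises_contrast_and_lowers_homogeneity(self):
        # the mechanism behind NEX sensitivity: extra noise decorrelates
        # neighbors, raising contrast and lowering homogeneity in expectation
        wins_c = wins_h = 0
        base = np.add.outer(np.linspace(0, 60, 24), np.linspace(0, 60, 24))
        mask = ROIMask(np.ones(base.shape, bool))
        for seed in range(20):
            r = np.random.default_rng(seed)
            clean = base + r.normal(0, 2, base.shape)
            noisy = clean + r.normal(0, 10, base.shape)
            fc = glcm_features(quantize(clean, mask, 32))
            fn = glcm_features(quantize(noisy, mask, 32))
            wins_c += fn["glcm_contrast"] > fc["glcm_contrast"]
            wins_h += fn["glcm_homogeneity"] < fc["glcm_homogeneity"]
        assert wins_c >= 18 and wins_h >= 18


class TestGlrlFeatures:
    def test_constant_grid_horizontal_direction_by_hand(self):
        # 4x4 constant ROI, horizontal: 4 runs of length 4 in one cell
        roi = full_roi(np.zeros((4, 4)), G=2)
        mat = _glrl_matrix(roi, (0, 1))
        assert mat[0, 3] == 4 and mat.sum() == 4
        f = _glrl_direction_features(mat, n_pixels=16)
        assert f["glrl_sre"] == pytest.approx(1 / 16)
        assert f["glrl_lre"] == pytest.approx(16.0)
        assert f["glrl_rp"] == pytest.approx(0.25)

    def test_alternating_sequence_all_unit_runs(self):
        f = glrl_features(full_roi([[0, 1, 0, 1, 0, 1]], G=2))
        assert f["glrl_sre"] == pytest.approx(1.0)
        assert f["glrl_lre"] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            roi = random_roi(rng)
            ours = glrl_features(roi)
            ref = naive_glrl_features(roi.levels, roi.mask.mask, roi.G)
            for k in FEATURE_FAMILIES["glrl"]:
                assert ours[k] == pytest.approx(ref[k], rel=1e-10, abs=1e-12)

    def test_rotation_invariance_on_square_mask(self, rng):
        levels = rng.integers(0, 5, (9, 9)).astype(np.int32)
        a = glrl_features(full_roi(levels, 5))
        b = glrl_features(full_roi(np.rot90(levels), 5))
        for k in FEATURE_FAMILIES["glrl"]:
            assert a[k] == pytest.approx(b[k], rel=1e-10)


class TestGlgmFeatures:
    def test_constant_image_zero_gradient(self):
        x = np.full((6, 6), 7.0)
        with pytest.warns(RuntimeWarning, match="gradient"):
            f = glgm_features(full_roi(np.zeros((6, 6)), 2), x)
        assert f["glgm_mgr"] == 0.0 and f["glgm_vgr"] == 0.0
        assert np.isnan(f["glgm_skewness"]) and np.isnan(f["glgm_kurtosis"])

    def test_linear_ramp_constant_gradient(self):
        x = 3.0 * np.arange(8)[None, :] * np.ones((8, 1))
        with pytest.warns(RuntimeWarning):
            f = glgm_features(full_roi(np.zeros((8, 8)), 2), x)
        # Sobel response to slope c along columns is 8c at every interior pixel
        assert f["glgm_mgr"] == pytest.approx(24.0)
        assert f["glgm_vgr"] == pytest.approx(0.0, abs=1e-18)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            roi = random_roi(rng)
            pixels = rng.normal(100, 25, roi.levels.shape)
            ours = glgm_features(roi, pixels)
            ref = naive_glgm_features(pixels, roi.mask.mask)
            for k in FEATURE_FAMILIES["glgm"]:
                assert ours[k] == pytest.approx(ref[k], rel=1e-10, abs=1e-12)


class TestLawsFeatures:
    def test_constant_image_values(self):
        v = 11.0
        f = laws_features(full_roi(np.zeros((6, 6)), 2), np.full((6, 6), v))
        assert f["laws_l1"] == pytest.approx((16 * v) ** 2)
        for k in range(2, 10):
            assert f[f"laws_l{k}"] == pytest.approx(0.0, abs=1e-18)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            roi = random_roi(rng)
            pixels = rng.normal(100, 25, roi.levels.shape)
            ours = laws_features(roi, pixels)
            ref = naive_laws_features(pixels, roi.mask.mask)
            for k in FEATURE_FAMILIES["laws"]:
                assert ours[k] == pytest.approx(ref[k], rel=1e-10, abs=1e-12)


class TestExtractAll:
    @pytest.fixture
    def normalized_slice(self, rng):
        x = rng.normal(250.0, 30.0, (48, 40))
        slice_ = ImageSlice(x, (1.0, 1.0), AcquisitionParams(matrix=x.shape))
        mask = np.zeros(x.shape, bool)
        mask[4:-4, 4:-4] = True
        return slice_, ROIMask(mask)

    def test_inventory_41_core_plus_extras(self, normalized_slice):
        slice_, mask = normalized_slice
        f = extract_all(slice_, mask)
        assert len(FEATURE_NAMES) == 41
        assert [len(v) for v in FEATURE_FAMILIES.values()] == [12, 5, 11, 4, 9]
        assert set(FEATURE_NAMES) <= set(f)
        assert set(EXTRA_NAMES) <= set(f)
        assert all(np.isfinite(f[k]) for k in FEATURE_NAMES)

    def test_deterministic(self, normalized_slice):
        slice_, mask = normalized_slice
        assert extract_all(slice_, mask) == extract_all(slice_, mask)

    def test_extras_can_be_disabled(self, normalized_slice):
        slice_, mask = normalized_slice
        f = extract_all(slice_, mask, FeatureConfig(include_extras=False))
        assert set(f) == set(FEATURE_NAMES)

    def test_mean_laws_is_sum_of_family(self, normalized_slice):
        slice_, mask = normalized_slice
        f = extract_all(slice_, mask)
        assert f["mean_laws"] == pytest.approx(
            sum(f[k] for k in FEATURE_FAMILIES["laws"]), rel=1e-12)
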