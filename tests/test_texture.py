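"""The 43 texture features against brute-force enumerators and hand examples."""
import numpy as np
import pytest

from tumortopo import VoxelGrid
from tumortopo._types import QuantizedGrid
from tumortopo.preprocess import ExtractionParams
from tumortopo.texture import (
    FEATURE_NAMES,
    TextureFeatureExtractor,
    extract_all,
    glcm_features,
    glcm_matrix,
    global_features,
    glrlm_features,
    glrlm_matrix,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
    ngtdm_table,
)

from . import _oracles as O


def qg(levels, ng):
    return QuantizedGrid(np.asarray(levels, dtype=np.int64), ng)


class TestGlobal:
    def test_constant_volume_zero_variance(self):
        with pytest.warns(UserWarning):
            f = global_features(np.full((3, 3, 3), 7.0))
        assert f == {"Variance": 0.0, "Skewness": 0.0, "Kurtosis": 0.0}

    def test_two_point_distribution_moments(self):
        f = global_features(np.array([0.0, 0.0, 255.0, 255.0]).reshape(2, 2, 1))
        assert f["Variance"] == pytest.approx(16256.25)
        assert f["Skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_distribution_zero_skewness(self, rng):
        v = rng.standard_normal((9, 9, 9))
        v = np.concatenate([v, -v]).reshape(9, 9, 18)
        assert global_features(v)["Skewness"] == pytest.approx(0.0, abs=1e-10)


class TestGLCM:
    def test_constant_volume(self):
        f = glcm_features(qg(np.ones((3, 3, 3)), 4))
        assert f["Energy"] == 1.0
        assert f["Contrast"] == 0.0
        assert f["Dissimilarity"] == 0.0
        assert f["Homogeneity"] == 1.0
        assert f["Entropy"] == 0.0

    def test_2x2x1_hand_enumeration(self):
        # [[1,2],[1,2]]: of the 12 ordered voxel pairs, 4 along x are
        # same-level, 4 along y and 4 along the in-plane diagonals are
        # cross-level, so Contrast = 8/12.
        lv = np.array([[1, 2], [1, 2]]).reshape(2, 2, 1)
        p = glcm_matrix(qg(lv, 2))
        assert np.allclose(p, O.glcm_oracle(lv, 2))
        assert glcm_features(qg(lv, 2))["Contrast"] == pytest.approx(8 / 12)

    def test_entropy_nonnegative_zero_iff_constant(self, rng):
        lv = rng.integers(1, 4, (4, 4, 4))
        assert glcm_features(qg(lv, 4))["Entropy"] >= 0.0


class TestGLRLM:
    def test_alternating_line_all_runs_length_one(self):
        lv = np.array([1, 2] * 6).reshape(12, 1, 1)
        f = glrlm_features(qg(lv, 2))
        assert f["Short Run Emphasis"] == 1.0
        assert f["Long Run Emphasis"] == 1.0

    def test_constant_line_single_direction_long_run(self):
        n = 7
        lv = np.ones((n, 1, 1), dtype=int)
        f = glrlm_features(qg(lv, 2), directions=[(1, 0, 0)])
        assert f["Long Run Emphasis"] == pytest.approx(n**2)
        assert f["Run Percentage"] == pytest.approx(1.0 / n)

    def test_random_grid_matches_run_scanner(self, rng):
        for _ in range(10):
            lv = rng.integers(1, 4, (3, 3, 3))
            mine = glrlm_matrix(qg(lv, 3))
            theirs = O.glrlm_oracle(lv, 3)
            assert np.array_equal(mine, theirs)
            f = list(glrlm_features(qg(lv, 3)).values())
            o = O.run_zone_stats_oracle(theirs, lv.size, 13)
            np.testing.assert_allclose(f, o, rtol=1e-10)


class TestGLSZM:
    def test_constant_volume_one_zone(self):
        n = 4 * 4 * 4
        f = glszm_features(qg(np.ones((4, 4, 4)), 2))
        assert f["Large Zone Emphasis"] == pytest.approx(n**2)
        assert f["Zone Percentage"] == pytest.approx(1.0 / n)

    def test_checkerboard_against_labelling_oracle(self):
        # under 26-connectivity diagonal same-level neighbors merge, so the
        # two checkerboard phases form two large zones
        idx = np.indices((4, 4, 4)).sum(axis=0)
        lv = (idx % 2) + 1
        assert np.array_equal(glszm_matrix(qg(lv, 2)), O.glszm_oracle(lv, 2))

    def test_random_grid_matches_flood_fill(self, rng):
        for _ in range(10):
            lv = rng.integers(1, 5, (4, 4, 4))
            mine = glszm_matrix(qg(lv, 4))
            theirs = O.glszm_oracle(lv, 4)
            assert np.array_equal(mine, theirs)


class TestNGTDM:
    def test_constant_volume(self):
        f = ngtdm_features(qg(np.ones((3, 3, 3)), 2))
        assert f["Contrast"] == 0.0
        assert f["Busyness"] == 0.0

    def test_single_bright_voxel_hand_computed(self):
        lv = np.ones((3, 3, 3), dtype=int)
        lv[1, 1, 1] = 2
        p, s = ngtdm_table(qg(lv, 2))
        assert p[0] == pytest.approx(26 / 27)
        assert p[1] == pytest.approx(1 / 27)
        # center: 26 neighbors all level 1 -> s_2 = 1; level-1 voxels see the
        # center from corners (7 nbs), edges (11 nbs) and faces (17 nbs)
        assert s[1] == pytest.approx(1.0)
        assert s[0] == pytest.approx(8 / 7 + 12 / 11 + 6 / 17)

    def test_coarseness_decreases_with_noise(self):
        from tumortopo.phantoms import PhantomSpec, generate_phantom
        from tumortopo.preprocess import quantize_equal_probability

        vals = []
        for noise in (2.0, 25.0):
            spec = PhantomSpec("x", shape=(16, 16, 8), noise_sd=noise, seed=5)
            g = generate_phantom(spec)
            f = ngtdm_features(quantize_equal_probability(g.values, 16))
            vals.append(f["Coarseness"])
        assert vals[1] < vals[0]


class TestExtractAll:
    def test_43_finite_features_in_table_order(self, random_volume):
        vec = extract_all(random_volume, ExtractionParams(1.5, 3.0, 8, "lloyd-max"))
        assert vec.values.shape == (43,)
        assert np.all(np.isfinite(vec.values))
        assert len(FEATURE_NAMES) == 43 and len(set(FEATURE_NAMES)) == 43

    def test_deterministic(self, random_volume):
        p = ExtractionParams(0.5, None, 16, "equal-probability")
        a = extract_all(random_volume, p).values
        b = extract_all(random_volume, p).values
        assert np.array_equal(a, b)

    def test_axis_permutation_invariance_isotropic(self, rng):
        v = rng.random((7, 7, 7)) * 255
        p = ExtractionParams(2.0, 1.0, 8, "equal-probability")
        base = extract_all(VoxelGrid(v, (1.0, 1.0, 1.0)), p).values
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            other = extract_all(VoxelGrid(np.transpose(v, perm), (1.0, 1.0, 1.0)), p).values
            np.testing.assert_allclose(other, base, rtol=1e-8)

    def test_transformer_matches_function(self, random_volume):
        est = TextureFeatureExtractor(wavelet_ratio=1.0, n_gray_levels=8)
        X = est.fit_transform([random_volume, random_volume])
        assert X.shape == (2, 43)
        direct = extract_all(random_volume, est._extraction_params()).values
        assert np.array_equal(X[0], direct)


class TestMatrixInvariants:
    def test_glcm_normalized_and_emphases_positive(self, rng):
        lv = rng.integers(1, 5, (4, 4, 3))
        assert glcm_matrix(qg(lv, 4)).sum() == pytest.approx(1.0)
        rl = glrlm_features(qg(lv, 4))
        assert 0 < rl["Run Percentage"] <= 1.0
        assert rl["Short Run Emphasis"] > 0 and rl["High GL Run Emphasis"] > 0
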