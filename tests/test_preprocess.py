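"""Normalization, resampling, wavelet filtering and quantization."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumortopo import VoxelGrid
from tumortopo.preprocess import (
    ExtractionParams,
    normalize_to_255,
    param_grid,
    quantize_equal_probability,
    quantize_lloyd_max,
    resample_isotropic,
    wavelet_bandpass,
)


class TestNormalize:
    def test_linear_map_endpoints_and_midpoint(self):
        g = VoxelGrid(np.array([10.0, 20.0, 30.0]).reshape(3, 1, 1))
        out = normalize_to_255(g).values.ravel()
        assert np.allclose(out, [0.0, 127.5, 255.0])

    def test_identity_when_already_full_range(self, rng):
        v = rng.random((4, 4, 4)) * 255.0
        v.flat[0], v.flat[1] = 0.0, 255.0
        out = normalize_to_255(VoxelGrid(v))
        assert np.allclose(out.values, v)

    def test_constant_input_maps_to_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_to_255(VoxelGrid(np.full((3, 3, 3), 9.0)))
        assert np.all(out.values == 0.0)

    def test_order_preserved_and_idempotent(self, random_volume):
        out = normalize_to_255(random_volume)
        assert out.values.min() == 0.0 and out.values.max() == 255.0
        # rank comparison against the input
        assert np.array_equal(
            np.argsort(out.values.ravel(), kind="stable"),
            np.argsort(random_volume.values.ravel(), kind="stable"),
        )
        again = normalize_to_255(out)
        assert np.allclose(again.values, out.values)


class TestResample:
    def test_native_isotropic_is_identity(self, rng):
        g = VoxelGrid(rng.random((5, 5, 5)), spacing=(2.0, 2.0, 2.0))
        out = resample_isotropic(g, 2.0)
        assert out.shape == g.shape and np.allclose(out.values, g.values)

    def test_ramp_along_z_closed_form(self):
        # 5 samples at 3 mm -> 15 samples at 1 mm: values j/3, clamped past
        # the last voxel center
        g = VoxelGrid(np.arange(5.0).reshape(1, 1, 5), spacing=(1.0, 1.0, 3.0))
        out = resample_isotropic(g, 1.0)
        expected = np.minimum(np.arange(15) / 3.0, 4.0)
        assert out.shape == (1, 1, 15)
        assert np.allclose(out.values.ravel(), expected)
        assert out.spacing == (1.0, 1.0, 1.0)

    def test_constant_stays_constant(self):
        g = VoxelGrid(np.full((6, 6, 4), 3.5), spacing=(1.5, 1.5, 3.0))
        for iso in (None, 1.0, 2.0, 5.0):
            assert np.allclose(resample_isotropic(g, iso).values, 3.5)

    def test_native_option_resamples_z_only(self):
        g = VoxelGrid(np.zeros((8, 8, 4)), spacing=(1.25, 1.25, 3.0))
        out = resample_isotropic(g, None)
        assert out.spacing == (1.25, 1.25, 1.25)
        assert out.shape[:2] == (8, 8)
        # physical extent along z preserved to within one voxel
        assert abs(out.shape[2] * 1.25 - 4 * 3.0) <= 1.25

    def test_invalid_iso_voxel(self, random_volume):
        with pytest.raises(ValueError):
            resample_isotropic(random_volume, -1.0)


class TestWaveletBandpass:
    def test_unit_ratio_is_identity(self, random_volume):
        out = wavelet_bandpass(random_volume, 1.0)
        assert np.allclose(out.values, random_volume.values, atol=1e-10)

    def test_constant_volume_unchanged_for_any_ratio(self):
        g = VoxelGrid(np.full((8, 8, 8), 42.0))
        for r in (0.5, 2 / 3, 1.5, 2.0):
            assert np.allclose(wavelet_bandpass(g, r).values, 42.0, atol=1e-9)

    def test_linearity_in_input(self, random_volume):
        out1 = wavelet_bandpass(random_volume, 2.0).values
        out3 = wavelet_bandpass(
            random_volume.with_values(3.0 * random_volume.values), 2.0
        ).values
        assert np.allclose(out3, 3.0 * out1, atol=1e-8)

    def test_axis_shorter_than_filter_support_raises(self):
        with pytest.raises(ValueError, match="axis"):
            wavelet_bandpass(VoxelGrid(np.zeros((8, 8, 3))), 2.0)


class TestQuantizers:
    def test_equal_probability_exact_quartiles(self):
        v = np.arange(1.0, 101.0).reshape(10, 5, 2)
        q = quantize_equal_probability(v, 4)
        counts = np.bincount(q.levels.ravel())[1:]
        assert np.array_equal(counts, [25, 25, 25, 25])
        assert q.levels.min() == 1 and q.levels.max() == 4

    def test_constant_input_single_level(self):
        for fn in (quantize_equal_probability, quantize_lloyd_max):
            q = fn(np.full((3, 3, 3), 5.0), 8)
            assert np.all(q.levels == 1)

    @pytest.mark.parametrize("transform", [np.exp, lambda x: x**3, lambda x: 10 + 2 * x])
    def test_equal_probability_monotone_invariance(self, rng, transform):
        v = rng.random((6, 6, 6)) * 4 - 2
        q1 = quantize_equal_probability(v, 8).levels
        q2 = quantize_equal_probability(transform(v), 8).levels
        assert np.array_equal(q1, q2)

    def test_quantizers_preserve_intensity_order(self, rng):
        v = rng.random((5, 5, 5))
        for fn in (quantize_equal_probability, quantize_lloyd_max):
            lv = fn(v, 8).levels.ravel()
            order = np.argsort(v.ravel())
            assert np.all(np.diff(lv[order]) >= 0)

    def test_lloyd_max_two_valued_is_exact(self):
        v = np.array([0.0, 255.0] * 32).reshape(4, 4, 4)
        q = quantize_lloyd_max(v, 2)
        assert set(np.unique(q.levels)) == {1, 2}
        assert np.all((q.levels == 2) == (v == 255.0))

    def test_lloyd_max_uniform_fixed_point(self, rng):
        # uniform density, 2 levels: centroids 1/4 and 3/4
        v = rng.random((40, 40, 25))
        q = quantize_lloyd_max(v, 2)
        c1 = v[q.levels == 1].mean()
        c2 = v[q.levels == 2].mean()
        assert abs(c1 - 0.25) < 0.02 and abs(c2 - 0.75) < 0.02


class TestExtractionParams:
    def test_grid_census_is_240(self):
        grid = param_grid()
        assert len(grid) == 240
        assert len(set(grid)) == 240

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ExtractionParams(wavelet_ratio=0.0)
        with pytest.raises(ValueError):
            ExtractionParams(quant_algorithm="median-cut")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_normalization_monotone_property(self, seed):
        v = np.random.default_rng(seed).random((3, 3, 3))
        out = normalize_to_255(VoxelGrid(v)).values
        a, b = v.ravel()[:2], out.ravel()[:2]
        assert (a[0] <= a[1]) == (b[0] <= b[1])
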