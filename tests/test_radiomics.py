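import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readiff.errors import FeatureError, QuantizationError
from readiff.preprocess import zscore_roi
from readiff.radiomics import (FAMILY_COUNTS, FEATURE_FAMILIES, FEATURE_NAMES,
                               QuantizedRoi, extract_all, quantize, registry_json)
from readiff.radiomics import filters as rfilters
from readiff.radiomics import glcm as rglcm
from readiff.radiomics import histogram as rhist
from readiff.radiomics import matrices as rmat
from readiff.radiomics.extractor import RadiomicFeatureExtractor

from conftest import make_roi
import oracles


class TestQuantize:
    def test_identity_when_levels_match(self):
        roi = make_roi(np.arange(32, dtype=float).reshape(4, 8))
        q = quantize(roi, Ng=32)
        assert np.array_equal(q.levels, np.arange(32).reshape(4, 8))

    def test_two_values_two_levels(self):
        roi = make_roi(np.array([[0.0, 10.0], [0.0, 10.0]]))
        q = quantize(roi, Ng=2)
        assert set(q.levels.ravel()) == {0, 1}

    def test_uniform_patch_occupies_all_levels(self, rng):
        roi = make_roi(rng.random((128, 128)))
        q = quantize(roi, Ng=8)
        freqs = np.bincount(q.levels[q.valid].ravel(), minlength=8) / q.valid.sum()
        assert (freqs >= 0.01).all()

    def test_constant_errors(self):
        with pytest.raises(QuantizationError):
            quantize(make_roi(np.full((4, 4), 2.0)), Ng=8)


class TestHistogram:
    def test_constant_patch_degenerate_stats(self):
        f = dict(zip(rhist.HISTOGRAM_NAMES, rhist.histogram_features(make_roi(np.full((6, 6), 5.0)))))
        assert f["sd"] == 0.0 and f["entropy"] == 0.0 and f["uniformity"] == 1.0

    def test_small_patch_hand_values(self):
        f = dict(zip(rhist.HISTOGRAM_NAMES,
                     rhist.histogram_features(make_roi(np.array([[1.0, 2.0], [3.0, 4.0]])))))
        assert f["mean"] == 2.5
        assert f["iqr"] == pytest.approx(1.5)     # p75=3.25, p25=1.75 (linear interp)
        assert f["median"] == 2.5
        assert f["min"] == 1.0 and f["max"] == 4.0 and f["range"] == 3.0

    def test_symmetric_patch_zero_skewness(self):
        vals = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        f = dict(zip(rhist.HISTOGRAM_NAMES, rhist.histogram_features(make_roi(vals))))
        assert abs(f["skewness"]) < 1e-12


class TestGlcm:
    def test_checkerboard_hand_matrix(self):
        levels = np.array([[0, 1], [1, 0]])
        q = QuantizedRoi(levels=levels, Ng=2, valid=np.ones((2, 2), bool))
        P = rglcm.cooccurrence(q, (0, 1))
        assert P[0, 1] == 0.5 and P[1, 0] == 0.5 and P[0, 0] == 0.0
        stats = dict(zip(rglcm.GLCM_STAT_NAMES, rglcm.glcm_stats(P)))
        assert stats["contrast"] == 1.0

    def test_constant_patch_degenerate(self):
        q = QuantizedRoi(levels=np.zeros((5, 5), np.int64), Ng=4, valid=np.ones((5, 5), bool))
        feats = dict(zip(rglcm.GLCM_NAMES, rglcm.glcm_features(q)))
        for deg in (0, 45, 90, 135):
            assert feats[f"glcm_{deg}deg_contrast"] == 0.0
            assert feats[f"glcm_{deg}deg_max_probability"] == 1.0

    def test_transpose_swaps_0_and_90(self, rng):
        levels = rng.integers(0, 6, (16, 16))
        q = QuantizedRoi(levels=levels, Ng=6, valid=np.ones((16, 16), bool))
        qt = QuantizedRoi(levels=levels.T.copy(), Ng=6, valid=np.ones((16, 16), bool))
        f = rglcm.glcm_features(q).reshape(4, -1)
        ft = rglcm.glcm_features(qt).reshape(4, -1)
        np.testing.assert_allclose(ft[0], f[2], atol=1e-12)  # 0 deg <-> 90 deg
        np.testing.assert_allclose(ft[2], f[0], atol=1e-12)
        np.testing.assert_allclose(ft[1], f[1], atol=1e-12)  # 45, 135 unchanged
        np.testing.assert_allclose(ft[3], f[3], atol=1e-12)

    def test_matches_skimage_on_valid_patch(self, rng):
        """Cross-check the co-occurrence counts against skimage."""
        from skimage.feature import graycomatrix

        levels = rng.integers(0, 8, (12, 12))
        q = QuantizedRoi(levels=levels, Ng=8, valid=np.ones((12, 12), bool))
        ours = rglcm.cooccurrence(q, (0, 1))
        theirs = graycomatrix(levels.astype(np.uint8), [1], [0], levels=8,
                              symmetric=True, normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestGlrlm:
    def test_single_row_hand_runs(self):
        levels = np.array([[0, 0, 1, 1, 1]])
        valid = np.ones((1, 5), bool)
        runs = rmat.run_lengths(levels, valid, (0, 1))
        assert sorted(runs) == [(0, 2), (1, 3)]
        feats = rmat._glrlm_direction(runs, n_pixels=5)
        assert feats[4] == pytest.approx(2 / 5)  # run percentage

    def test_runs_broken_by_invalid(self):
        levels = np.array([[1, 1, 1, 1]])
        valid = np.array([[True, True, False, True]])
        runs = rmat.run_lengths(levels, valid, (0, 1))
        assert sorted(runs) == [(1, 1), (1, 2)]


class TestNgtdmLawsFractal:
    def test_constant_patch_ngtdm_contrast_zero(self):
        q = QuantizedRoi(levels=np.zeros((9, 9), np.int64), Ng=4, valid=np.ones((9, 9), bool))
        feats = dict(zip(rmat.NGTDM_NAMES, rmat.ngtdm_features(q)))
        for w in (3, 5, 7):
            assert feats[f"ngtdm_w{w}_contrast"] == 0.0

    def test_constant_patch_laws_energy_zero(self):
        feats = dict(zip(rfilters.LAWS_NAMES, rfilters.laws_features(make_roi(np.full((12, 12), 3.0)))))
        assert feats["laws_E5E5_mean"] == pytest.approx(0.0, abs=1e-10)
        assert feats["laws_S5S5_mean"] == pytest.approx(0.0, abs=1e-10)

    def test_fractal_dimension_extremes(self, rng):
        filled = rfilters.box_counting_dimension(np.ones((64, 64), bool))
        assert filled == pytest.approx(2.0, abs=0.1)
        dots = np.zeros((64, 64), bool)
        idx = rng.integers(0, 64, (2, 40))
        dots[idx[0], idx[1]] = True
        sparse = rfilters.box_counting_dimension(dots)
        assert sparse < 2.0


class TestTransformFamilies:
    def test_white_noise_gabor_isotropy(self, rng):
        roi = make_roi(rng.normal(size=(128, 128)))
        g = rfilters.gabor_features(roi).reshape(2, 3)  # (frequency, orientation)
        for row in g:
            assert row.max() / row.min() < 1.10

    def test_constant_patch_mr8_zero_energy(self):
        feats = rfilters.rfs_features(make_roi(np.full((40, 40), 2.0)))
        assert np.allclose(feats, 0.0, atol=1e-12)

    def test_tuned_sinusoid_dominates_orientation(self):
        cols = np.arange(64)
        img = np.tile(np.sin(2 * np.pi * 0.25 * cols), (64, 1))
        g = rfilters.gabor_features(make_roi(img))
        names = rfilters.GABOR_NAMES
        assert names[int(np.argmax(g))] == "gabor_f0.25_t0"

    def test_small_roi_rejected_by_mr8(self):
        with pytest.raises(FeatureError):
            rfilters.rfs_features(make_roi(np.random.default_rng(0).random((10, 10))))

    def test_fourier_hf_fraction_orders_smooth_vs_noise(self, rng):
        from scipy import ndimage

        noise = rng.normal(size=(64, 64))
        smooth = ndimage.gaussian_filter(noise, 4)
        f_noise = rfilters.fourier_features(make_roi(noise))
        f_smooth = rfilters.fourier_features(make_roi(smooth))
        assert f_noise[1] > f_smooth[1]          # more high-frequency power
        assert f_smooth[0] < f_noise[0]          # steeper spectral decay


# ---------------------------------------------------------------- oracles

def _random_quantized(seed, size=8, Ng=4, masked=True):
    rng = np.random.default_rng(seed)
    levels = rng.integers(0, Ng, (size, size))
    valid = rng.random((size, size)) > 0.2 if masked else np.ones((size, size), bool)
    if not valid.any():
        valid[0, 0] = True
    return QuantizedRoi(levels=levels, Ng=Ng, valid=valid)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_glcm_matches_naive_oracle(seed):
    q = _random_quantized(seed)
    for deg, off in oracles.OFFSETS.items():
        expected = oracles.naive_cooccurrence(q.levels, q.valid, off, q.Ng)
        if expected.sum() == 0:
            continue
        np.testing.assert_allclose(rglcm.cooccurrence(q, off), expected, atol=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_glrlm_matches_naive_oracle(seed):
    q = _random_quantized(seed)
    for off in oracles.OFFSETS.values():
        ours = sorted(rmat.run_lengths(q.levels, q.valid, off))
        theirs = sorted(oracles.naive_runs(q.levels, q.valid, off))
        assert ours == theirs


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_glds_matches_naive_oracle(seed):
    q = _random_quantized(seed)
    for d in (1, 2, 4):
        expected = np.zeros(q.Ng)
        for off in oracles.OFFSETS.values():
            expected += oracles.naive_abs_diff_hist(q.levels, q.valid, (off[0] * d, off[1] * d), q.Ng)
        got = np.zeros(q.Ng)
        for off in oracles.OFFSETS.values():
            diffs = rmat._abs_diffs(q, (off[0] * d, off[1] * d))
            if diffs.size:
                got += np.bincount(diffs, minlength=q.Ng)
        np.testing.assert_allclose(got, expected)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_ngtdm_matches_naive_oracle(seed):
    q = _random_quantized(seed)
    for window in (3, 5, 7):
        if q.levels.shape[0] < window:
            continue
        s_naive, n_naive = oracles.naive_ngtdm(q.levels, q.valid, window, q.Ng)
        if n_naive.sum() == 0:
            continue
        s_ours, n_ours = rmat._ngtdm_arrays(q, window)
        np.testing.assert_allclose(n_ours, n_naive)
        np.testing.assert_allclose(s_ours, s_naive, atol=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_sfm_matches_naive_oracle(seed):
    q = _random_quantized(seed)
    rng = np.random.default_rng(seed + 1)
    for _ in range(4):
        off = (int(rng.integers(0, 5)), int(rng.integers(-4, 5)))
        if off == (0, 0):
            continue
        np.testing.assert_allclose(
            np.nan_to_num(np.array(rmat.sfm_delta_stats(q, off), dtype=float)),
            np.nan_to_num(np.array(oracles.naive_delta_stats(q.levels, q.valid, off), dtype=float)),
        )


# ---------------------------------------------------------------- extract_all

class TestExtractAll:
    def test_family_counts(self, textured_patch):
        fv = extract_all(textured_patch)
        assert len(fv) == 203
        counts = {}
        for fam in fv.families:
            counts[fam] = counts.get(fam, 0) + 1
        assert counts == FAMILY_COUNTS
        assert np.isfinite(fv.values).all()

    def test_repeat_call_bit_identical(self, textured_patch):
        a = extract_all(textured_patch)
        b = extract_all(textured_patch)
        assert np.array_equal(a.values, b.values)

    def test_affine_invariance_after_zscore(self, textured_patch):
        other = make_roi(3.7 * textured_patch.pixels + 11.0)
        fa = extract_all(zscore_roi(textured_patch)).values
        fb = extract_all(zscore_roi(other)).values
        np.testing.assert_allclose(fa, fb, rtol=1e-6, atol=1e-6)

    def test_invariant_to_invalid_padding(self, textured_patch):
        padded_pixels = np.zeros((60, 60))
        padded_valid = np.zeros((60, 60), dtype=bool)
        padded_pixels[6:54, 6:54] = textured_patch.pixels
        padded_valid[6:54, 6:54] = True
        padded = make_roi(padded_pixels, padded_valid)
        np.testing.assert_array_equal(extract_all(padded).values,
                                      extract_all(textured_patch).values)

    def test_constant_roi_errors(self):
        with pytest.raises(QuantizationError):
            extract_all(make_roi(np.full((40, 40), 1.0)))

    def test_registry_export(self):
        import json

        reg = json.loads(registry_json())
        assert len(reg) == 203
        assert [r["name"] for r in reg] == FEATURE_NAMES
        assert [r["family"] for r in reg] == FEATURE_FAMILIES

    def test_sklearn_transformer_interface(self, textured_patch, rng):
        from scipy import ndimage

        other = make_roi(ndimage.gaussian_filter(rng.normal(size=(48, 48)), 3.0))
        ext = RadiomicFeatureExtractor()
        df = ext.fit_transform([textured_patch, other])
        assert df.shape == (2, 203)
        assert list(df.columns) == FEATURE_NAMES
        assert ext.get_params()["Ng"] == 32
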