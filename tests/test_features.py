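"""Texture-feature unit and property tests against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lritex.features import (
    FEATURE_NAMES,
    FeatureConfig,
    GrayLevelROI,
    cooccurrence_matrix,
    feature_vector,
    glcm_features,
    global_stats,
    glrlm_features,
    ngtdm,
    ngtdm_contrast,
    resample_gray_levels,
    run_length_matrices,
)
from lritex.features import RLM_DIRECTIONS, _run_length_features_single

from oracles import (
    glcm_features_oracle,
    glcm_oracle,
    glrlm_features_oracle,
    glrlm_oracle,
    ngtdm_contrast_oracle,
    ngtdm_oracle,
)

from conftest import random_gray_roi


def as_gl(levels, s_bits=5):
    levels = np.asarray(levels, dtype=np.int64)
    return GrayLevelROI(levels=levels, s_bits=s_bits, original_min=0, original_max=0)


class TestResampling:
    def test_constant_roi_maps_to_level_one(self):
        gl = resample_gray_levels(np.full((5, 5), 123))
        assert np.all(gl.levels == 1)

    def test_full_range_endpoints(self):
        # intensities 0..99 at 5 bits: 0 -> 1 and 99 -> 32
        pixels = np.arange(100).reshape(10, 10)
        gl = resample_gray_levels(pixels, 5)
        assert gl.levels.min() == 1
        assert gl.levels.max() == 32
        assert gl.levels[0, 0] == 1
        assert gl.levels[-1, -1] == 32

    def test_monotone_in_intensity(self, rng):
        pixels = rng.integers(0, 5000, size=(12, 12))
        gl = resample_gray_levels(pixels, 5)
        order = np.argsort(pixels.ravel())
        assert np.all(np.diff(gl.levels.ravel()[order]) >= 0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        arrays(
            np.int64,
            st.tuples(st.integers(2, 6), st.integers(2, 6)),
            elements=st.integers(0, 65535),
        )
    )
    def test_levels_always_within_alphabet(self, pixels):
        gl = resample_gray_levels(pixels, 5)
        assert gl.levels.min() >= 1
        assert gl.levels.max() <= 32
        if pixels.max() - pixels.min() >= 32:
            assert gl.levels.min() == 1 and gl.levels.max() == 32


class TestCooccurrence:
    def test_constant_roi_concentrates_on_diagonal(self):
        m = cooccurrence_matrix(as_gl(np.ones((4, 4))))
        assert m.p[0, 0] == pytest.approx(1.0)
        assert m.p.sum() == pytest.approx(1.0)

    def test_two_by_two_matches_pair_enumeration(self):
        levels = np.array([[1, 1], [2, 2]])
        m = cooccurrence_matrix(as_gl(levels))
        np.testing.assert_allclose(m.p, glcm_oracle(levels, 32), rtol=0, atol=1e-15)

    def test_matches_bruteforce_oracle_on_random_rois(self, rng):
        for _ in range(100):
            levels = random_gray_roi(rng)
            m = cooccurrence_matrix(as_gl(levels))
            oracle = glcm_oracle(levels, 32)
            np.testing.assert_allclose(m.p, oracle, rtol=1e-12, atol=1e-15)
            assert m.p.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(m.p, m.p.T, rtol=0, atol=1e-15)

    def test_matches_skimage_cross_check(self, rng):
        # independent library route: skimage distance-1 symmetric GLCMs
        from skimage.feature import graycomatrix

        levels = random_gray_roi(rng)
        m = cooccurrence_matrix(as_gl(levels))
        sk = graycomatrix(
            (levels - 1).astype(np.uint8),
            distances=[1],
            angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
            levels=32,
            symmetric=True,
            normed=True,
        )
        np.testing.assert_allclose(m.p, sk[:, :, 0, :].mean(axis=2), rtol=1e-12, atol=1e-15)

    def test_too_small_roi_raises(self):
        with pytest.raises(ValueError):
            cooccurrence_matrix(as_gl(np.array([[1, 2, 3]])))


class TestGLCMFeatures:
    def test_constant_roi_degenerate_values(self):
        f = glcm_features(cooccurrence_matrix(as_gl(np.ones((4, 4)))))
        assert f["angular_second_moment"] == pytest.approx(1.0)
        assert f["contrast_glcm"] == pytest.approx(0.0)
        assert f["correlation"] == 0.0

    def test_uniform_two_level_closed_form(self):
        p = np.zeros((32, 32))
        p[:2, :2] = 0.25
        f = glcm_features(p)
        assert f["angular_second_moment"] == pytest.approx(0.25)
        assert f["contrast_glcm"] == pytest.approx(0.5)
        assert f["correlation"] == pytest.approx(0.0, abs=1e-15)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError):
            glcm_features(np.full((4, 4), 0.5))

    def test_matches_direct_sum_oracle(self, rng):
        for _ in range(50):
            levels = random_gray_roi(rng)
            p = cooccurrence_matrix(as_gl(levels)).p
            f = glcm_features(p)
            o = glcm_features_oracle(p)
            for name in f:
                assert f[name] == pytest.approx(o[name], rel=1e-12, abs=1e-12)


class TestRunLength:
    def test_hand_enumerated_row(self):
        rlm = run_length_matrices(as_gl(np.array([[1, 1, 2, 2, 2]])))
        r0 = rlm.matrices[0]
        assert r0[0, 1] == 1  # level 1, run length 2
        assert r0[1, 2] == 1  # level 2, run length 3
        assert r0.sum() == 2

    def test_constant_roi_single_runs(self):
        rlm = run_length_matrices(as_gl(np.ones((4, 7))))
        assert rlm.matrices[0][0, 6] == 4  # 4 rows of one length-7 run

    def test_pixel_conservation_all_directions(self, rng):
        levels = random_gray_roi(rng)
        rlm = run_length_matrices(as_gl(levels))
        j = np.arange(1, max(levels.shape) + 1)
        for d in RLM_DIRECTIONS:
            assert (rlm.matrices[d] * j[None, :]).sum() == levels.size

    def test_matches_scanline_oracle_on_random_rois(self, rng):
        for _ in range(100):
            levels = random_gray_roi(rng)
            rlm = run_length_matrices(as_gl(levels))
            for d in RLM_DIRECTIONS:
                np.testing.assert_array_equal(rlm.matrices[d], glrlm_oracle(levels, 32, d))


class TestRunLengthFeatures:
    def test_single_row_closed_forms(self):
        rlm = run_length_matrices(as_gl(np.array([[1, 1, 2, 2, 2]])))
        f0 = _run_length_features_single(rlm.matrices[0], rlm.n_pixels)
        assert f0["sre"] == pytest.approx(13 / 72)
        assert f0["rp"] == pytest.approx(2 / 5)

    def test_constant_roi_sre_closed_form(self):
        n, m = 5, 8
        rlm = run_length_matrices(as_gl(np.ones((n, m))))
        f0 = _run_length_features_single(rlm.matrices[0], rlm.n_pixels)
        assert f0["sre"] == pytest.approx(1 / m**2)
        assert f0["lre"] == pytest.approx(m**2)

    def test_all_eleven_match_literal_formula_oracle(self, rng):
        for _ in range(100):
            levels = random_gray_roi(rng)
            rlm = run_length_matrices(as_gl(levels))
            feats = glrlm_features(rlm)
            per_dir = [
                glrlm_features_oracle(glrlm_oracle(levels, 32, d), levels.size)
                for d in RLM_DIRECTIONS
            ]
            for name in feats:
                expect = np.mean([p[name] for p in per_dir])
                assert feats[name] == pytest.approx(expect, rel=1e-12)


class TestNGTDM:
    def test_constant_roi_all_zero(self):
        v = ngtdm(as_gl(np.ones((5, 5))), 1)
        assert np.all(v.s == 0)
        assert ngtdm_contrast(v) == 0.0

    def test_single_bright_pixel_hand_enumeration(self):
        levels = np.ones((4, 4), dtype=np.int64)
        levels[1, 1] = 2
        v = ngtdm(as_gl(levels), 1)
        assert v.n == 4
        assert v.s[1] == pytest.approx(1.0)
        assert v.s[0] == pytest.approx(3 / 8)
        np.testing.assert_allclose(v.p[:2], [3 / 4, 1 / 4])
        assert ngtdm_contrast(v) == pytest.approx(33 / 512)

    def test_too_small_roi_raises(self):
        with pytest.raises(ValueError):
            ngtdm(as_gl(np.ones((2, 4))), 1)

    def test_matches_per_pixel_oracle_on_random_rois(self, rng):
        for _ in range(100):
            levels = random_gray_roi(rng)
            v = ngtdm(as_gl(levels), 1)
            s, counts, n = ngtdm_oracle(levels, 32, 1)
            np.testing.assert_allclose(v.s, s, rtol=1e-12, atol=1e-12)
            np.testing.assert_array_equal(v.counts, counts)
            assert v.n == n
            assert ngtdm_contrast(v) == pytest.approx(
                ngtdm_contrast_oracle(s, counts, n), rel=1e-12, abs=1e-15
            )


class TestGlobalStats:
    def test_constant_roi(self):
        f = global_stats(np.full((3, 3), 7.0))
        assert (f["intensity_max"], f["intensity_min"], f["intensity_mean"]) == (7, 7, 7)
        assert f["intensity_sd"] == 0 and f["skewness"] == 0 and f["kurtosis"] == 0

    def test_small_symmetric_sample(self):
        f = global_stats(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["intensity_mean"] == pytest.approx(2.5)
        assert f["intensity_sd"] == pytest.approx(np.sqrt(1.25))
        assert f["skewness"] == pytest.approx(0.0, abs=1e-14)

    def test_gaussian_kurtosis_is_noncentral_three(self, rng):
        x = rng.standard_normal(200_000)
        f = global_stats(x)
        assert f["kurtosis"] == pytest.approx(3.0, abs=0.1)


class TestFeatureVector:
    def test_default_vector_has_21_named_features_in_order(self, rng):
        fv = feature_vector(rng.integers(0, 1000, size=(20, 20)))
        assert list(fv) == list(FEATURE_NAMES)
        assert len(fv) == 21

    def test_optional_coarseness_appends_22nd(self, rng):
        fv = feature_vector(
            rng.integers(0, 1000, size=(20, 20)), FeatureConfig(include_coarseness=True)
        )
        assert len(fv) == 22 and list(fv)[-1] == "ngtdm_coarseness"

    def test_constant_roi_degenerate_vector(self):
        fv = feature_vector(np.full((20, 20), 42))
        assert fv["angular_second_moment"] == 1.0
        assert fv["contrast_glcm"] == 0.0
        assert fv["ngtdm_contrast"] == 0.0
        assert fv["intensity_sd"] == 0.0
        assert np.isfinite(list(fv.values())).all()

    def test_composition_equals_subvectors(self, rng):
        pixels = rng.integers(0, 1000, size=(12, 12))
        fv = feature_vector(pixels)
        gl = resample_gray_levels(pixels)
        assert fv["angular_second_moment"] == glcm_features(cooccurrence_matrix(gl))[
            "angular_second_moment"
        ]
        assert fv["sre"] == glrlm_features(run_length_matrices(gl))["sre"]
        assert fv["ngtdm_contrast"] == ngtdm_contrast(ngtdm(gl, 1))
        assert fv["intensity_mean"] == global_stats(pixels)["intensity_mean"]

    def test_intensity_shift_invariance_of_texture_features(self, rng):
        pixels = rng.integers(0, 500, size=(15, 15))
        f1 = feature_vector(pixels)
        f2 = feature_vector(pixels + 777)
        texture = set(FEATURE_NAMES) - {"intensity_max", "intensity_min", "intensity_mean"}
        for name in texture:
            assert f1[name] == pytest.approx(f2[name], rel=1e-12), name
        for name in ("intensity_max", "intensity_min", "intensity_mean"):
            assert f2[name] == pytest.approx(f1[name] + 777)

    def test_rotation_invariance_of_direction_averaged_features(self, rng):
        pixels = rng.integers(0, 500, size=(14, 14))
        f1 = feature_vector(pixels)
        f2 = feature_vector(np.rot90(pixels))
        for name in FEATURE_NAMES:
            assert f1[name] == pytest.approx(f2[name], rel=1e-10), name
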