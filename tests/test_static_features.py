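"""Static extraction: discretisation, preprocessing, shape and GLCM oracles."""

import numpy as np
import pytest

from dynrad import ExtractionSettings, discretize, drop_constant_features, extract_static_features, preprocess
from dynrad.images import ImageVolume, RoiMask
from dynrad.simulate import ellipsoid_mask
from dynrad.static_features import GLCM_DIRECTIONS, glcm_matrix, glcm_features_from_matrix
from oracles import glcm_counts, glcm_stats_naive

import pandas as pd


class TestDiscretize:
    def test_hand_example(self):
        np.testing.assert_array_equal(discretize(np.array([0, 25, 49, 50]), 25), [1, 2, 2, 3])

    def test_constant_roi_single_level(self):
        np.testing.assert_array_equal(discretize(np.full(5, 3.2), 25), np.ones(5, dtype=int))

    def test_translation_invariance(self, rng):
        v = rng.uniform(-100, 300, 50)
        np.testing.assert_array_equal(discretize(v, 25), discretize(v + 1000, 25))

    def test_level_count_formula(self, rng):
        v = rng.uniform(0, 500, 200)
        levels = discretize(v, 25)
        assert levels.max() == int(np.floor((v.max() - v.min()) / 25)) + 1


class TestPreprocess:
    def test_znorm_then_shift(self):
        vox = np.zeros((4, 4, 4))
        vox[0, 0, 0] = 1.0  # non-constant so z-scoring is defined
        vol = ImageVolume(vox)
        mask = RoiMask(np.ones((4, 4, 4)))
        out, _ = preprocess(vol, mask, ExtractionSettings(resample_spacing=None))
        assert out.voxels.mean() == pytest.approx(1000.0, abs=1e-9)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            preprocess(ImageVolume(np.zeros((3, 3, 3))), RoiMask(np.ones((3, 3, 3))),
                       ExtractionSettings(resample_spacing=None))

    def test_resampling_doubles_axes(self, rng):
        vol = ImageVolume(rng.normal(size=(8, 8, 8)), spacing=(2, 2, 2))
        mask = RoiMask(np.ones((8, 8, 8)), spacing=(2, 2, 2))
        out, out_m = preprocess(vol, mask, ExtractionSettings(resample_spacing=(1, 1, 1)))
        assert all(abs(a - 16) <= 1 for a in out.voxels.shape)
        assert out_m.voxels.shape == out.voxels.shape

    def test_mask_resampling_roughly_preserves_volume(self):
        grid = (26, 26, 26)
        sphere = ellipsoid_mask(grid, (10, 10, 10))
        vol = ImageVolume(np.random.default_rng(0).normal(size=grid), spacing=(2, 2, 2))
        mask = RoiMask(sphere, spacing=(2, 2, 2))
        _, out_m = preprocess(vol, mask, ExtractionSettings(resample_spacing=(1, 1, 1)))
        vol_before = sphere.sum() * 8.0
        vol_after = out_m.voxels.sum() * 1.0
        assert abs(vol_after - vol_before) / vol_before < 0.15


def _simple_settings():
    return ExtractionSettings(resample_spacing=None, normalize=False, bin_width=1.0)


class TestFirstOrderAndShape:
    def test_constant_roi_degenerate_firstorder(self):
        vox = np.zeros((5, 5, 5))
        vox[0, 0, 0] = 50  # outside ROI
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        fv = extract_static_features(ImageVolume(vox), RoiMask(mask), _simple_settings())
        assert fv.values["firstorder_Entropy"] == 0.0
        assert fv.values["firstorder_Variance"] == 0.0
        assert fv.values["firstorder_Uniformity"] == 1.0

    def test_sphere_is_isotropic(self):
        mask = ellipsoid_mask((25, 25, 25), (9, 9, 9))
        vox = np.random.default_rng(1).normal(size=(25, 25, 25))
        fv = extract_static_features(ImageVolume(vox), RoiMask(mask), _simple_settings())
        assert fv.values["shape_Elongation"] == pytest.approx(1.0, abs=1e-6)
        assert fv.values["shape_Flatness"] == pytest.approx(1.0, abs=1e-6)
        assert fv.values["shape_VoxelVolume"] == mask.sum()

    def test_ellipsoid_axis_ratios(self):
        mask = ellipsoid_mask((41, 41, 41), (16, 12, 8))
        vox = np.zeros((41, 41, 41)); vox[0, 0, 0] = 1
        fv = extract_static_features(ImageVolume(vox), RoiMask(mask), _simple_settings())
        assert fv.values["shape_Elongation"] == pytest.approx(12 / 16, rel=0.03)
        assert fv.values["shape_Flatness"] == pytest.approx(8 / 16, rel=0.03)

    def test_shape_ignores_intensities(self, rng):
        mask = ellipsoid_mask((15, 15, 15), (5, 4, 3))
        a = extract_static_features(ImageVolume(rng.normal(size=(15, 15, 15))), RoiMask(mask), _simple_settings())
        b = extract_static_features(ImageVolume(rng.normal(size=(15, 15, 15)) * 50), RoiMask(mask), _simple_settings())
        for k in a.values:
            if k.startswith("shape_"):
                assert a.values[k] == pytest.approx(b.values[k], rel=1e-12)

    def test_intensity_offset_absorbed_by_normalization(self, rng):
        vox = rng.normal(size=(8, 8, 8))
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        s = ExtractionSettings(resample_spacing=None)
        a = extract_static_features(ImageVolume(vox), RoiMask(mask), s)
        b = extract_static_features(ImageVolume(vox + 250.0), RoiMask(mask), s)
        for k, v in a.values.items():
            if k.startswith(("firstorder_", "glcm_")):
                assert v == pytest.approx(b.values[k], rel=1e-9, abs=1e-9)

    def test_single_voxel_roi_flagged_nan(self):
        vox = np.random.default_rng(0).normal(size=(4, 4, 4))
        mask = np.zeros((4, 4, 4), bool)
        mask[2, 2, 2] = True
        fv = extract_static_features(ImageVolume(vox), RoiMask(mask), _simple_settings())
        assert np.isnan(fv.values["glcm_Contrast"])
        assert "glcm_Contrast" in fv.nan_reasons
        assert np.isnan(fv.values["shape_Sphericity"])


class TestGLCM:
    def test_checkerboard_contrast_by_hand(self):
        # 3x3x1 in-plane checkerboard of levels {1, 2}: every in-plane
        # axis-aligned neighbour pair differs by exactly 1
        vox = np.indices((1, 3, 3)).sum(axis=0) % 2  # values 0/1 -> levels 1/2
        mask = np.ones((1, 3, 3), bool)
        levels = vox.astype(np.int64) + 1
        for direction in ((0, 0, 1), (0, 1, 0)):
            P = glcm_matrix(levels, mask, direction, 2)
            feats = glcm_features_from_matrix(P)
            assert feats["glcm_Contrast"] == pytest.approx(1.0)
            oracle = glcm_stats_naive(glcm_counts(levels, mask, direction))
            assert feats["glcm_Contrast"] == pytest.approx(oracle["glcm_Contrast"])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_on_random_rois(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(3, 7, 3))
        levels = rng.integers(1, 5, shape).astype(np.int64)
        mask = rng.random(shape) < 0.7
        mask.flat[0] = True  # never empty
        n_levels = int(levels[mask].max())
        for direction in GLCM_DIRECTIONS[:: 4]:
            P = glcm_matrix(levels, mask, direction, n_levels)
            if P.sum() == 0:
                continue
            got = glcm_features_from_matrix(P)
            expected = glcm_stats_naive(glcm_counts(levels, mask, direction)[:n_levels, :n_levels])
            for k, v in expected.items():
                assert got[k] == pytest.approx(v, rel=1e-9, abs=1e-9), k


class TestDropConstantFeatures:
    def test_spec_examples(self):
        m = pd.DataFrame({"a": [1, 1, 1], "b": [1, 2, 3]})
        assert list(drop_constant_features(m).columns) == ["b"]
        m2 = pd.DataFrame({"a": [1, 2, 3], "b": [0, 5, 1]})
        pd.testing.assert_frame_equal(drop_constant_features(m2), m2)

    def test_float_noise_below_tolerance_removed(self):
        m = pd.DataFrame({"a": [1.0, 1.0 + 1e-15, 1.0], "b": [1, 2, 3]})
        assert list(drop_constant_features(m).columns) == ["b"]

    def test_all_constant_errors(self):
        with pytest.raises(ValueError, match="no informative"):
            drop_constant_features(pd.DataFrame({"a": [2, 2, 2]}))
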