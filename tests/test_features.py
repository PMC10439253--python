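"""Radiomics bank: discretization, families, brute-force oracle equivalence."""

import numpy as np
import pytest

from dlrs.exceptions import ConfigError, DataError, TooFewPixelsError
from dlrs.features import (
    DEFAULT_BIN_SETTINGS,
    FAMILY_COUNTS,
    GLCM_FEATURE_NAMES,
    GLDM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    DiscretizationSetting,
    LabelImage,
    RadiomicsVector,
    discretize,
    extract_radiomics,
    feature_dictionary,
    feature_names,
    firstorder_features,
    glcm_features,
    glcm_features_single,
    glcm_matrix,
    gldm_features,
    glrlm_features,
    glszm_features,
    shape2d_features,
    zscore_apply,
    zscore_fit,
)

from conftest import random_label_image
from oracles import (
    bf_glcm_features_averaged,
    bf_gldm_features,
    bf_glrlm_features,
    bf_glszm_features,
)


def _uniform_label_image(values, n_bins):
    arr = np.asarray(values)
    return LabelImage(labels=arr, mask=np.ones_like(arr, dtype=bool), n_bins=n_bins)


class TestDiscretize:
    def test_four_values_four_bins(self):
        img = np.array([[0.0, 1.0], [2.0, 3.0]])
        li = discretize(img, np.ones((2, 2), bool), DiscretizationSetting(4))
        assert sorted(li.in_mask_labels()) == [1, 2, 3, 4]

    def test_constant_region_maps_to_label_one(self):
        img = np.full((3, 3), 5.0)
        li = discretize(img, np.ones((3, 3), bool), DiscretizationSetting(8))
        assert set(li.in_mask_labels()) == {1}

    def test_single_bin_rejected(self):
        with pytest.raises(ConfigError):
            DiscretizationSetting(1)

    def test_too_few_pixels(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True
        with pytest.raises(TooFewPixelsError):
            discretize(np.zeros((3, 3)), mask, DiscretizationSetting(4))

    def test_shift_invariance(self, rng):
        img = rng.normal(size=(10, 10))
        mask = np.ones((10, 10), bool)
        li1 = discretize(img, mask, DiscretizationSetting(8))
        li2 = discretize(img + 37.5, mask, DiscretizationSetting(8))
        np.testing.assert_array_equal(li1.labels, li2.labels)


class TestShape2D:
    def test_square_pixel_surface(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        f = shape2d_features(mask, (1.0, 1.0))
        assert f["shape_PixelSurface"] == pytest.approx(100.0)

    def test_disk_sphericity_near_one(self):
        n = 101
        xs, ys = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        mask = (xs - n // 2) ** 2 + (ys - n // 2) ** 2 <= 40**2
        f = shape2d_features(mask, (1.0, 1.0))
        assert abs(f["shape_Sphericity"] - 1.0) < 0.05
        assert f["shape_MaximumDiameter"] == pytest.approx(80.0, rel=0.05)

    def test_elongation_bounded(self, rng):
        for _ in range(5):
            mask = rng.random((12, 12)) < 0.5
            if mask.sum() < 3:
                continue
            f = shape2d_features(mask, (1.0, 1.0))
            assert 0.0 <= f["shape_Elongation"] <= 1.0 + 1e-12

    def test_physical_units(self):
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        f1 = shape2d_features(mask, (1.0, 1.0))
        f2 = shape2d_features(mask, (2.0, 2.0))
        assert f2["shape_PixelSurface"] == pytest.approx(4 * f1["shape_PixelSurface"])
        assert f2["shape_Perimeter"] == pytest.approx(2 * f1["shape_Perimeter"])


class TestFirstOrder:
    def test_constant_region(self):
        li = _uniform_label_image(np.ones((3, 3), int), 8)
        f = firstorder_features(li, np.full(9, 7.0))
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0

    def test_hand_computed_values(self):
        labels = np.array([[1, 2], [3, 4]])
        li = _uniform_label_image(labels, 4)
        f = firstorder_features(li, np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["Mean"] == pytest.approx(2.5)
        assert f["Range"] == pytest.approx(3.0)
        assert f["Energy"] == pytest.approx(1 + 4 + 9 + 16)
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(30 / 4))

    def test_uniform_histogram_entropy(self):
        n_bins = 8
        labels = (np.arange(64).reshape(8, 8) % n_bins) + 1
        li = _uniform_label_image(labels, n_bins)
        f = firstorder_features(li, np.random.default_rng(0).normal(size=64))
        assert f["Entropy"] == pytest.approx(np.log2(n_bins))
        assert f["Uniformity"] == pytest.approx(1.0 / n_bins)

    def test_mean_shift_covariance(self, rng):
        labels = rng.integers(1, 5, size=(6, 6))
        li = _uniform_label_image(labels, 4)
        raw = rng.normal(size=36)
        f1 = firstorder_features(li, raw)
        f2 = firstorder_features(li, raw + 10.0)
        assert f2["Mean"] == pytest.approx(f1["Mean"] + 10.0)
        assert f2["Variance"] == pytest.approx(f1["Variance"])


class TestGLCMExamples:
    def test_constant_region(self):
        li = _uniform_label_image(np.ones((4, 4), int), 4)
        f = glcm_features(li)
        assert f["Contrast"] == 0.0
        assert f["JointEntropy"] == 0.0
        assert f["MaximumProbability"] == 1.0

    def test_two_by_two_horizontal(self):
        li = _uniform_label_image(np.array([[1, 1], [2, 2]]), 2)
        P = glcm_matrix(li, (0, 1))
        p = P / P.sum()
        assert p[0, 0] == pytest.approx(0.5)
        assert p[1, 1] == pytest.approx(0.5)
        assert glcm_features_single(P)["Contrast"] == 0.0

    def test_checkerboard_horizontal_contrast(self):
        labels = 1 + (np.indices((6, 6)).sum(axis=0) % 2)
        li = _uniform_label_image(labels, 2)
        f = glcm_features_single(glcm_matrix(li, (0, 1)))
        assert f["Contrast"] == pytest.approx(1.0)


class TestGLRLMExamples:
    def test_single_run_short_run_emphasis(self):
        L = 5
        li = _uniform_label_image(np.ones((1, L), int), 2)
        f = glrlm_features(li)
        # horizontal: one run of length L -> SRE 1/L^2; vertical: L runs of 1
        from dlrs.features import glrlm_matrix
        from dlrs.features.texture import _rlm_style_features

        horiz = _rlm_style_features(glrlm_matrix(li, (0, 1)), L, "run")
        assert horiz["ShortRunEmphasis"] == pytest.approx(1.0 / L**2)

    def test_constant_image_glnn(self):
        li = _uniform_label_image(np.ones((4, 4), int), 3)
        f = glrlm_features(li)
        assert f["GrayLevelNonUniformityNormalized"] == pytest.approx(1.0)

    def test_alternating_rln_equals_run_count(self):
        labels = np.array([[1, 2, 1, 2, 1, 2]])
        li = _uniform_label_image(labels, 2)
        from dlrs.features import glrlm_matrix

        P = glrlm_matrix(li, (0, 1))
        n_runs = P.sum()
        assert n_runs == 6  # every pixel its own run
        rln = (P.sum(axis=0) ** 2).sum() / n_runs
        assert rln == pytest.approx(n_runs)


class TestGLSZMExamples:
    def test_constant_region_single_zone(self):
        li = _uniform_label_image(np.ones((3, 4), int), 2)
        f = glszm_features(li)
        assert f["ZoneEntropy"] == 0.0
        assert f["LargeAreaEmphasis"] == pytest.approx(144.0)

    def test_two_patches_small_area_emphasis(self):
        # two disjoint same-label patches of sizes 3 and 5
        labels = np.zeros((5, 9), int)
        mask = np.zeros((5, 9), bool)
        labels[0, 0:3] = 1
        mask[0, 0:3] = True
        labels[2, 4:9] = 1
        mask[2, 4:9] = True
        li = LabelImage(labels=labels, mask=mask, n_bins=2)
        f = glszm_features(li)
        assert f["SmallAreaEmphasis"] == pytest.approx((1 / 9 + 1 / 25) / 2)

    def test_all_distinct_labels_zones_size_one(self):
        # with 8-connected zones, only fully distinct labels guarantee
        # singleton zones (checkerboard colors touch diagonally)
        labels = np.arange(1, 17).reshape(4, 4)
        li = _uniform_label_image(labels, 16)
        f = glszm_features(li)
        assert f["LargeAreaEmphasis"] == pytest.approx(1.0)
        assert f["SmallAreaEmphasis"] == pytest.approx(1.0)

    def test_checkerboard_two_zones_under_8_connectivity(self):
        labels = 1 + (np.indices((4, 4)).sum(axis=0) % 2)
        li = _uniform_label_image(labels, 2)
        from dlrs.features import glszm_matrix

        P = glszm_matrix(li)
        assert P.sum() == 2  # each color is one diagonally-connected zone
        assert P[0, 7] == 1 and P[1, 7] == 1


class TestGLDMExamples:
    def test_constant_3x3_center_dependence(self):
        li = _uniform_label_image(np.ones((3, 3), int), 2)
        from dlrs.features import gldm_matrix

        P = gldm_matrix(li)
        assert P[0, 8] == 1  # the center pixel has all 8 neighbors equal

    def test_all_distinct_dnu_equals_pixel_count(self):
        labels = np.arange(1, 10).reshape(3, 3)
        li = _uniform_label_image(labels, 9)
        f = gldm_features(li)
        assert f["DependenceNonUniformity"] == pytest.approx(9.0)

    def test_constant_region_entropy_matches_brute_force(self, rng):
        li = _uniform_label_image(np.ones((4, 5), int), 3)
        f = gldm_features(li)
        bf = bf_gldm_features(li.labels, li.mask, 3, GLDM_FEATURE_NAMES)
        assert f["DependenceEntropy"] == pytest.approx(bf["DependenceEntropy"], rel=1e-12)


class TestBruteForceEquivalence:
    """Every texture feature vs naive enumeration on random label images."""

    N_IMAGES = 110
    RTOL = 1e-9

    def test_all_families_match_oracles(self, rng):
        worst = 0.0
        for trial in range(self.N_IMAGES):
            li = random_label_image(rng)
            pairs = [
                (glcm_features(li), bf_glcm_features_averaged(
                    li.labels, li.mask, li.n_bins, GLCM_FEATURE_NAMES)),
                (glrlm_features(li), bf_glrlm_features(
                    li.labels, li.mask, li.n_bins, GLRLM_FEATURE_NAMES)),
                (glszm_features(li), bf_glszm_features(
                    li.labels, li.mask, li.n_bins, GLSZM_FEATURE_NAMES)),
                (gldm_features(li), bf_gldm_features(
                    li.labels, li.mask, li.n_bins, GLDM_FEATURE_NAMES)),
            ]
            for impl, bf in pairs:
                for k, v in bf.items():
                    err = abs(impl[k] - v) / max(abs(v), 1e-12)
                    worst = max(worst, err)
                    assert err < self.RTOL, f"{k}: {impl[k]} vs {v} (trial {trial})"
        assert worst < self.RTOL


class TestRotationInvariance:
    def test_direction_averaged_features_invariant_under_rot90(self, rng):
        for _ in range(10):
            li = random_label_image(rng)
            rot = LabelImage(
                labels=np.rot90(li.labels).copy(),
                mask=np.rot90(li.mask).copy(),
                n_bins=li.n_bins,
            )
            for fn in (glcm_features, glrlm_features, glszm_features, gldm_features):
                a, b = fn(li), fn(rot)
                for k in a:
                    assert a[k] == pytest.approx(b[k], rel=1e-9), (fn.__name__, k)


class TestExtractRadiomics:
    def test_count_parity(self, phantom_case):
        from dlrs.pipeline import PreprocessConfig, preprocess_case

        _, vec = preprocess_case(phantom_case.volume, phantom_case.mask, PreprocessConfig())
        assert len(vec) == 361
        counts = {}
        for name in vec.names:
            fam = name.split("_")[0]
            counts[fam] = counts.get(fam, 0) + 1
        assert counts == FAMILY_COUNTS

    def test_single_setting_count(self, phantom_case):
        from dlrs.volumes import window_normalize

        vec = extract_radiomics(
            window_normalize(phantom_case.volume), phantom_case.mask, settings=(16,)
        )
        assert len(vec) == 9 + 88

    def test_determinism_bitwise(self, phantom_case):
        from dlrs.volumes import window_normalize

        vol = window_normalize(phantom_case.volume)
        v1 = extract_radiomics(vol, phantom_case.mask)
        v2 = extract_radiomics(vol, phantom_case.mask)
        assert np.array_equal(v1.values, v2.values)

    def test_feature_dictionary_schema(self):
        d = feature_dictionary()
        assert d["n_features"] == 361
        assert len({e["name"] for e in d["features"]}) == 361
        assert d["version"]


class TestZScore:
    def test_hand_computed(self):
        names = ["a", "b"]
        v1 = RadiomicsVector(np.array([1.0, 0.0]), names, "c1")
        v2 = RadiomicsVector(np.array([3.0, 0.0]), names, "c2")
        stats = zscore_fit([v1, v2])
        assert stats.mean[0] == pytest.approx(2.0)
        assert stats.std[0] == pytest.approx(1.0)  # denominator n
        z = zscore_apply(v2, stats)
        assert z.values[0] == pytest.approx(1.0)
        assert z.values[1] == 0.0  # constant feature maps to 0

    def test_fit_set_standardizes_to_zero_mean(self, rng):
        names = [f"f{i}" for i in range(5)]
        vecs = [RadiomicsVector(rng.normal(size=5), names, str(i)) for i in range(20)]
        stats = zscore_fit(vecs)
        Z = np.stack([zscore_apply(v, stats).values for v in vecs])
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)

    def test_insufficient_data(self):
        v = RadiomicsVector(np.zeros(3), ["a", "b", "c"], "x")
        with pytest.raises(DataError):
            zscore_fit([v])
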