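"""Radiomics engine: discretization, texture matrices, feature families.

The worked micro-examples (1x1x4 bars, cubes) are checked against values
derived by hand; texture matrices are additionally checked exactly against
independent brute-force enumerators on random small ROIs.
"""

import numpy as np
import pytest

from mfcrad.radiomics import (
    DIRECTIONS_13,
    FAMILY_SIZES,
    RadiomicsConfig,
    compute_glcm,
    compute_glrlm,
    compute_glszm,
    discretize_fbn,
    extract_handcrafted,
    feature_names,
    histogram_features,
    intensity_features,
    shape_features,
    texture_features,
)
from mfcrad.radiomics.discretize import DiscretizedROI
from mfcrad.radiomics.texture import average_feature_dicts
from mfcrad.synthetic import generate_phantom

from conftest import make_bar_roi
from _oracles import brute_glcm, brute_glrlm, brute_glszm


def random_droi(rng, max_side=5, n_levels=4):
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    mask = (rng.uniform(size=shape) < 0.7).astype(np.uint8)
    if mask.sum() == 0:
        mask[0, 0, 0] = 1
    bins = np.zeros(shape, dtype=np.int32)
    bins[mask > 0] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return DiscretizedROI(bins=bins, mask=mask, n_bins=n_levels)


class TestDiscretize:
    def test_endpoints_map_to_first_and_last_bin(self):
        vol = np.array([[[0.0, 10.0]]])
        droi = discretize_fbn(vol, np.ones_like(vol), n_bins=32)
        assert droi.bins[0, 0, 0] == 1
        assert droi.bins[0, 0, 1] == 32

    def test_midpoint_formula(self):
        # floor(32 * 5/10) + 1 = 17
        vol = np.array([[[0.0, 5.0, 10.0]]])
        droi = discretize_fbn(vol, np.ones_like(vol), n_bins=32)
        assert droi.bins[0, 0, 1] == 17

    def test_constant_roi_maps_to_bin_one(self):
        vol = np.full((3, 3, 3), 7.0)
        droi = discretize_fbn(vol, np.ones((3, 3, 3)), n_bins=32)
        assert set(np.unique(droi.in_mask_bins)) == {1}

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            discretize_fbn(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)))

    def test_all_bins_in_range(self, rng):
        vol = rng.normal(size=(6, 6, 6))
        droi = discretize_fbn(vol, np.ones((6, 6, 6)), n_bins=8)
        assert droi.in_mask_bins.min() >= 1
        assert droi.in_mask_bins.max() <= 8


class TestGLCM:
    def test_bar_example_counts(self):
        droi = make_bar_roi([1, 1, 2, 2])
        per_dir, _ = compute_glcm(droi)
        m = next(x for x in per_dir if x.direction == (0, 0, 1)).counts
        assert m[0, 0] == 2 and m[0, 1] == 1 and m[1, 0] == 1 and m[1, 1] == 2
        assert m.sum() == 6

    def test_uniform_roi_all_mass_on_diagonal(self):
        droi = make_bar_roi([1, 1, 1, 1], n_bins=2)
        _, agg = compute_glcm(droi)
        p = agg.normalized()
        assert p[0, 0] == 1.0

    def test_aggregate_is_mean_of_directional(self, rng):
        droi = random_droi(rng)
        per_dir, agg = compute_glcm(droi)
        np.testing.assert_allclose(
            agg.counts, np.mean([m.counts for m in per_dir], axis=0)
        )

    def test_counts_match_brute_force(self, rng):
        for _ in range(20):
            droi = random_droi(rng)
            per_dir, _ = compute_glcm(droi)
            for m in per_dir:
                expected = brute_glcm(droi.bins, droi.mask, m.direction, droi.n_bins)
                np.testing.assert_array_equal(m.counts, expected)


class TestGLRLM:
    def test_bar_example_two_runs(self):
        droi = make_bar_roi([1, 1, 2, 2])
        mats = compute_glrlm(droi)
        m = next(x for x in mats if x.direction == (0, 0, 1)).counts
        assert m[0, 1] == 1 and m[1, 1] == 1
        assert m.sum() == 2

    def test_uniform_bar_single_run(self):
        droi = make_bar_roi([1, 1, 1, 1], n_bins=1)
        mats = compute_glrlm(droi)
        m = next(x for x in mats if x.direction == (0, 0, 1)).counts
        assert m[0, 3] == 1 and m.sum() == 1

    def test_run_weighted_sum_conserves_voxels(self, rng):
        droi = random_droi(rng)
        for m in compute_glrlm(droi):
            lengths = np.arange(1, m.counts.shape[1] + 1)
            assert (m.counts @ lengths).sum() == droi.n_voxels

    def test_counts_match_brute_force(self, rng):
        for _ in range(20):
            droi = random_droi(rng)
            for m in compute_glrlm(droi):
                expected = brute_glrlm(droi.bins, droi.mask, m.direction, droi.n_bins)
                k = min(m.counts.shape[1], expected.shape[1])
                np.testing.assert_array_equal(m.counts[:, :k], expected[:, :k])
                assert m.counts[:, k:].sum() == 0 and expected[:, k:].sum() == 0


class TestGLSZM:
    def test_bar_example_two_zones(self):
        droi = make_bar_roi([1, 1, 2, 2])
        m = compute_glszm(droi).counts
        assert m[0, 1] == 1 and m[1, 1] == 1
        assert m.sum() == 2

    def test_uniform_roi_one_zone(self):
        droi = make_bar_roi([1] * 7, n_bins=1)
        m = compute_glszm(droi).counts
        assert m[0, 6] == 1 and m.sum() == 1

    def test_zone_weighted_sum_conserves_voxels(self, rng):
        for _ in range(10):
            droi = random_droi(rng)
            m = compute_glszm(droi)
            sizes = np.arange(1, m.counts.shape[1] + 1)
            assert (m.counts @ sizes).sum() == droi.n_voxels

    def test_counts_match_brute_force(self, rng):
        for _ in range(20):
            droi = random_droi(rng)
            m = compute_glszm(droi).counts
            expected = brute_glszm(droi.bins, droi.mask, droi.n_bins)
            k = min(m.shape[1], expected.shape[1])
            np.testing.assert_array_equal(m[:, :k], expected[:, :k])


class TestTextureFeatures:
    def test_uniform_roi_glcm_contrast_zero(self):
        droi = make_bar_roi([1, 1, 1, 1], n_bins=2)
        per_dir, _ = compute_glcm(droi)
        feats = average_feature_dicts([texture_features(m) for m in per_dir])
        assert feats["contrast"] == 0.0
        assert feats["correlation"] == 0.0  # degenerate convention

    def test_bar_short_run_emphasis(self):
        droi = make_bar_roi([1, 1, 2, 2])
        mats = compute_glrlm(droi)
        m = next(x for x in mats if x.direction == (0, 0, 1))
        feats = texture_features(m)
        assert feats["short_run_emphasis"] == pytest.approx(0.25)

    def test_family_output_lengths(self, rng):
        droi = random_droi(rng)
        per_dir, _ = compute_glcm(droi)
        assert len(texture_features(per_dir[0])) == 22
        assert len(texture_features(compute_glrlm(droi)[0])) == 16
        assert len(texture_features(compute_glszm(droi))) == 16


class TestFirstOrder:
    def test_constant_roi_zero_variance_and_entropy(self):
        vol = np.full((3, 3, 3), 5.0)
        mask = np.ones((3, 3, 3))
        droi = discretize_fbn(vol, mask)
        assert intensity_features(vol, mask)["variance"] == 0.0
        assert histogram_features(droi)["entropy"] == 0.0

    def test_two_even_bins_entropy_one_bit(self):
        droi = make_bar_roi([1, 1, 2, 2])
        assert histogram_features(droi)["entropy"] == pytest.approx(1.0)

    def test_intensity_mean(self):
        vol = np.array([[[-10.0, 10.0, 30.0]]])
        assert intensity_features(vol, np.ones_like(vol))["mean"] == pytest.approx(10.0)

    def test_family_sizes(self):
        vol = np.arange(27, dtype=float).reshape(3, 3, 3)
        mask = np.ones((3, 3, 3))
        droi = discretize_fbn(vol, mask)
        assert len(intensity_features(vol, mask)) == 18
        assert len(histogram_features(droi)) == 20


class TestShape:
    def test_cube_volume_and_face_area(self):
        mask = np.zeros((14, 14, 14))
        mask[2:12, 2:12, 2:12] = 1
        feats = shape_features(mask)
        assert feats["volume"] == pytest.approx(1000.0)
        assert feats["surface_area"] == pytest.approx(600.0)

    def test_sphere_rotation_invariance(self):
        a = generate_phantom(shape=(48, 48, 48), tumor_volume_cc=2.0, seed=3)
        # 90-degree rotation maps the voxel grid onto itself: exact features
        fa = shape_features(a.mask)
        fb = shape_features(np.rot90(a.mask, axes=(0, 1)))
        for k in fa:
            assert fa[k] == pytest.approx(fb[k], rel=1e-9), k

    def test_anisotropic_spacing_scales_volume(self):
        mask = np.ones((4, 4, 4))
        feats = shape_features(mask, spacing=(2.0, 1.0, 1.0))
        assert feats["volume"] == pytest.approx(128.0)

    def test_elongation_flatness_in_unit_interval(self, phantom):
        feats = shape_features(phantom.mask)
        assert 0 < feats["flatness"] <= feats["elongation"] <= 1.0


class TestExtractHandcrafted:
    def test_exactly_105_named_finite_features(self, phantom):
        feats = extract_handcrafted(phantom.volume, phantom.mask)
        assert len(feats) == 105
        assert list(feats) == feature_names()
        assert all(np.isfinite(v) for v in feats.values())
        for family, size in FAMILY_SIZES.items():
            assert sum(1 for k in feats if k.startswith(f"{family}__")) == size

    def test_repeat_call_bit_identical(self, phantom):
        a = extract_handcrafted(phantom.volume, phantom.mask)
        b = extract_handcrafted(phantom.volume, phantom.mask)
        assert a == b

    def test_translation_invariance(self, phantom):
        """Shifting the tumor within the grid leaves all features unchanged."""
        vox = phantom.volume.voxels
        mask = phantom.mask
        shifted_vox = np.roll(vox, (3, -2, 4), axis=(0, 1, 2))
        shifted_mask = np.roll(mask, (3, -2, 4), axis=(0, 1, 2))
        a = extract_handcrafted(vox, mask)
        b = extract_handcrafted(shifted_vox, shifted_mask)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9), k

    def test_rotation_90deg_invariance_of_texture(self, phantom):
        """The 13-direction set maps to itself under 90-degree rotations."""
        a = extract_handcrafted(phantom.volume.voxels, phantom.mask)
        b = extract_handcrafted(
            np.ascontiguousarray(np.rot90(phantom.volume.voxels, axes=(1, 2))),
            np.ascontiguousarray(np.rot90(phantom.mask, axes=(1, 2))),
        )
        for k in a:
            if k.split("__")[0] in ("glcm", "glrlm", "glszm", "histogram", "intensity"):
                assert a[k] == pytest.approx(b[k], rel=1e-9), k

    def test_two_voxel_roi_finite(self):
        vol = np.zeros((4, 4, 4))
        vol[1, 1, 1], vol[1, 1, 2] = 5.0, 9.0
        mask = np.zeros((4, 4, 4))
        mask[1, 1, 1] = mask[1, 1, 2] = 1
        feats = extract_handcrafted(vol, mask)
        assert all(np.isfinite(v) for v in feats.values())

    def test_single_voxel_roi_warns_and_zeroes_texture(self):
        vol = np.zeros((3, 3, 3))
        mask = np.zeros((3, 3, 3))
        mask[1, 1, 1] = 1
        with pytest.warns(UserWarning, match="single-voxel"):
            feats = extract_handcrafted(vol, mask)
        assert feats["glcm__contrast"] == 0.0
        assert len(feats) == 105
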