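"""Tests for drusen feature extraction, with independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amdprog.biomarkers import (
    assemble_features,
    average_session,
    compute_extent_density,
    compute_height_slope,
    compute_regional,
    compute_reflectivity_stats,
    compute_size_features,
    label_instances,
    normalize_reflectivity,
)
from amdprog.bundles import CIRRUS_TO_INTERNAL, FEATURE_NAMES, DrusenScanBundle, ImagingFeatureVector
from amdprog.synthetic import CapDruse, PhantomSpec, generate_phantom

from tests.test_synthetic import flood_fill_count


def make_bundle(mask, voxel=(0.05, 0.05, 0.01), elevation=None, intensity=None,
                fovea=None):
    mask = np.asarray(mask, dtype=bool)
    nx, ny, nz = mask.shape
    if elevation is None:
        elevation = mask.any(axis=2).astype(float) * nz * voxel[2]
    if intensity is None:
        rng = np.random.default_rng(0)
        intensity = rng.random(mask.shape)
    if fovea is None:
        fovea = (nx * voxel[0] / 2, ny * voxel[1] / 2)
    return DrusenScanBundle(
        drusen_mask=mask,
        elevation_map_mm=elevation,
        intensity_volume=intensity,
        voxel_size_mm=voxel,
        fovea_center_mm=fovea,
    )


class TestLabelInstances:
    def test_empty_mask(self):
        _, count = label_instances(np.zeros((4, 4, 4), dtype=bool))
        assert count == 0

    def test_corner_contact_is_connected(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True  # shares only a corner
        _, count = label_instances(mask)
        assert count == 1
        assert flood_fill_count(mask) == 1

    def test_two_separated_blobs(self):
        mask = np.zeros((8, 8, 4), dtype=bool)
        mask[0:2, 0:2, :2] = True
        mask[5:7, 5:7, :2] = True
        _, count = label_instances(mask)
        assert count == 2

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            label_instances(np.full((3, 3, 3), 2))

    def test_six_connectivity_splits_diagonal(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        mask[1, 1, 1] = True
        _, count = label_instances(mask, connectivity=6)
        assert count == 2

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((8, 8, 6)) < 0.15
        _, count = label_instances(mask)
        assert count == flood_fill_count(mask)


class TestSizeFeatures:
    def test_hundred_voxel_arithmetic(self):
        mask = np.zeros((20, 20, 10), dtype=bool)
        mask[0:10, 0:10, 0] = True  # 100 voxels
        bundle = make_bundle(mask, voxel=(0.03, 0.03, 0.002))
        labels, count = label_instances(mask)
        out = compute_size_features(bundle, labels, count)
        assert out["total_volume"] == pytest.approx(100 * 0.03 * 0.03 * 0.002)
        assert out["total_area"] == pytest.approx(100 * 0.03 * 0.03)

    def test_hemisphere_volume_within_tolerance(self, hemisphere_phantom):
        bundle, truth = hemisphere_phantom
        labels, count = label_instances(bundle.drusen_mask)
        out = compute_size_features(bundle, labels, count)
        assert out["total_volume"] == pytest.approx(truth.volumes_mm3[0], rel=0.05)
        assert out["total_area"] == pytest.approx(truth.areas_mm2[0], rel=0.05)

    def test_two_identical_drusen_mean_is_half_total(self):
        mask = np.zeros((16, 16, 4), dtype=bool)
        mask[0:3, 0:3, 0:2] = True
        mask[8:11, 8:11, 0:2] = True
        bundle = make_bundle(mask)
        labels, count = label_instances(mask)
        out = compute_size_features(bundle, labels, count)
        assert count == 2
        assert out["mean_volume"] == pytest.approx(out["total_volume"] / 2)


class TestExtentDensity:
    def test_filled_square_density_one(self):
        mask = np.zeros((12, 12, 4), dtype=bool)
        mask[2:8, 3:9, 0:2] = True
        bundle = make_bundle(mask)
        labels, count = label_instances(mask)
        out = compute_extent_density(bundle, labels, count)
        assert out["extent_area"] == pytest.approx(36 * 0.05 * 0.05)
        assert out["density"] == pytest.approx(1.0)

    def test_two_corner_squares_vs_rasterized_hull_oracle(self):
        shapely_geom = pytest.importorskip("shapely.geometry")
        mask = np.zeros((20, 20, 4), dtype=bool)
        mask[0:2, 0:2, 0] = True
        mask[18:20, 18:20, 0] = True
        bundle = make_bundle(mask)
        labels, count = label_instances(mask)
        out = compute_extent_density(bundle, labels, count)
        # oracle: shapely hull over the same pixel-corner cloud
        px = 0.05
        pts = []
        for i, j in np.argwhere(mask.any(axis=2)):
            for di in (0, 1):
                for dj in (0, 1):
                    pts.append(((i + di) * px, (j + dj) * px))
        hull = shapely_geom.MultiPoint(pts).convex_hull
        assert out["extent_area"] == pytest.approx(hull.area, rel=1e-9)
        assert out["density"] == pytest.approx(8 * px * px / hull.area, rel=1e-9)

    def test_single_convex_druse_high_density(self, hemisphere_phantom):
        bundle, _ = hemisphere_phantom
        labels, count = label_instances(bundle.drusen_mask)
        out = compute_extent_density(bundle, labels, count)
        assert 0.90 <= out["density"] <= 1.0

    def test_no_drusen_zeroes(self):
        bundle = make_bundle(np.zeros((6, 6, 4), dtype=bool))
        out = compute_extent_density(bundle, np.zeros((6, 6, 4), dtype=int), 0)
        assert out == {"extent_area": 0.0, "density": 0.0}

    def test_single_pixel_degenerate_fallback(self):
        mask = np.zeros((8, 8, 4), dtype=bool)
        mask[4, 4, 0] = True
        bundle = make_bundle(mask)
        labels, count = label_instances(mask)
        out = compute_extent_density(bundle, labels, count)
        assert out["density"] == pytest.approx(1.0)


class TestHeightSlope:
    def test_hemisphere_peak(self, hemisphere_phantom):
        bundle, truth = hemisphere_phantom
        labels, count = label_instances(bundle.drusen_mask)
        out = compute_height_slope(bundle, labels, count)
        dz = bundle.voxel_size_mm[2]
        assert abs(out["max_height"] - truth.peak_heights_mm[0]) <= 2 * dz + 1e-3

    def test_planar_ramp_slope(self):
        nx, ny = 16, 16
        voxel = (0.05, 0.05, 0.01)
        s = 0.4
        x = (np.arange(nx) + 0.5) * voxel[0]
        elevation = np.tile(s * x[:, None], (1, ny))
        mask = np.ones((nx, ny, 2), dtype=bool)
        bundle = make_bundle(mask, voxel=voxel, elevation=elevation)
        labels, count = label_instances(mask)
        out = compute_height_slope(bundle, labels, count)
        assert out["avg_slope"] == pytest.approx(s, rel=1e-9)

    def test_flat_zero(self):
        mask = np.ones((6, 6, 2), dtype=bool)
        bundle = make_bundle(mask, elevation=np.zeros((6, 6)))
        labels, count = label_instances(mask)
        out = compute_height_slope(bundle, labels, count)
        assert out == {"max_height": 0.0, "avg_slope": 0.0}


class TestNormalizeReflectivity:
    def test_percentiles_mapped(self):
        rng = np.random.default_rng(1)
        vol = rng.uniform(0, 100, size=(20, 20, 20))
        out = normalize_reflectivity(vol)
        assert np.percentile(out, 5) == pytest.approx(0.0, abs=1e-6)
        assert np.percentile(out, 95) == pytest.approx(1.0, abs=1e-6)
        mid = (50.0 - np.percentile(vol, 5)) / (np.percentile(vol, 95) - np.percentile(vol, 5))
        assert mid == pytest.approx(0.5, abs=0.02)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        vol = rng.normal(size=(10, 10, 10))
        np.testing.assert_allclose(
            normalize_reflectivity(vol), normalize_reflectivity(3.7 * vol + 11.0),
            atol=1e-9,
        )

    def test_constant_volume_errors(self):
        with pytest.raises(ValueError, match="degenerate intensity range"):
            normalize_reflectivity(np.full((5, 5, 5), 3.0))

    def test_not_clipped(self):
        vol = np.zeros((10, 10, 10))
        vol[0, 0, 0] = 100.0  # extreme outlier above p95
        vol[:5] = np.random.default_rng(0).random((5, 10, 10))
        out = normalize_reflectivity(vol)
        assert out.max() > 1.0


class TestReflectivityStats:
    def test_uniform_masked_values_zero_std(self):
        vol = np.zeros((4, 4, 4))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, :2] = True
        vol[mask] = 0.7
        out = compute_reflectivity_stats(vol, mask)
        assert out["mean_reflectivity"] == pytest.approx(0.7)
        assert out["std_reflectivity"] == 0.0

    def test_hand_listed_values(self):
        vals = np.array([0.1, 0.4, 0.5, 0.9, 0.6])
        vol = np.zeros((5, 1, 1))
        vol[:, 0, 0] = vals
        mask = np.ones((5, 1, 1), dtype=bool)
        out = compute_reflectivity_stats(vol, mask)
        assert out["mean_reflectivity"] == pytest.approx(vals.mean())
        assert out["std_reflectivity"] == pytest.approx(vals.std(ddof=0))

    def test_empty_mask_flagged(self):
        out = compute_reflectivity_stats(np.ones((3, 3, 3)), np.zeros((3, 3, 3), bool))
        assert out == {"mean_reflectivity": 0.0, "std_reflectivity": 0.0,
                       "undefined_stats": True}

    def test_bright_druse_above_volume_mean(self, hemisphere_phantom):
        bundle, _ = hemisphere_phantom
        norm = normalize_reflectivity(bundle.intensity_volume)
        out = compute_reflectivity_stats(norm, bundle.drusen_mask)
        assert out["mean_reflectivity"] > norm.mean()


class TestRegional:
    def test_druse_at_fovea_fully_inside_3mm(self):
        spec = PhantomSpec(druse_list=[CapDruse((3.0, 3.0), 0.2, 0.15)])
        bundle, _ = generate_phantom(spec)
        labels, count = label_instances(bundle.drusen_mask)
        size = compute_size_features(bundle, labels, count)
        reg = compute_regional(bundle, labels, 3.0)
        assert reg["area_3mm"] == pytest.approx(size["total_area"])
        assert reg["volume_3mm"] == pytest.approx(size["total_volume"])

    def test_distant_druse_outside_3mm_inside_5mm(self):
        spec = PhantomSpec(
            druse_list=[CapDruse((3.0, 5.5), 0.2, 0.15)],
            fovea_center_mm=(3.0, 1.3),
        )
        bundle, _ = generate_phantom(spec)  # druse center 4.2 mm from fovea
        labels, count = label_instances(bundle.drusen_mask)
        size = compute_size_features(bundle, labels, count)
        reg3 = compute_regional(bundle, labels, 3.0)
        reg5 = compute_regional(bundle, labels, 5.0)
        assert reg3["area_3mm"] == 0.0
        assert reg5["area_5mm"] == pytest.approx(size["total_area"])

    def test_straddling_druse_per_pixel_oracle(self):
        spec = PhantomSpec(
            druse_list=[CapDruse((3.0, 5.0), 0.4, 0.2)],
            fovea_center_mm=(3.0, 2.2),
        )
        bundle, _ = generate_phantom(spec)  # druse straddles the 3 mm circle
        labels, count = label_instances(bundle.drusen_mask)
        reg = compute_regional(bundle, labels, 3.0)
        # brute-force per-pixel oracle
        x, y = bundle.enface_coords_mm()
        fp = labels.max(axis=2) > 0
        n_inside = 0
        for i in range(fp.shape[0]):
            for j in range(fp.shape[1]):
                if fp[i, j] and np.hypot(x[i] - 3.0, y[j] - 2.2) <= 3.0:
                    n_inside += 1
        assert reg["area_3mm"] == pytest.approx(n_inside * bundle.pixel_area_mm2)
        assert 0.0 < reg["area_3mm"] < fp.sum() * bundle.pixel_area_mm2


class TestAssembleFeatures:
    def test_empty_bundle_all_zero(self):
        bundle = make_bundle(np.zeros((8, 8, 4), dtype=bool))
        vec = assemble_features(bundle)
        assert vec.n_drusen == 0
        assert vec.undefined_stats
        np.testing.assert_array_equal(vec.as_array(), 0.0)

    def test_phantom_within_tolerance(self, hemisphere_phantom):
        bundle, truth = hemisphere_phantom
        vec = assemble_features(bundle)
        vec.check_invariants()
        assert vec.n_drusen == 1
        assert vec.total_volume == pytest.approx(truth.volumes_mm3[0], rel=0.05)
        assert vec.total_area == pytest.approx(truth.areas_mm2[0], rel=0.05)

    def test_cirrus_passthrough(self, hemisphere_phantom):
        bundle, _ = hemisphere_phantom
        provided = {name: 123.0 + i for i, name in enumerate(CIRRUS_TO_INTERNAL)}
        vec = assemble_features(bundle, cirrus=provided)
        assert not vec.cirrus_mirrored
        for name, value in provided.items():
            assert getattr(vec, name) == value

    def test_cirrus_mirrored_when_absent(self, hemisphere_phantom):
        bundle, _ = hemisphere_phantom
        vec = assemble_features(bundle)
        assert vec.cirrus_mirrored
        for cirrus_name, internal_name in CIRRUS_TO_INTERNAL.items():
            assert getattr(vec, cirrus_name) == getattr(vec, internal_name)

    def test_deterministic(self, hemisphere_phantom):
        bundle, _ = hemisphere_phantom
        np.testing.assert_array_equal(
            assemble_features(bundle).as_array(), assemble_features(bundle).as_array()
        )

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_invariants_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((10, 10, 8)) < rng.uniform(0.02, 0.3)
        bundle = make_bundle(mask, intensity=rng.random((10, 10, 8)))
        assemble_features(bundle).check_invariants()

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_containment_under_voxel_addition(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((10, 10, 8)) < 0.1
        bigger = mask | (rng.random((10, 10, 8)) < 0.05)
        intensity = rng.random((10, 10, 8))
        v1 = assemble_features(make_bundle(mask, intensity=intensity))
        v2 = assemble_features(make_bundle(bigger, intensity=intensity))
        assert v2.total_volume >= v1.total_volume - 1e-12
        assert v2.total_area >= v1.total_area - 1e-12
        assert v2.extent_area >= v1.extent_area - 1e-12

    def test_voxel_size_covariance(self):
        """Same physical phantom at doubled en-face voxel size: features move
        only within discretization tolerance."""
        druse = [CapDruse((3.0, 3.0), 0.4, 0.25)]
        specs = [
            PhantomSpec(grid_shape=(160, 160, 256), voxel_size_mm=(6 / 160, 6 / 160, 2 / 256),
                        druse_list=druse),
            PhantomSpec(grid_shape=(80, 80, 256), voxel_size_mm=(6 / 80, 6 / 80, 2 / 256),
                        druse_list=druse),
        ]
        vecs = [assemble_features(generate_phantom(s)[0]) for s in specs]
        assert vecs[0].total_volume == pytest.approx(vecs[1].total_volume, rel=0.05)
        assert vecs[0].total_area == pytest.approx(vecs[1].total_area, rel=0.08)
        assert vecs[0].max_height == pytest.approx(vecs[1].max_height, abs=0.02)


class TestAverageSession:
    def test_single_vector_identity(self):
        v = ImagingFeatureVector(n_drusen=2, total_volume=0.1)
        out = average_session([v])
        np.testing.assert_array_equal(out.as_array(), v.as_array())

    def test_two_vector_mean(self):
        v1 = ImagingFeatureVector(total_volume=0.1)
        v2 = ImagingFeatureVector(total_volume=0.3)
        assert average_session([v1, v2]).total_volume == pytest.approx(0.2)

    def test_three_vector_elementwise_oracle(self):
        rng = np.random.default_rng(4)
        arrays = [rng.random(len(FEATURE_NAMES)) for _ in range(3)]
        vectors = [ImagingFeatureVector.from_array(a) for a in arrays]
        out = average_session(vectors)
        np.testing.assert_allclose(out.as_array(), np.mean(arrays, axis=0), atol=1e-12)

    def test_mixed_eyes_rejected(self):
        v = ImagingFeatureVector()
        with pytest.raises(ValueError, match="eye_ids"):
            average_session([v, v], eye_ids=["A", "B"])

    def test_mixed_dates_rejected(self):
        v = ImagingFeatureVector()
        with pytest.raises(ValueError, match="session_dates"):
            average_session([v, v], session_dates=["2020-01-01", "2020-02-01"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_session([])
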