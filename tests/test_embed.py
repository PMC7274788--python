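"""CBE: downsampling, condensation, reference clusters, features, moments."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cloudmorph import frames, synthgen
from cloudmorph.core import FeatureMatrix, PointCloud
from cloudmorph.embed import (ReferenceClusters, cbe_feature_matrix,
                              cbe_features, condense_cloud,
                              density_dependent_downsample,
                              fit_reference_clusters, local_densities,
                              median_pairwise_distance, moments_feature_names,
                              moments_features, pca_reduce)


def blob_halo_cloud(rng, n_blob=425, n_pairs=30, n_isolated=15):
    """Dense blob + close pairs + isolated points.

    The blob dominates the pairwise-distance median, so the density radius
    (median x 5) sees blob points at high local density, pair members at
    LD = 1 and isolated points at LD = 0; the 3rd-percentile target density
    falls strictly between 0 and 1.
    """
    blob = rng.normal(0, 1.0, (n_blob, 3))
    pairs = []
    for i in range(n_pairs):
        base = np.array([200.0 + 150.0 * i, 0.0, 0.0])
        pairs += [base, base + [3.0, 0, 0]]
    isolated = [np.array([-200.0 - 150.0 * i, 0.0, 0.0])
                for i in range(n_isolated)]
    return np.vstack([blob, np.array(pairs), np.array(isolated)])


class TestDensityDownsampling:
    def test_low_density_points_always_retained(self):
        rng = np.random.default_rng(0)
        pts = blob_halo_cloud(rng)
        radius = median_pairwise_distance(pts) * 5
        ld = local_densities(pts, radius)
        td = np.percentile(ld, 3)
        low = np.flatnonzero(ld < td)
        assert low.size > 0
        for seed in range(100):
            kept, p = density_dependent_downsample(pts, rng=seed)
            assert np.all(p[low] == 1.0)
            # the low-density points all survive
            for i in low:
                assert np.any(np.all(kept == pts[i], axis=1))

    def test_retention_frequency_matches_keep_probability(self):
        rng = np.random.default_rng(1)
        pts = blob_halo_cloud(rng)
        _, p = density_dependent_downsample(pts, rng=0)
        n_runs = 200
        for idx in [0, 425]:  # a dense blob point and a pair member
            hits = 0
            for seed in range(n_runs):
                kept, _ = density_dependent_downsample(pts, rng=seed)
                hits += np.any(np.all(kept == pts[idx], axis=1))
            expect = p[idx]
            sd = np.sqrt(expect * (1 - expect) / n_runs)
            assert abs(hits / n_runs - expect) < 3 * sd + 1e-9

    def test_cap_enforced_exactly(self):
        rng = np.random.default_rng(2)
        pts = rng.random((3000, 3))
        kept, _ = density_dependent_downsample(pts, max_points=1000, rng=3)
        assert kept.shape[0] == 1000

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            density_dependent_downsample(np.zeros((1, 3)))


class TestCondense:
    def test_k_equals_n_returns_points(self):
        pts = np.random.default_rng(0).normal(size=(30, 3))
        out = condense_cloud(pts, k=30, rng=0)
        np.testing.assert_allclose(np.sort(out, axis=0), np.sort(pts, axis=0))

    def test_k_one_returns_centroid(self):
        pts = np.random.default_rng(1).normal(size=(50, 3))
        out = condense_cloud(pts, k=1, rng=0)
        np.testing.assert_allclose(out[0], pts.mean(axis=0), atol=1e-9)

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.1, (1000, 3))
        b = rng.normal(0, 0.1, (1000, 3)) + np.array([10.0, 0, 0])
        centers = condense_cloud(np.vstack([a, b]), k=2, rng=1)
        centers = centers[np.argsort(centers[:, 0])]
        np.testing.assert_allclose(centers[0], a.mean(axis=0), atol=0.1)
        np.testing.assert_allclose(centers[1], b.mean(axis=0), atol=0.1)

    def test_fewer_points_than_k_rejected(self):
        with pytest.raises(ValueError):
            condense_cloud(np.zeros((5, 3)), k=10)


class TestReferenceClusters:
    def _clouds(self, n_samples=4, cells_per_sample=3, seed=0):
        rng = np.random.default_rng(seed)
        return {
            f"s{i}": [rng.normal(size=(600, 3)) for _ in range(cells_per_sample)]
            for i in range(n_samples)
        }

    def test_deterministic_given_seed(self):
        clouds = self._clouds()
        a = fit_reference_clusters(clouds, k=5, rng=42).centers
        b = fit_reference_clusters(clouds, k=5, rng=42).centers
        np.testing.assert_array_equal(a, b)

    def test_single_repeated_point_cell(self):
        cloud = np.tile([[1.0, 2.0, 3.0]], (600, 1))
        refs = fit_reference_clusters({"s": [cloud]}, k=1, rng=0)
        # centering moves the repeated point to the origin
        np.testing.assert_allclose(refs.centers[0], [0, 0, 0], atol=1e-9)

    def test_centers_inside_occupied_region(self):
        rng = np.random.default_rng(3)
        fam_a = [rng.normal(0, 1, (600, 3)) for _ in range(10)]
        fam_b = [rng.normal(0, 1, (600, 3)) * np.array([3, 0.5, 0.5])
                 for _ in range(10)]
        clouds = {f"a{i}": [c] for i, c in enumerate(fam_a)}
        clouds.update({f"b{i}": [c] for i, c in enumerate(fam_b)})
        refs = fit_reference_clusters(clouds, k=8, rng=1)
        all_pts = np.vstack(fam_a + fam_b)
        lo, hi = all_pts.min(axis=0), all_pts.max(axis=0)
        assert np.all(refs.centers >= lo) and np.all(refs.centers <= hi)


class TestCBEFeatures:
    def _refs(self, centers, frame="CFOR"):
        return ReferenceClusters(centers=np.asarray(centers, float),
                                 frame=frame, source_samples=("s",), seed=0)

    def test_vector_variant_dimensionality_is_3k(self):
        rng = np.random.default_rng(0)
        refs = self._refs(rng.normal(size=(20, 3)))
        row = cbe_features(rng.normal(size=(500, 3)), refs)
        assert row.shape == (60,)

    def test_single_centroid_geometry(self):
        # 25 identical points at the origin, one center at (1,0,0):
        # feature = centroid - center = (-1, 0, 0)
        cloud = np.zeros((25, 3))
        refs = self._refs([[1.0, 0.0, 0.0]])
        row = cbe_features(cloud, refs, n_neighbors=25)
        np.testing.assert_allclose(row, [-1.0, 0.0, 0.0], atol=1e-12)

    def test_magnitude_variant_is_norm_of_vectors(self):
        rng = np.random.default_rng(1)
        refs = self._refs(rng.normal(size=(7, 3)))
        for seed in range(50):
            pts = np.random.default_rng(seed).normal(size=(100, 3))
            vec = cbe_features(pts, refs, variant="vectors").reshape(7, 3)
            mag = cbe_features(pts, refs, variant="magnitudes")
            np.testing.assert_allclose(mag, np.linalg.norm(vec, axis=1),
                                       atol=1e-12)

    def test_cloud_smaller_than_neighbors_rejected(self):
        refs = self._refs(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            cbe_features(np.zeros((10, 3)), refs, n_neighbors=25)

    def test_cfor_route_invariant_to_similarity_transforms(self):
        """CBE rows from the CFOR pipeline agree across rigid + scale
        transformed replicates of the same cell (same references)."""
        rng = np.random.default_rng(2)
        refs = self._refs(rng.normal(size=(10, 3)) * 0.0005)
        for seed in range(3):
            cell = synthgen.generate_cell_cloud(
                synthgen.sample_generator_params(seed), seed)
            pts = cell.cloud.points
            rot = Rotation.random(random_state=seed).as_matrix()
            moved = (pts @ rot.T) * 3.7 + np.array([5.0, -2.0, 8.0])
            a = cbe_features(frames.cfor_pipeline(PointCloud(pts)).rep, refs)
            b = cbe_features(frames.cfor_pipeline(PointCloud(moved)).rep, refs)
            assert np.abs(a - b).max() < 1e-6


class TestPCAReduce:
    def test_ratios_non_increasing_and_bounded(self):
        rng = np.random.default_rng(0)
        fm = FeatureMatrix(rng.normal(size=(50, 8)),
                           feature_names=[f"f{i}" for i in range(8)])
        _, model = pca_reduce(fm, n_keep=5)
        r = model.explained_variance_ratios
        assert np.all(np.diff(r) <= 1e-12)
        assert r.sum() <= 1 + 1e-9

    def test_rank_one_data_concentrates_in_pc1(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(60, 1))
        v = rng.normal(size=(1, 6))
        fm = FeatureMatrix(u @ v, feature_names=[f"f{i}" for i in range(6)])
        _, model = pca_reduce(fm, n_keep=3)
        assert model.explained_variance_ratios[0] >= 0.999

    def test_sign_anchoring_makes_pc_positively_correlated(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(80, 5))
        fm = FeatureMatrix(x, feature_names=[f"f{i}" for i in range(5)])
        pcs_plain, _ = pca_reduce(fm, n_keep=2)
        anchor = -pcs_plain.values[:, [0]]  # engineered feature anti-aligned
        pcs, model = pca_reduce(fm, n_keep=2, sign_anchor=anchor)
        corr = np.corrcoef(pcs.values[:, 0], anchor[:, 0])[0, 1]
        assert corr > 0

    def test_transform_reproduces_scores(self):
        rng = np.random.default_rng(3)
        fm = FeatureMatrix(rng.normal(size=(40, 6)),
                           feature_names=[f"f{i}" for i in range(6)])
        pcs, model = pca_reduce(fm, n_keep=4)
        np.testing.assert_allclose(model.transform(fm.values), pcs.values,
                                   atol=1e-9)


class TestMoments:
    def test_exactly_55_features(self):
        names = moments_feature_names()
        assert len(names) == 55
        row = moments_features(np.random.default_rng(0).normal(size=(50, 3)))
        assert row.shape == (55,)
        # 3 + 6 + 10 + 15 + 21 split
        assert sum(n.startswith("rM1") for n in names) == 3
        assert sum(n.startswith("cM2") for n in names) == 6
        assert sum(n.startswith("nM3") for n in names) == 10
        assert sum(n.startswith("nM4") for n in names) == 15
        assert sum(n.startswith("nM5") for n in names) == 21

    def test_gaussian_cloud_matches_closed_forms(self):
        pts = np.random.default_rng(1).normal(size=(100_000, 3))
        row = dict(zip(moments_feature_names(), moments_features(pts)))
        # second centralized moments: identity covariance
        for name in ["cM2_200", "cM2_020", "cM2_002"]:
            assert abs(row[name] - 1.0) < 0.02
        for name in ["cM2_110", "cM2_101", "cM2_011"]:
            assert abs(row[name]) < 0.02
        # pure fourth standardized moments = 3; odd moments = 0
        for name in ["nM4_400", "nM4_040", "nM4_004"]:
            assert abs(row[name] - 3.0) < 0.1
        for name in ["nM3_300", "nM3_030", "nM3_003", "nM5_500"]:
            assert abs(row[name]) < 0.1

    def test_mirror_parity(self):
        pts = np.random.default_rng(2).normal(size=(500, 3)) + 0.3
        mirrored = pts * np.array([1, 1, -1])  # flip x
        names = moments_feature_names()
        a = moments_features(pts)
        b = moments_features(mirrored)
        for name, va, vb in zip(names, a, b):
            if not name.startswith("n"):
                continue
            k = int(name.split("_")[1][2])  # x exponent
            if k % 2:
                np.testing.assert_allclose(vb, -va, atol=1e-12)
            else:
                np.testing.assert_allclose(vb, va, atol=1e-12)

    def test_permutation_invariance(self):
        pts = np.random.default_rng(3).normal(size=(200, 3))
        perm = np.random.default_rng(4).permutation(200)
        np.testing.assert_allclose(moments_features(pts),
                                   moments_features(pts[perm]), atol=1e-12)

    def test_degenerate_axis_rejected(self):
        pts = np.zeros((10, 3))
        pts[:, 0] = np.arange(10)
        with pytest.raises(ValueError):
            moments_features(pts)
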