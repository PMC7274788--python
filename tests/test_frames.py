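"""TFOR/CFOR normalization and engineered features."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from cloudmorph import frames, synthgen
from cloudmorph.core import PointCloud
from cloudmorph.frames import (apply_tfor, cfor_normalize, cfor_pipeline,
                               engineered_features, fit_tfor,
                               pairwise_distance_representation)


def ellipsoid_mask(shape, semi, center=None, rot=None):
    """Binary ellipsoid; semi-axes in voxels along (z, y, x)."""
    grid = np.stack(np.meshgrid(*(np.arange(s) for s in shape),
                                indexing="ij"), axis=-1).astype(float)
    c = np.array(shape) / 2 if center is None else np.asarray(center)
    rel = grid - c
    if rot is not None:
        rel = rel @ rot.T
    return ((rel / np.asarray(semi)) ** 2).sum(axis=-1) <= 1.0


def teardrop_mask(shape=(40, 56, 120)):
    """Asymmetric tissue stand-in: tapering ellipsoid, asymmetric on every
    axis so the skewness-based flip rule is decisive."""
    z, y, x = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    c = np.array(shape) / 2
    xr = (x - c[2]) / 50.0
    taper = np.clip(1.0 - 0.45 * xr, 0.3, 2.0)
    ry = 18.0 * taper * np.where(y >= c[1], 1.25, 0.75)
    rz = 12.0 * taper * np.where(z >= c[0], 1.2, 0.8)
    return (xr ** 2 + ((y - c[1]) / ry) ** 2 + ((z - c[0]) / rz) ** 2) <= 1.0


class TestFitTFOR:
    def test_recovers_ellipsoid_axes_within_two_degrees(self):
        mask = ellipsoid_mask((20, 30, 70), semi=(5, 10, 30))
        t = fit_tfor(mask, spacing=(1, 1, 1), rng=0)
        # axis 0 (front-rear) = x, axis 1 = y, axis 2 (apicobasal) = z
        for row, unit in zip(t.rotation, [(0, 0, 1), (0, 1, 0), (1, 0, 0)]):
            angle = np.degrees(np.arccos(min(abs(np.dot(row, unit)), 1.0)))
            assert angle < 2.0

    def test_frontal_most_point_at_origin(self):
        mask = teardrop_mask()
        t = fit_tfor(mask, spacing=(1, 1, 1), rng=1)
        from cloudmorph.core import IntensityVolume
        from cloudmorph.isla import sample_landmarks

        cloud = sample_landmarks(IntensityVolume(mask.astype(float), (1, 1, 1)),
                                 n_points=3000, rng=1)
        scores = t.apply(cloud.points)
        assert abs(scores[:, 0].min()) < 1e-9

    def test_invariant_to_in_plane_acquisition_angle(self):
        # The same tissue acquired at a 15 degree mounting angle lands on the
        # same tissue frame: matched points map to matched TFOR coordinates.
        shape = (40, 80, 120)
        base = teardrop_mask()
        pad = np.zeros(shape, bool)
        pad[:base.shape[0], 12:12 + base.shape[1], :base.shape[2]] = base
        rot = Rotation.from_euler("z", 15, degrees=True).as_matrix()
        # rotate mask about its center within the (y, x) plane
        grid = np.stack(np.meshgrid(*(np.arange(s) for s in shape),
                                    indexing="ij"), axis=-1).astype(float)
        c = np.array(shape) / 2
        rel = grid - c
        rot_zyx = np.eye(3)
        rot_zyx[1:, 1:] = rot[:2, :2]
        src = rel @ rot_zyx + c
        idx = np.round(src).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=-1)
        rotated = np.zeros(shape, bool)
        rotated[ok] = pad[idx[ok, 0], idx[ok, 1], idx[ok, 2]]

        t1 = fit_tfor(pad, spacing=(1, 1, 1), rng=0)
        t2 = fit_tfor(rotated, spacing=(1, 1, 1), rng=0)
        pts = np.argwhere(pad)[::47].astype(float)
        pts_rot = (pts - c) @ np.linalg.inv(rot_zyx) + c
        a = t1.apply(pts)
        b = t2.apply(pts_rot)
        assert np.abs(a - b).mean() < 1.0
        assert np.abs(a - b).max() < 4.0

    def test_mirrored_tissue_keeps_consistent_front_rear_orientation(self):
        mask = teardrop_mask()
        mirrored = mask[:, :, ::-1]
        t1 = fit_tfor(mask, spacing=(1, 1, 1), rng=0)
        t2 = fit_tfor(mirrored, spacing=(1, 1, 1), rng=0)
        pts = np.argwhere(mask).astype(float)
        pts_m = pts.copy()
        pts_m[:, 2] = mask.shape[2] - 1 - pts[:, 2]
        s1 = t1.apply(pts)[:, 0]
        s2 = t2.apply(pts_m)[:, 0]
        # same front-rear profile (no 180 degree flip): skewness signs agree
        sk1 = np.mean((s1 - s1.mean()) ** 3)
        sk2 = np.mean((s2 - s2.mean()) ** 3)
        assert np.sign(sk1) == np.sign(sk2)

    def test_degenerate_mask_rejected(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        with pytest.raises(ValueError):
            fit_tfor(mask, spacing=(1, 1, 1), rng=0)


class TestApplyTFOR:
    def test_identity_transform_preserves_cloud(self):
        t = frames.TFORTransform(np.eye(3), np.zeros(3), (1, 1, 1))
        cloud = PointCloud(np.random.default_rng(0).normal(size=(50, 3)))
        out = apply_tfor(cloud, t)
        np.testing.assert_array_equal(out.points, cloud.points)
        assert out.frame == "TFOR"

    def test_rigid_motion_preserves_pairwise_distances(self):
        rot = Rotation.from_euler("xyz", [10, 30, 75], degrees=True).as_matrix()
        t = frames.TFORTransform(rot, np.array([5.0, -2.0, 1.0]), (1, 1, 1))
        pts = np.random.default_rng(1).normal(size=(80, 3))
        out = apply_tfor(PointCloud(pts), t)
        np.testing.assert_allclose(pdist(out.points), pdist(pts), rtol=1e-10)

    def test_sample_mismatch_rejected(self):
        t = frames.TFORTransform(np.eye(3), np.zeros(3), (1, 1, 1),
                                 sample_id="s1")
        cloud = PointCloud(np.zeros((2, 3)) + [[0, 0, 0], [1, 1, 1]],
                           sample_id="s2")
        with pytest.raises(ValueError, match="sample_id"):
            apply_tfor(cloud, t)


class TestCFORNormalize:
    def test_magnitudes_sum_to_one(self):
        cloud = PointCloud(np.random.default_rng(0).normal(size=(100, 3)) * 7)
        out = cfor_normalize(cloud)
        mags = np.linalg.norm(out.points - out.points.mean(axis=0), axis=1)
        assert abs(mags.sum() - 1.0) < 1e-12

    def test_scale_invariance(self):
        pts = np.random.default_rng(1).normal(size=(60, 3))
        a = cfor_normalize(PointCloud(pts)).points
        b = cfor_normalize(PointCloud(pts * 37.5)).points
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_two_point_closed_form(self):
        # sum of the two centroid distances is 1 => each point at +/- 0.5 u
        cloud = PointCloud(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 4.0]]))
        out = cfor_normalize(cloud).points
        np.testing.assert_allclose(out, [[0, 0, -0.5], [0, 0, 0.5]], atol=1e-12)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            cfor_normalize(PointCloud(np.ones((5, 3))))


class TestPDRepresentation:
    def test_invariant_to_rigid_motion_and_mirror(self):
        pts = np.random.default_rng(2).normal(size=(120, 3))
        rot = Rotation.from_euler("zyx", [12, 110, -40], degrees=True).as_matrix()
        mirrored = pts @ rot.T * np.array([1, 1, -1]) + np.array([3, -1, 2])
        a = pairwise_distance_representation(PointCloud(pts)).rep
        b = pairwise_distance_representation(PointCloud(mirrored)).rep
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_two_point_rows(self):
        rep = pairwise_distance_representation(
            PointCloud(np.array([[0, 0, 0], [0, 0, 3.0]]))).rep
        np.testing.assert_allclose(rep, [[3, 3, 3], [3, 3, 3]])

    def test_three_point_row_against_percentile_oracle(self):
        pts = np.array([[0, 0, 0], [3.0, 0, 0], [0, 4.0, 0]])
        cloud = PointCloud(pts[:, ::-1])  # (z,y,x) ordering irrelevant
        rep = pairwise_distance_representation(cloud).rep
        expected_row0 = np.percentile([3.0, 4.0], [10, 50, 90])
        np.testing.assert_allclose(rep[0], expected_row0, atol=1e-12)

    def test_columns_monotone_for_random_clouds(self):
        for seed in range(5):
            pts = np.random.default_rng(seed).normal(size=(40, 3))
            rep = pairwise_distance_representation(PointCloud(pts)).rep
            assert np.all(rep[:, 0] <= rep[:, 1])
            assert np.all(rep[:, 1] <= rep[:, 2])

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance_representation(PointCloud(np.zeros((1, 3))))


class TestCFORPipelineInvariance:
    def test_full_similarity_invariance(self):
        """normalize -> PD output identical under translation, rotation,
        reflection and uniform scaling."""
        rng = np.random.default_rng(3)
        for seed in range(5):
            cell = synthgen.generate_cell_cloud(
                synthgen.sample_generator_params(seed), seed)
            pts = cell.cloud.points
            rot = Rotation.random(random_state=seed).as_matrix()
            flip = np.diag([1, -1, 1]) if seed % 2 else np.eye(3)
            s = rng.uniform(0.2, 5.0)
            moved = (pts @ rot.T @ flip) * s + rng.normal(size=3) * 10
            a = cfor_pipeline(PointCloud(pts)).rep
            b = cfor_pipeline(PointCloud(moved)).rep
            assert np.abs(a - b).max() < 1e-9


class TestEngineeredFeatures:
    def test_digital_ball_sphericity_near_one(self):
        r = 10
        mask = ellipsoid_mask((24, 24, 24), semi=(r, r, r))
        cloud = PointCloud(np.argwhere(mask).astype(float))
        row = engineered_features(mask, (1, 1, 1), cloud)
        assert abs(row["sphericity"] - 1.0) < 0.05

    def test_box_extents_in_microns(self):
        pts = np.array([[0, 0, 0], [5.0, 10.0, 20.0], [2.0, 3.0, 7.0]])
        mask = np.ones((2, 2, 2), bool)
        row = engineered_features(mask, (1, 1, 1), PointCloud(pts))
        assert (row["extent_ax0_um"], row["extent_ax1_um"],
                row["extent_ax2_um"]) == (5.0, 10.0, 20.0)

    def test_volume_arithmetic(self):
        mask = np.zeros((10, 10, 10), bool)
        mask.ravel()[:1000] = True
        cloud = PointCloud(np.random.default_rng(0).normal(size=(10, 3)))
        row = engineered_features(mask, (0.1, 0.1, 0.2), cloud)
        assert abs(row["volume_um3"] - 2.0) < 1e-9

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            engineered_features(np.zeros((3, 3, 3), bool), (1, 1, 1),
                                PointCloud(np.zeros((2, 3))))
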