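"""Cubic neighborhoods, plane fitting, angle conversion, leaf signs."""

import numpy as np
import pytest

from phytocloud import (
    ColoredPointCloud,
    NeighborhoodSpec,
    apply_leaf_sign,
    compute_angle_field,
    cube_neighborhood,
    fit_plane_normal,
    normal_to_angles,
)
from phytocloud.cloud import CALIBRATED
from phytocloud.errors import (
    DegenerateNeighborhoodError,
    FrameError,
    ValidationError,
)
from conftest import planar_patch


def brute_force_cube(points, center, side):
    """Exhaustive O(n) scan oracle for the closed axis-aligned cube."""
    inside = np.all(np.abs(points - center) <= side / 2.0, axis=1)
    return np.flatnonzero(inside)


class TestCubeNeighborhood:
    def test_inclusion_and_exclusion(self):
        cloud = ColoredPointCloud(
            points=[[0, 0, 0], [0.2, 0, 0], [0.3, 0, 0]], frame=CALIBRATED
        )
        idx = cube_neighborhood(cloud, 0, NeighborhoodSpec(cube_side=0.5))
        assert idx.tolist() == [0, 1]

    def test_closed_boundary(self):
        cloud = ColoredPointCloud(
            points=[[0, 0, 0], [0.25, 0, 0]], frame=CALIBRATED
        )
        idx = cube_neighborhood(cloud, 0, NeighborhoodSpec(cube_side=0.5))
        assert 1 in idx

    def test_uncalibrated_cloud_rejected(self):
        cloud = ColoredPointCloud(points=[[0, 0, 0]], frame="raw")
        with pytest.raises(FrameError):
            cube_neighborhood(cloud, 0, NeighborhoodSpec())

    def test_grid_matches_exhaustive_scan(self):
        axis = np.arange(-0.5, 0.5001, 0.1)
        grid = np.stack(np.meshgrid(axis, axis, axis), axis=-1).reshape(-1, 3)
        cloud = ColoredPointCloud(points=grid, frame=CALIBRATED)
        spec = NeighborhoodSpec(cube_side=0.5)
        for index in (0, len(grid) // 2, len(grid) - 1):
            got = cube_neighborhood(cloud, index, spec)
            want = brute_force_cube(grid, grid[index], 0.5)
            assert np.array_equal(got, want)

    def test_random_clouds_match_exhaustive_scan(self, rng):
        for _ in range(10):
            points = rng.uniform(-2, 2, (int(rng.integers(50, 2000)), 3))
            cloud = ColoredPointCloud(points=points, frame=CALIBRATED)
            spec = NeighborhoodSpec(cube_side=float(rng.uniform(0.2, 1.0)))
            index = int(rng.integers(0, len(points)))
            got = cube_neighborhood(cloud, index, spec)
            want = brute_force_cube(points, points[index], spec.cube_side)
            assert np.array_equal(got, want)


class TestFitPlaneNormal:
    def test_horizontal_plane(self, rng):
        pts = np.column_stack([rng.uniform(-1, 1, 50), rng.uniform(-1, 1, 50),
                               np.zeros(50)])
        np.testing.assert_allclose(fit_plane_normal(pts), [0, 0, 1], atol=1e-12)

    def test_45_degree_plane_up_signed(self, rng):
        x = rng.uniform(-1, 1, 100)
        y = rng.uniform(-1, 1, 100)
        pts = np.column_stack([x, y, x])  # plane z = x
        normal = fit_plane_normal(pts)
        np.testing.assert_allclose(
            normal, np.array([-1.0, 0.0, 1.0]) / np.sqrt(2), atol=1e-9
        )

    def test_collinear_points_degenerate(self):
        t = np.linspace(0, 1, 10)
        pts = np.column_stack([t, 2 * t, 3 * t])
        with pytest.raises(DegenerateNeighborhoodError):
            fit_plane_normal(pts)

    def test_noisy_plane_within_pilot_tolerance(self, rng):
        """200 points, ortho-noise sigma = 0.01·L on a 0.5 cm patch: the
        pre-computed 500-rep pilot put the 99th-percentile normal error at
        0.45 degrees; assert within 0.6."""
        for _ in range(20):
            zen = np.degrees(np.arccos(rng.uniform(0, 1)))
            azi = rng.uniform(0, 360)
            cloud, true_normal = planar_patch(
                zen, azi, n=200, extent=0.25, noise=0.005,
                seed=int(rng.integers(1 << 31)),
            )
            normal = fit_plane_normal(cloud.points)
            angle = np.degrees(np.arccos(np.clip(abs(normal @ true_normal), 0, 1)))
            assert angle <= 0.6


class TestNormalToAngles:
    @pytest.mark.parametrize("normal,zen,azi", [
        ((1.0, 0.0, 0.0), 90.0, 0.0),
        ((0.5, 0.5, np.sqrt(2) / 2), 45.0, 45.0),
        ((0.0, 1.0, 0.0), 90.0, 90.0),
    ])
    def test_reference_directions(self, normal, zen, azi):
        z, a, defined = normal_to_angles(np.array(normal))
        assert z == pytest.approx(zen)
        assert a == pytest.approx(azi)
        assert defined

    def test_vertical_normal_azimuth_flagged(self):
        z, a, defined = normal_to_angles(np.array([0.0, 0.0, 1.0]))
        assert z == 0.0
        assert not defined

    def test_non_unit_rejected(self):
        with pytest.raises(ValidationError):
            normal_to_angles(np.array([0.0, 0.0, 2.0]))


class TestComputeAngleField:
    def test_exact_recovery_on_noiseless_plane(self):
        cloud, _ = planar_patch(37.0, 123.0, n=600, extent=1.0, seed=3)
        field = compute_angle_field(cloud, NeighborhoodSpec())
        valid = field.valid
        assert valid.sum() > 0.9 * len(cloud)
        np.testing.assert_allclose(field.zenith[valid], 37.0, atol=1e-6)
        np.testing.assert_allclose(field.azimuth[valid], 123.0, atol=1e-6)

    def test_sparse_points_masked_matches_census(self, rng):
        import warnings

        points = rng.uniform(-3, 3, (300, 3))
        cloud = ColoredPointCloud(points=points, frame=CALIBRATED)
        spec = NeighborhoodSpec(cube_side=0.5, min_points=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            field = compute_angle_field(cloud, spec)
        for i in range(len(cloud)):
            n_inside = len(brute_force_cube(points, points[i], 0.5))
            assert field.n_neighbors[i] == n_inside
            if n_inside < spec.min_points:
                assert not field.valid[i]

    def test_all_masked_warns(self, rng):
        cloud = ColoredPointCloud(
            points=rng.uniform(-10, 10, (20, 3)), frame=CALIBRATED
        )
        with pytest.warns(UserWarning, match="masked"):
            field = compute_angle_field(cloud, NeighborhoodSpec(cube_side=0.1))
        assert not field.valid.any()

    def test_curved_surface_matches_analytic_normals(self):
        """Densely sampled parabolic leaf: fitted zeniths track the analytic
        surface-normal zeniths to within the local-planarity bias."""
        from phytocloud.synthetic import LeafSpec, make_leaf

        spec = LeafSpec(label=1, curvature=0.4, noise_sigma=0.0,
                        point_density=600.0, zenith_true=20.0)
        cloud, truth = make_leaf(spec, seed=11)
        field = compute_angle_field(cloud, NeighborhoodSpec())
        valid = field.valid
        err = np.abs(field.zenith[valid] - truth.zenith[valid])
        assert np.median(err) <= 1.0

    def test_rotation_equivariance_about_z(self):
        alpha = 73.0
        cloud, _ = planar_patch(30.0, 40.0, n=500, extent=1.0, seed=9)
        field = compute_angle_field(cloud.copy(), NeighborhoodSpec())
        rad = np.radians(alpha)
        rz = np.array([
            [np.cos(rad), -np.sin(rad), 0], [np.sin(rad), np.cos(rad), 0],
            [0, 0, 1],
        ])
        rotated = ColoredPointCloud(
            points=cloud.points @ rz.T, colors=cloud.colors, frame=CALIBRATED
        )
        field_rot = compute_angle_field(rotated, NeighborhoodSpec())
        both = field.valid & field_rot.valid
        np.testing.assert_allclose(
            field_rot.zenith[both], field.zenith[both], atol=1e-6
        )
        shifted = (field.azimuth[both] + alpha) % 360.0
        diff = np.abs(field_rot.azimuth[both] - shifted)
        diff = np.minimum(diff, 360.0 - diff)
        assert diff.max() <= 1e-6


class TestApplyLeafSign:
    def _field_and_cloud(self):
        from phytocloud.synthetic import LeafSpec, make_leaf

        cloud, _ = make_leaf(
            LeafSpec(label=1, zenith_true=23.7, noise_sigma=0.0,
                     point_density=100.0), seed=2,
        )
        field = compute_angle_field(cloud, NeighborhoodSpec())
        return field, cloud

    def test_down_leaf_negated(self):
        field, cloud = self._field_and_cloud()
        signed = apply_leaf_sign(field, cloud, {1: "down"})
        valid = signed.valid
        np.testing.assert_allclose(
            signed.signed_zenith[valid], -field.zenith[valid]
        )
        assert np.nanmedian(signed.signed_zenith[valid]) == pytest.approx(
            -23.7, abs=1e-5
        )

    def test_up_flags_identity(self):
        field, cloud = self._field_and_cloud()
        signed = apply_leaf_sign(field, cloud, {1: "up"})
        np.testing.assert_array_equal(signed.signed_zenith, field.zenith)

    def test_unknown_label_rejected(self):
        field, cloud = self._field_and_cloud()
        with pytest.raises(ValidationError, match="99"):
            apply_leaf_sign(field, cloud, {99: "down"})
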