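"""Alpha-shape reconstruction, surface area and convex-hull volume."""

import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from tillerscan import (AlphaSweepParams, PointCloud, TriangleMesh,
                        alpha_shape_mesh, auto_alpha, convex_hull_volume,
                        mesh_surface_area)
from tillerscan.errors import (AlphaSweepError, DegenerateGeometryError,
                               EmptyMeshError)
from tillerscan.surface_volume import _AlphaShapeContext, _largest_component_share

CUBE = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                dtype=float)


def _sphere_sample(n, radius, rng, noise=0.0):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    pts = v * radius
    if noise:
        pts = pts + rng.normal(scale=noise, size=pts.shape)
    return pts


class TestMeshSurfaceArea:
    def test_single_triangle(self):
        mesh = TriangleMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.]]),
                            np.array([[0, 1, 2]]), alpha_used=1.0)
        assert mesh_surface_area(mesh) == pytest.approx(0.5)

    def test_duplicated_triangles_double_area(self, rng):
        v = rng.normal(size=(9, 3))
        t = np.array([[0, 1, 2], [3, 4, 5], [6, 7, 8]])
        once = TriangleMesh(v, t, 1.0)
        twice = TriangleMesh(v, np.vstack([t, t]), 1.0)
        assert mesh_surface_area(twice) == pytest.approx(
            2 * mesh_surface_area(once), rel=1e-12)

    def test_unit_cube_hull_area(self):
        mesh = alpha_shape_mesh(PointCloud(CUBE), math.inf)
        assert mesh_surface_area(mesh) == pytest.approx(6.0)

    def test_degenerate_triangle_contributes_zero(self):
        mesh = TriangleMesh(np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2.]]),
                            np.array([[0, 1, 2]]), 1.0)
        assert mesh_surface_area(mesh) == 0.0


class TestAlphaShapeMesh:
    def test_large_alpha_equals_convex_hull_on_cube(self):
        """With a probe ball much larger than the cloud, only hull facets
        admit an empty ball: the mesh is the convex hull."""
        mesh = alpha_shape_mesh(PointCloud(CUBE), 10.0)
        assert mesh_surface_area(mesh) == pytest.approx(6.0)

    def test_infinite_alpha_matches_hull_area_random_cloud(self, rng):
        pts = rng.uniform(size=(500, 3))
        mesh = alpha_shape_mesh(PointCloud(pts), math.inf)
        hull = ConvexHull(pts)
        assert mesh_surface_area(mesh) == pytest.approx(hull.area, rel=1e-6)
        assert math.isinf(mesh.alpha_used)

    def test_sphere_sample_area_close_to_analytic(self, rng):
        """A uniform sphere sample reconstructs to ~4*pi*r^2."""
        pts = _sphere_sample(5000, 0.1, rng)
        mesh = alpha_shape_mesh(PointCloud(pts), 0.05)
        assert mesh_surface_area(mesh) == pytest.approx(
            4 * np.pi * 0.1 ** 2, rel=0.05)

    def test_tiny_alpha_raises_empty_mesh(self, rng):
        pts = _sphere_sample(2000, 0.1, rng, noise=1e-5)
        with pytest.raises(EmptyMeshError):
            alpha_shape_mesh(PointCloud(pts), 1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            alpha_shape_mesh(PointCloud(np.eye(3)), 0.1)


class TestAutoAlpha:
    def test_minimality_when_alpha_min_qualifies(self, rng):
        """A sample dense relative to alpha_min returns alpha_min itself."""
        pts = _sphere_sample(6000, 0.05, rng, noise=1e-5)
        params = AlphaSweepParams(alpha_min=0.01, alpha_step=0.005,
                                  alpha_max=0.1)
        assert auto_alpha(PointCloud(pts), params) == pytest.approx(0.01)

    def test_returned_alpha_is_first_qualifying(self, rng):
        """The selected alpha meets the connected-component criterion and
        the previous grid value does not (checked against the criterion
        directly)."""
        pts = _sphere_sample(1200, 0.05, rng, noise=1e-5)
        params = AlphaSweepParams(alpha_min=0.002, alpha_step=0.001,
                                  alpha_max=0.1)
        alpha = auto_alpha(PointCloud(pts), params)
        ctx = _AlphaShapeContext(pts)

        def qualifies(a):
            faces = ctx.boundary_faces(a)
            return faces.shape[0] > 0 and \
                _largest_component_share(faces, len(pts)) >= 0.99

        assert qualifies(alpha)
        assert alpha > params.alpha_min
        assert not qualifies(alpha - params.alpha_step)

    def test_two_distant_objects_never_accepted(self, rng):
        """Two sphere samples 1 m apart cannot give a connected mesh for any
        alpha far below the gap, so a capped sweep fails rather than
        returning a two-component alpha."""
        a = _sphere_sample(400, 0.05, rng, noise=1e-5)
        b = _sphere_sample(400, 0.05, rng, noise=1e-5) + [1.0, 0, 0]
        params = AlphaSweepParams(alpha_min=0.01, alpha_step=0.01,
                                  alpha_max=0.15)
        with pytest.raises(AlphaSweepError):
            auto_alpha(PointCloud(np.vstack([a, b])), params)


class TestConvexHullVolume:
    def test_unit_cube(self):
        assert convex_hull_volume(PointCloud(CUBE)) == pytest.approx(1.0)

    def test_interior_points_do_not_change_hull(self, rng):
        pts = np.vstack([CUBE, rng.uniform(0.01, 0.99, size=(500, 3))])
        assert convex_hull_volume(PointCloud(pts)) == pytest.approx(1.0)

    def test_regular_tetrahedron_closed_form(self):
        tet = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0],
                        [0.5, np.sqrt(3) / 6, np.sqrt(6) / 3]])
        assert convex_hull_volume(PointCloud(tet)) == pytest.approx(
            np.sqrt(2) / 12, rel=1e-12)

    def test_coplanar_cloud_rejected(self, rng):
        xy = rng.normal(size=(50, 2))
        pts = np.column_stack([xy, np.zeros(50)])
        with pytest.raises(DegenerateGeometryError):
            convex_hull_volume(PointCloud(pts))

    def test_rigid_motion_invariance_and_cubic_scaling(self, rng):
        pts = rng.normal(size=(100, 3))
        v = convex_hull_volume(PointCloud(pts))
        th = 0.5
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        moved = pts @ rot.T + [1, 2, 3]
        assert convex_hull_volume(PointCloud(moved)) == pytest.approx(v, rel=1e-9)
        assert convex_hull_volume(PointCloud(2.5 * pts)) == pytest.approx(
            2.5 ** 3 * v, rel=1e-9)


def test_mesh_export_readable(tmp_path, rng):
    import trimesh
    pts = _sphere_sample(500, 0.1, rng, noise=1e-4)
    mesh = alpha_shape_mesh(PointCloud(pts), 0.05)
    from tillerscan.surface_volume import export_mesh
    out = tmp_path / "shape.ply"
    export_mesh(mesh, out)
    back = trimesh.load(str(out), process=False)
    assert len(back.faces) == mesh.n_triangles
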