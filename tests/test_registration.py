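"""ICP rigid registration and the mean surface-discrepancy statistic:
exact transform recovery, RMS monotonicity, stopping rule, and the
point-to-mesh distance against a brute-force all-triangle oracle."""

import numpy as np
import pytest

from osteosurf.geometry import RigidTransform, SurfaceGrid, TriMesh, point_mesh_distance, rotation_about_axis
from osteosurf.registration import (
    best_fit_rigid,
    icp_register,
    mean_surface_discrepancy,
    surface_to_mesh,
    surface_to_pointcloud,
)


def _wavy_cloud(n_side=100, seed=0, size_um=7000.0):
    """Synthetic tidemark-like point cloud (n_side^2 points)."""
    rng = np.random.default_rng(seed)
    c = np.linspace(0, size_um, n_side)
    Y, X = np.meshgrid(c, c, indexing="ij")
    Z = (
        1000.0
        + 80 * np.sin(2 * np.pi * X / 5400) * np.cos(2 * np.pi * Y / 4100)
        + rng.normal(0, 20, size=X.shape)
    )
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def brute_force_point_triangle(p, tri):
    """Oracle: min distance to plane projection (if inside) and to the
    three edges; formulated independently of the implementation's
    Voronoi-region case analysis."""
    a, b, c = tri
    n = np.cross(b - a, c - a)
    nn = n / np.linalg.norm(n)
    best = np.inf
    # face candidate via barycentric coordinates of the plane projection
    q = p - np.dot(p - a, nn) * nn
    T = np.column_stack([b - a, c - a])
    uv, *_ = np.linalg.lstsq(T, q - a, rcond=None)
    if uv[0] >= -1e-12 and uv[1] >= -1e-12 and uv.sum() <= 1 + 1e-12:
        best = np.linalg.norm(p - q)
    # edge candidates
    for e0, e1 in ((a, b), (b, c), (c, a)):
        d = e1 - e0
        t = np.clip(np.dot(p - e0, d) / np.dot(d, d), 0.0, 1.0)
        best = min(best, np.linalg.norm(p - (e0 + t * d)))
    return best


class TestSurfaceConversion:
    def test_grid_nodes_become_points_with_exact_coordinates(self):
        s = SurfaceGrid([[10.0, 20.0], [30.0, 40.0]], (32.0, 15.0))
        pts = surface_to_pointcloud(s)
        assert pts.shape == (4, 3)
        assert pts.tolist() == [
            [0.0, 0.0, 10.0],
            [15.0, 0.0, 20.0],
            [0.0, 32.0, 30.0],
            [15.0, 32.0, 40.0],
        ]

    def test_invalid_nodes_excluded_on_request(self):
        s = SurfaceGrid(
            [[10.0, 20.0], [30.0, 40.0]],
            (32.0, 15.0),
            valid_mask=[[True, False], [True, True]],
        )
        assert surface_to_pointcloud(s, exclude_invalid=True).shape == (3, 3)

    def test_doubling_spacing_doubles_lateral_coordinates(self):
        h = [[1.0, 2.0], [3.0, 4.0]]
        p1 = surface_to_pointcloud(SurfaceGrid(h, (10.0, 10.0)))
        p2 = surface_to_pointcloud(SurfaceGrid(h, (20.0, 20.0)))
        assert np.allclose(p2[:, :2], 2 * p1[:, :2])
        assert np.allclose(p2[:, 2], p1[:, 2])

    def test_triangle_count(self):
        for ny, nx in ((2, 2), (5, 7)):
            s = SurfaceGrid(np.zeros((ny, nx)), (10.0, 10.0))
            mesh = surface_to_mesh(s)
            assert len(mesh.faces) == 2 * (ny - 1) * (nx - 1)

    def test_planar_grid_has_parallel_normals(self):
        y, x = np.mgrid[0:4, 0:5].astype(float)
        s = SurfaceGrid(2 * x - y + 5, (10.0, 10.0))
        mesh = surface_to_mesh(s)
        tris = mesh.triangles
        normals = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        assert np.allclose(np.abs(normals @ normals[0]), 1.0, atol=1e-9)


class TestICP:
    def test_identical_clouds_give_identity(self):
        cloud = _wavy_cloud(n_side=30)
        res = icp_register(cloud, cloud, init=None)
        assert res.converged
        assert res.rms_history[-1] < 1e-9
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(res.transform.translation, 0, atol=1e-6)

    def test_pure_translation_recovered(self):
        cloud = _wavy_cloud(n_side=40)
        t = np.array([100.0, -50.0, 20.0])
        res = icp_register(cloud, cloud + t)
        assert np.abs(res.transform.translation - t).max() < 0.1
        assert res.transform.rotation_angle_deg() < 0.001

    def test_rotation_plus_translation_recovered(self):
        cloud = _wavy_cloud(n_side=40)
        true = RigidTransform(rotation_about_axis("z", 1.0), [200.0, 100.0, -30.0])
        res = icp_register(cloud, true.apply(cloud))
        delta = res.transform.compose(true.inverse())
        assert delta.rotation_angle_deg() < 0.001
        assert np.abs(delta.translation).max() < 0.1

    def test_rms_history_non_increasing(self):
        cloud = _wavy_cloud(n_side=40, seed=3)
        true = RigidTransform(rotation_about_axis("y", 2.0), [300.0, -200.0, 50.0])
        res = icp_register(cloud, true.apply(cloud))
        diffs = np.diff(res.rms_history)
        assert np.all(diffs <= 1e-9)

    def test_stopping_rule_honours_tolerance(self):
        cloud = _wavy_cloud(n_side=30, seed=5)
        true = RigidTransform(rotation_about_axis("z", 2.0), [100.0, 50.0, 10.0])
        res = icp_register(cloud, true.apply(cloud), tol_um=0.01)
        assert res.converged
        # the last recorded step is the first to fall below the tolerance
        h = res.rms_history
        assert abs(h[-2] - h[-1]) < 0.01
        assert np.all(np.abs(np.diff(h[:-1])) >= 0.01)

    def test_degenerate_source_rejected(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError):
            icp_register(line, _wavy_cloud(10))

    def test_matches_independent_procrustes_on_known_pairing(self, rng):
        # dual route: our closed-form rigid fit vs an independent library
        src = rng.normal(size=(50, 3)) * 100
        true = RigidTransform(rotation_about_axis("x", 4.0), [10.0, -5.0, 3.0])
        dst = true.apply(src)
        ours = best_fit_rigid(src, dst)
        import trimesh.registration as tr

        m, _, _ = tr.procrustes(src, dst, reflection=False, scale=False)
        assert np.allclose(ours.matrix(), m, atol=1e-8)


class TestDiscrepancy:
    def _flat_mesh(self, z=0.0, n=6, step=100.0):
        s = SurfaceGrid(np.full((n, n), z), (step, step))
        return surface_to_mesh(s)

    def test_point_above_plane(self):
        mesh = self._flat_mesh()
        d, sd, per = mean_surface_discrepancy(np.array([[250.0, 250.0, 10.0]]), mesh)
        assert d == pytest.approx(10.0, abs=1e-9)
        assert sd == 0.0

    def test_points_on_mesh_have_zero_distance(self):
        mesh = self._flat_mesh(z=5.0)
        pts = mesh.vertices[::3]
        d, _, _ = mean_surface_discrepancy(pts, mesh)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_mean_of_known_distances(self):
        mesh = self._flat_mesh()
        pts = np.array([[100.0, 100.0, 10.0], [200.0, 200.0, 20.0], [300.0, 300.0, 30.0]])
        d, _, per = mean_surface_discrepancy(pts, mesh)
        assert np.allclose(per, [10.0, 20.0, 30.0])
        assert d == pytest.approx(20.0)

    def test_empty_inputs_rejected(self):
        mesh = self._flat_mesh()
        with pytest.raises(ValueError):
            mean_surface_discrepancy(np.empty((0, 3)), mesh)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_all_triangle_scan(self, seed):
        rng = np.random.default_rng(seed)
        ny, nx = 6, 8  # 70 triangles <= 100
        s = SurfaceGrid(rng.normal(0, 40, size=(ny, nx)), (80.0, 80.0))
        mesh = surface_to_mesh(s)
        pts = np.column_stack(
            [
                rng.uniform(-100, 700, 40),
                rng.uniform(-100, 500, 40),
                rng.uniform(-200, 200, 40),
            ]
        )
        d_impl = point_mesh_distance(pts, mesh, k=4)  # force the pruned path
        tris = mesh.triangles
        d_oracle = np.array([min(brute_force_point_triangle(p, t) for t in tris) for p in pts])
        assert np.allclose(d_impl, d_oracle, atol=1e-8)

    def test_invariant_under_common_rigid_transform(self, rng):
        s = SurfaceGrid(rng.normal(0, 30, size=(5, 5)), (100.0, 100.0))
        mesh = surface_to_mesh(s)
        pts = rng.uniform(0, 400, size=(20, 3))
        d0, _, _ = mean_surface_discrepancy(pts, mesh)
        T = RigidTransform(rotation_about_axis("z", 30.0) @ rotation_about_axis("x", 10.0), [500.0, -200.0, 100.0])
        mesh_t = TriMesh(T.apply(mesh.vertices), mesh.faces)
        d1, _, _ = mean_surface_discrepancy(T.apply(pts), mesh_t)
        assert d1 == pytest.approx(d0, abs=1e-6)
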