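import numpy as np
import pytest

import disctls as d
from disctls.io import PointCloud
from disctls.normals import (DegenerateNeighborhoodError, estimate_normals,
                             fit_quadratic_patch, orient_normals_mst, patch_normal)


def _grid(n=5, spacing=0.1):
    xs = np.arange(n) * spacing
    g = np.array([(x, y) for x in xs for y in xs])
    return g - g.mean(axis=0)


class TestQuadraticPatch:
    def test_flat_plane_gives_zero_coefficients(self):
        xy = _grid(3)[:7]
        pts = np.column_stack([xy, np.zeros(len(xy))])
        patch = fit_quadratic_patch(pts)
        np.testing.assert_allclose(patch.coefficients, 0.0, atol=1e-9)

    def test_paraboloid_recovered_exactly(self):
        # 9 grid points on z = x² + y²; expected coefficients verified by a
        # generic linear solve of the same design
        xy = _grid(3)
        z = xy[:, 0] ** 2 + xy[:, 1] ** 2
        patch = fit_quadratic_patch(np.column_stack([xy, z]))
        A = np.stack([xy[:, 0]**2, xy[:, 1]**2, xy[:, 0]*xy[:, 1],
                      xy[:, 0], xy[:, 1], np.ones(len(xy))], axis=1)
        expected = np.linalg.lstsq(A, z, rcond=None)[0]
        np.testing.assert_allclose(patch.coefficients, expected, atol=1e-12)
        np.testing.assert_allclose(patch.coefficients,
                                   [1, 1, 0, 0, 0, 0], atol=1e-9)

    def test_tilted_plane(self):
        # six unisolvent points for the quadric basis, on z = 2x
        xy = 0.1 * np.array([(0, 0), (1, 0), (0, 1), (1, 1), (2, 0), (0, 2)], float)
        pts = np.column_stack([xy, 2.0 * xy[:, 0]])
        patch = fit_quadratic_patch(pts)
        assert patch.d == pytest.approx(2.0, abs=1e-9)
        assert abs(patch.a) < 1e-9 and abs(patch.e) < 1e-9

    def test_collinear_neighborhood_raises(self):
        t = np.linspace(0, 1, 8)
        pts = np.column_stack([t, t, np.zeros(8)])  # collinear in xy
        with pytest.raises(DegenerateNeighborhoodError):
            fit_quadratic_patch(pts)


class TestPatchNormal:
    def test_flat_patch(self):
        patch = fit_quadratic_patch(np.column_stack([_grid(3)[:7], np.zeros(7)]))
        np.testing.assert_allclose(patch_normal(patch), [0, 0, 1], atol=1e-9)

    def test_slope_two(self):
        from disctls.normals import QuadraticPatch
        n = patch_normal(QuadraticPatch(0, 0, 0, 2, 0, 0))
        np.testing.assert_allclose(n, np.array([-2, 0, 1]) / np.sqrt(5), atol=1e-12)

    def test_paraboloid_off_origin(self):
        from disctls.normals import QuadraticPatch
        n = patch_normal(QuadraticPatch(1, 1, 0, 0, 0, 0), at=(1.0, 0.0))
        expected = np.array([-2, 0, 1]) / np.linalg.norm([-2, 0, 1])
        np.testing.assert_allclose(n, expected, atol=1e-12)


class TestEstimateNormals:
    @pytest.mark.parametrize("method,k", [("quadric", 6), ("pca", 8)])
    def test_sphere_normals_are_radial(self, method, k):
        g = np.random.default_rng(2)
        p = g.normal(size=(10000, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        est = estimate_normals(PointCloud(p), k=k, method=method)
        align = np.abs(np.einsum("ij,ij->i", est.normals, p))
        assert (align >= 0.99).mean() >= 0.99

    def test_flat_grid_vertical_normals(self):
        xy = _grid(20, 0.05)
        cloud = PointCloud(np.column_stack([xy, np.zeros(len(xy))]))
        est = estimate_normals(cloud, k=6)
        np.testing.assert_allclose(np.abs(est.normals[:, 2]), 1.0, atol=1e-9)

    def test_cylinder_wall_normals_orthogonal_to_axis(self, rng):
        n = 8000
        th = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack([np.cos(th), np.sin(th), rng.uniform(0, 2, n)])
        est = estimate_normals(PointCloud(pts), k=8)
        # angle from the xy-plane should be < 2 degrees for >= 95 % of points
        tilt = np.degrees(np.arcsin(np.abs(est.normals[:, 2])))
        assert (tilt < 2.0).mean() >= 0.95

    def test_unit_length(self, rng):
        cloud = PointCloud(rng.normal(size=(500, 3)))
        for method in ("quadric", "pca"):
            est = estimate_normals(cloud, k=8, method=method)
            np.testing.assert_allclose(np.linalg.norm(est.normals, axis=1), 1.0,
                                       atol=1e-9)


class TestOrientation:
    def test_flipped_flat_grid_becomes_uniform(self, rng):
        xy = _grid(15, 0.05)
        pts = np.column_stack([xy, np.zeros(len(xy))])
        normals = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
        flip = rng.random(len(pts)) < 0.5
        normals[flip] *= -1
        oriented = orient_normals_mst(d.OrientedPointCloud(pts, normals))
        assert np.abs(oriented.normals[:, 2].sum()) == len(pts)  # all equal signs

    def test_sphere_oriented_outward(self):
        g = np.random.default_rng(3)
        p = g.normal(size=(5000, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        est = estimate_normals(PointCloud(p), k=8, method="pca")
        oriented = orient_normals_mst(est)
        assert np.einsum("ij,ij->i", oriented.normals, p).mean() >= 0.95

    def test_mst_edge_consistency_invariant(self):
        g = np.random.default_rng(4)
        p = g.normal(size=(3000, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        oriented = orient_normals_mst(estimate_normals(PointCloud(p), k=8, method="pca"),
                                      k_graph=8)
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import minimum_spanning_tree
        from scipy.spatial import cKDTree
        _, idx = cKDTree(p).query(p, k=9)
        rows = np.repeat(np.arange(len(p)), 8)
        cols = idx[:, 1:].ravel()
        w = 1.0 - np.abs(np.einsum("ij,ij->i", oriented.normals[rows],
                                   oriented.normals[cols])) + 1e-9
        mst = minimum_spanning_tree(coo_matrix((w, (rows, cols)),
                                               shape=(len(p),) * 2).tocsr().maximum(
            coo_matrix((w, (rows, cols)), shape=(len(p),) * 2).tocsr().T)).tocoo()
        dots = np.einsum("ij,ij->i", oriented.normals[mst.row], oriented.normals[mst.col])
        assert (dots >= 0).all()

    def test_inward_preset_normals_flipped_outward(self):
        # upper hemisphere cap with all normals pre-set inward: the outward
        # (away-from-centroid) rule must flip the whole patch
        g = np.random.default_rng(6)
        p = g.normal(size=(500, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        p = p[p[:, 2] > 0.3]
        oriented = orient_normals_mst(d.OrientedPointCloud(p, -p.copy()))
        assert np.einsum("ij,ij->i", oriented.normals, p).mean() > 0.9

    def test_rotation_equivariance(self):
        g = np.random.default_rng(5)
        p = g.normal(size=(2000, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        base = orient_normals_mst(estimate_normals(PointCloud(p), k=8, method="pca"))
        rot = orient_normals_mst(estimate_normals(PointCloud(p @ R.T), k=8, method="pca"))
        np.testing.assert_allclose(rot.normals, base.normals @ R.T, atol=1e-6)
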