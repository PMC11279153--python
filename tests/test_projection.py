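"""Core projection: plane intersection, containment filter, nearest hit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conformalprint import (
    PlaneCoefficients,
    SurfaceSpec,
    barycentric_filter,
    build_spatial_index,
    make_closed_box,
    make_surface,
    project_point_to_mesh,
    project_point_to_plane,
    project_trajectory,
)
from conformalprint.errors import UnmappedPointError
from conformalprint.fixtures import make_raster_trajectory
from conformalprint.trajectory import PlanarTrajectory, densify

from conftest import mesh_from_tris


# ---------------------------------------------------------------------------
# independent oracles (pure-python, no shared code with the implementation)

def oracle_project_all_facets(P, v, mesh):
    """Scalar loop over every facet: cross-product plane, signed-area
    containment, min-|t| selection with lowest-facet-id tie-break."""
    P = np.asarray(P, float)
    v = np.asarray(v, float) / np.linalg.norm(v)
    best = None
    for fid in mesh.usable_ids:
        t1, t2, t3 = mesh.vertices[fid]
        n = np.cross(t2 - t1, t3 - t1)
        den = n @ v
        if abs(den) < 1e-12 * np.linalg.norm(n):
            continue
        t = -(n @ P - n @ t1) / den
        q = P + t * v
        if not oracle_point_in_triangle(q, t1, t2, t3):
            continue
        cand = (abs(t), fid, q, t)
        if best is None or cand[0] < best[0] - 1e-9 or (
            abs(cand[0] - best[0]) <= 1e-9 and fid < best[1]
        ):
            best = cand
    return best  # (dist, facet_id, point, t) or None


def oracle_point_in_triangle(q, t1, t2, t3, tol=1e-9):
    """Signed-area test: sub-triangle areas sum to the full area."""
    area = 0.5 * np.linalg.norm(np.cross(t2 - t1, t3 - t1))
    a1 = 0.5 * np.linalg.norm(np.cross(t2 - q, t3 - q))
    a2 = 0.5 * np.linalg.norm(np.cross(q - t1, t3 - t1))
    a3 = 0.5 * np.linalg.norm(np.cross(t2 - t1, q - t1))
    return abs((a1 + a2 + a3) - area) <= tol * max(area, 1.0)


# ---------------------------------------------------------------------------

class TestProjectPointToPlane:
    def test_straight_down_onto_floor(self):
        t, q = project_point_to_plane(
            (0.5, 0.5, 10), (0, 0, -1), PlaneCoefficients(0, 0, 1, 0)
        )
        assert t == pytest.approx(10)
        np.testing.assert_allclose(q, (0.5, 0.5, 0))

    def test_onto_tilted_plane_z_eq_x(self):
        # plane z = x is (-1, 0, 1, 0); from (2,0,10) straight down t = 8
        t, q = project_point_to_plane(
            (2, 0, 10), (0, 0, -1), PlaneCoefficients(-1, 0, 1, 0)
        )
        assert t == pytest.approx(8)
        np.testing.assert_allclose(q, (2, 0, 2))
        assert q[2] == pytest.approx(q[0])  # lies on z = x

    def test_parallel_returns_none(self):
        out = project_point_to_plane(
            (0, 0, 10), (0, 0, -1), PlaneCoefficients(1, 0, 0, 0)
        )
        assert out is None


class TestBarycentricFilter:
    @pytest.mark.parametrize(
        "point,inside,m,n",
        [
            ((0.25, 0.25, 0), True, 0.25, 0.25),
            ((1, 1, 0), False, 1.0, 1.0),
            ((1 / 3, 1 / 3, 0), True, 1 / 3, 1 / 3),
            ((0.5, 0, 0), True, 0.5, 0.0),  # edge midpoint: boundary inclusive
            ((0, 0, 0), True, 0.0, 0.0),    # vertex: boundary inclusive
            ((1, 0, 0), True, 1.0, 0.0),
        ],
    )
    def test_unit_triangle_cases(self, unit_triangle_verts, point, inside, m, n):
        got_inside, got_m, got_n = barycentric_filter(point, unit_triangle_verts)
        assert got_inside == inside
        assert got_m == pytest.approx(m, abs=1e-12)
        assert got_n == pytest.approx(n, abs=1e-12)

    def test_degenerate_triangle_is_outside(self):
        degen = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], float)
        inside, _, _ = barycentric_filter((0.5, 0.5, 0.5), degen)
        assert not inside

    @settings(max_examples=500, deadline=None)
    @given(
        coords=st.lists(st.floats(-20, 20), min_size=9, max_size=9),
        m=st.floats(-0.5, 1.5),
        n=st.floats(-0.5, 1.5),
    )
    def test_agrees_with_signed_area_oracle(self, coords, m, n):
        """Construct a point from known (m, n) on a random triangle's plane
        and compare the filter against an area-sum containment oracle."""
        verts = np.array(coords).reshape(3, 3)
        e1, e2 = verts[1] - verts[0], verts[2] - verts[0]
        if np.linalg.norm(np.cross(e1, e2)) < 1e-3:
            return  # skip degenerate draws
        # keep clear of the decision boundary where tolerances differ
        if min(abs(m), abs(n), abs(1 - m - n)) < 1e-6:
            return
        point = (1 - m - n) * verts[0] + m * verts[1] + n * verts[2]
        inside, got_m, got_n = barycentric_filter(point, verts)
        assert got_m == pytest.approx(m, rel=1e-6, abs=1e-9)
        assert got_n == pytest.approx(n, rel=1e-6, abs=1e-9)
        assert inside == oracle_point_in_triangle(point, *verts)
        assert inside == (m >= 0 and n >= 0 and m + n <= 1)


class TestProjectPointToMesh:
    def test_single_facet(self):
        mesh = mesh_from_tris([[[0, 0, 0], [2, 0, 0], [0, 2, 0]]])
        hit = project_point_to_mesh((0.5, 0.5, 10), (0, 0, -1), mesh)
        np.testing.assert_allclose(hit.point, (0.5, 0.5, 0))
        assert hit.facet_id == 0
        assert hit.distance == pytest.approx(10)

    def test_nearest_of_stacked_facets(self):
        mesh = mesh_from_tris(
            [
                [[0, 0, 1], [2, 0, 1], [0, 2, 1]],
                [[0, 0, 3], [2, 0, 3], [0, 2, 3]],
            ]
        )
        hit = project_point_to_mesh((0.5, 0.5, 10), (0, 0, -1), mesh)
        assert hit.point[2] == pytest.approx(3)  # distance 7 beats 9
        assert hit.facet_id == 1

    def test_coincident_facets_tie_break_lowest_id(self):
        tri = [[0, 0, 1], [2, 0, 1], [0, 2, 1]]
        mesh = mesh_from_tris([tri, tri])
        hit = project_point_to_mesh((0.5, 0.5, 5), (0, 0, -1), mesh)
        assert hit.facet_id == 0

    def test_shared_edge_point_never_lost(self):
        """A point projecting exactly onto an edge shared by two facets
        must hit one of them, chosen deterministically (lowest id)."""
        mesh = mesh_from_tris(
            [
                [[0, 0, 0], [1, 0, 0], [1, 1, 0]],
                [[0, 0, 0], [1, 1, 0], [0, 1, 0]],
            ]
        )
        hit = project_point_to_mesh((0.5, 0.5, 5), (0, 0, -1), mesh)
        assert hit is not None
        assert hit.facet_id == 0

    def test_miss_policies(self):
        mesh = mesh_from_tris([[[0, 0, 0], [1, 0, 0], [0, 1, 0]]])
        with pytest.raises(UnmappedPointError, match=r"\(x=5"):
            project_point_to_mesh((5, 5, 10), (0, 0, -1), mesh, policy="error")
        assert (
            project_point_to_mesh((5, 5, 10), (0, 0, -1), mesh, policy="drop") is None
        )


class TestSpatialIndex:
    def test_single_facet_candidates(self):
        mesh = mesh_from_tris([[[0, 0, 0], [1, 0, 0], [0, 1, 0]]])
        idx = build_spatial_index(mesh, (0, 0, -1))
        assert list(idx.candidates((0.5, 0.25, 5))) == [0]

    def test_superset_contract_on_grid(self):
        spec = SurfaceSpec("sinusoid", {"amplitude": 2}, nu=11, nv=11,
                           extent=(0, 10, 0, 10))
        mesh, _ = make_surface(spec)
        idx = build_spatial_index(mesh, (0, 0, -1))
        rng = np.random.default_rng(0)
        for _ in range(50):
            P = np.array([*rng.uniform(0, 10, 2), 20.0])
            cand_ids = set(idx.tables.ids[idx.candidates(P)])
            best = oracle_project_all_facets(P, (0, 0, -1), mesh)
            if best is not None:
                assert best[1] in cand_ids

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_indexed_equals_oracle_on_random_surfaces(self, seed):
        """Indexed nearest hit identical (facet and point) to the
        exhaustive scalar-loop oracle."""
        rng = np.random.default_rng(seed)
        spec = SurfaceSpec(
            "sinusoid",
            {
                "amplitude": rng.uniform(0.5, 3),
                "wavelength_x": rng.uniform(4, 15),
                "wavelength_y": rng.uniform(4, 15),
                "z0": 5.0,
            },
            nu=int(rng.integers(8, 20)),
            nv=int(rng.integers(8, 20)),
            extent=(0, 20, 0, 20),
        )
        mesh, _ = make_surface(spec)
        idx = build_spatial_index(mesh, (0, 0, -1))
        for _ in range(100):
            P = np.array([*rng.uniform(0.1, 19.9, 2), 30.0])
            hit = project_point_to_mesh(P, (0, 0, -1), mesh, index=idx)
            ora = oracle_project_all_facets(P, (0, 0, -1), mesh)
            assert ora is not None
            assert hit.facet_id == ora[1]
            # oracle rounds differently (no precomputed D); agreement to 1e-9
            np.testing.assert_allclose(hit.point, ora[2], atol=1e-9)

    def test_indexed_equals_unindexed_path(self):
        mesh, _ = make_surface(
            SurfaceSpec("hemisphere", {"radius": 20}, nu=32, nv=32,
                        extent=(-10, 10, -10, 10))
        )
        idx = build_spatial_index(mesh, (0, 0, -1))
        rng = np.random.default_rng(9)
        for _ in range(100):
            P = np.array([*rng.uniform(-9, 9, 2), 30.0])
            a = project_point_to_mesh(P, (0, 0, -1), mesh, index=idx)
            b = project_point_to_mesh(P, (0, 0, -1), mesh, index=None)
            assert a.facet_id == b.facet_id
            np.testing.assert_array_equal(a.point, b.point)


class TestProjectTrajectory:
    def test_flat_substrate_with_clearance(self, make_config):
        mesh, _ = make_surface(
            SurfaceSpec("plane", {"z0": 2.0}, nu=4, nv=4, extent=(0, 10, 0, 10))
        )
        cfg = make_config(clearance=0.2)
        traj = densify(make_raster_trajectory((1, 9, 1, 9), 4), cfg.d)
        path = project_trajectory(traj, mesh, cfg)
        np.testing.assert_allclose(path.points[:, 2], 2.2, atol=1e-12)

    def test_tilted_plane_closed_form(self, make_config):
        mesh, _ = make_surface(
            SurfaceSpec("tilted_plane", {"a": 0.5}, nu=6, nv=6, extent=(0, 10, 0, 10))
        )
        cfg = make_config(clearance=0.0)
        traj = densify(make_raster_trajectory((0.5, 9.5, 0.5, 9.5), 1), cfg.d)
        path = project_trajectory(traj, mesh, cfg)
        err = np.abs(path.points[:, 2] - 0.5 * path.points[:, 0])
        assert err.max() <= 1e-9

    def test_xy_preserved_bit_for_bit(self, make_config):
        mesh, _ = make_surface(
            SurfaceSpec("sinusoid", {"amplitude": 1.5, "z0": 3}, nu=20, nv=20,
                        extent=(0, 10, 0, 10))
        )
        cfg = make_config()
        traj = densify(make_raster_trajectory((0.5, 9.5, 0.5, 9.5), 2), cfg.d)
        path = project_trajectory(traj, mesh, cfg)
        assert np.array_equal(path.points[:, :2], traj.points)

    def test_closed_box_selects_top_surface(self, make_config):
        """Lifted projection lands on z=3, never the z=1 underside."""
        mesh = make_closed_box((0, 10, 0, 10), z_bottom=1.0, z_top=3.0)
        cfg = make_config(clearance=0.0)
        traj = densify(make_raster_trajectory((1, 9, 1, 9), 2), cfg.d)
        path = project_trajectory(traj, mesh, cfg)
        np.testing.assert_allclose(path.points[:, 2], 3.0, atol=1e-12)

    def test_drop_policy_accounting(self, make_config):
        mesh, _ = make_surface(
            SurfaceSpec("plane", {"z0": 0.0}, nu=3, nv=3, extent=(0, 5, 0, 5))
        )
        cfg = make_config(no_hit_policy="drop")
        traj = PlanarTrajectory(np.array([(1.0, 1.0), (4.0, 1.0), (20.0, 1.0)]))
        dense = densify(traj, cfg.d)
        path = project_trajectory(dense, mesh, cfg)
        assert len(path) + len(path.unmapped) == path.n_input
        # exactly the densified points beyond the 5 mm footprint are dropped
        assert path.unmapped == [i for i, (x, _) in enumerate(dense.points) if x > 5]
        assert len(path.unmapped) > 0

    def test_error_policy_names_point(self, make_config):
        mesh, _ = make_surface(
            SurfaceSpec("plane", {"z0": 0.0}, nu=3, nv=3, extent=(0, 5, 0, 5))
        )
        cfg = make_config()
        traj = PlanarTrajectory(np.array([(1.0, 1.0), (30.0, 1.0)]))
        with pytest.raises(UnmappedPointError):
            project_trajectory(densify(traj, cfg.d), mesh, cfg)

    def test_hit_points_satisfy_plane_equation(self, make_config):
        mesh, _ = make_surface(
            SurfaceSpec("hemisphere", {"radius": 15}, nu=24, nv=24,
                        extent=(-7, 7, -7, 7))
        )
        cfg = make_config(clearance=0.0)
        traj = densify(make_raster_trajectory((-6, 6, -6, 6), 3), cfg.d)
        path = project_trajectory(traj, mesh, cfg)
        for q, fid in zip(path.points, path.facet_ids):
            A, B, C, D = mesh.planes[fid]
            res = abs(A * q[0] + B * q[1] + C * q[2] + D)
            assert res <= 1e-9 * np.linalg.norm([A, B, C])
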