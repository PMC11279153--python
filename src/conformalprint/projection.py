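"""Core conformal projection: cast trajectory points along v onto a mesh.

For a trajectory point P and a facet plane Ax + By + Cz + D = 0 the line
P + t*v intersects the plane at

    t = -(A*Px + B*Py + C*Pz + D) / (A*vx + B*vy + C*vz),

which is undefined (no intersection) when the line is parallel to the
plane.  The intersection is then tested for containment in the facet by
solving P_hit = (1 - m - n)*T1 + m*T2 + n*T3 for the barycentric
coordinates (m, n); the point is inside iff m >= 0, n >= 0 and
m + n <= 1, applied with a small boundary tolerance so points landing
exactly on shared edges are never lost.  Among all facets containing
their intersection, the hit with the shortest spatial distance |t| from
P wins; ties within ``tie_tol`` go to the lowest facet_id, which makes
results deterministic on meshes with coincident overlapping facets.

Trajectory points are first lifted to z_start = bbox_max_z + lift_margin
so that on a closed mesh the nearest hit is the upper surface, then each
hit is offset by (clearance + layer_index * layer_height) along -v to
realise the nozzle standoff and multi-layer conformal passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PrintConfig
from .errors import EmptyMeshError, UnmappedPointError
from .mesh_io import PlaneCoefficients, Triangle, TriangleMesh
from .trajectory import TRAVEL, PlanarTrajectory

#: relative threshold below which the line is treated as parallel to a plane
EPS_PARALLEL = 1e-12

#: default barycentric boundary tolerance
EPS_BARY = 1e-9

#: default |t| window for facet_id tie-breaking, mm
TIE_TOL = 1e-9


def normalize_direction(v) -> np.ndarray:
    """Return v as a float64 unit vector; raise on zero/non-finite input."""
    v = np.asarray(v, dtype=np.float64).reshape(3)
    norm = np.linalg.norm(v)
    if not np.isfinite(norm) or norm == 0:
        raise ValueError("projection vector must be a non-zero finite 3-vector")
    return v / norm


@dataclass(frozen=True)
class ProjectionHit:
    """One accepted projection: hit point, line parameter and facet."""

    point: np.ndarray
    t: float
    m: float
    n: float
    facet_id: int

    @property
    def distance(self) -> float:
        """Spatial distance from the source point (|t| for unit v), mm."""
        return abs(self.t)


@dataclass
class ConformalPath:
    """Ordered 3D toolpath after projection.

    ``unmapped`` lists densified-input indices that had no valid hit;
    under the "drop" policy those points are absent from ``points``,
    under "passthrough" they remain at the lifted height with
    facet_id -1.
    """

    points: np.ndarray
    kinds: list[str]
    facet_ids: np.ndarray
    unmapped: list[int] = field(default_factory=list)
    n_input: int = 0

    def __len__(self) -> int:
        return len(self.points)

    def with_offset(self, delta: np.ndarray) -> "ConformalPath":
        """Copy of the path rigidly shifted by ``delta`` (mm)."""
        return ConformalPath(
            self.points + np.asarray(delta, float),
            list(self.kinds),
            self.facet_ids.copy(),
            list(self.unmapped),
            self.n_input,
        )

    def path_length(self, kind: str | None = None) -> float:
        """Total 3D length of segments, optionally restricted to one kind."""
        if len(self.points) < 2:
            return 0.0
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if kind is None:
            return float(seg.sum())
        mask = np.array([k == kind for k in self.kinds[1:]])
        return float(seg[mask].sum())


def project_point_to_plane(P, v, plane) -> tuple[float, np.ndarray] | None:
    """Intersect the line P + t*v with a plane; None when parallel.

    Returns (t, hit_point); t is signed, in mm for unit-length v.
    """
    P = np.asarray(P, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if isinstance(plane, PlaneCoefficients):
        plane = plane.as_array()
    A, B, C, D = np.asarray(plane, dtype=np.float64)
    abc = np.array([A, B, C])
    den = float(abc @ v)
    if abs(den) < EPS_PARALLEL * np.linalg.norm(abc):
        return None
    t = -float(abc @ P + D) / den
    return t, P + t * v


def barycentric_coordinates(point, tri) -> tuple[float, float] | None:
    """Solve P = (1-m-n)*T1 + m*T2 + n*T3 for (m, n); None if degenerate.

    The 2x2 system is solved in the two coordinate axes least aligned
    with the triangle normal, which avoids singular systems for
    near-vertical facets.
    """
    if isinstance(tri, Triangle):
        verts = np.stack([tri.v1, tri.v2, tri.v3])
    else:
        verts = np.asarray(tri, dtype=np.float64)
    point = np.asarray(point, dtype=np.float64)
    e1 = verts[1] - verts[0]
    e2 = verts[2] - verts[0]
    normal = np.cross(e1, e2)
    drop = int(np.argmax(np.abs(normal)))
    a, b = [ax for ax in (0, 1, 2) if ax != drop]
    det = e1[a] * e2[b] - e2[a] * e1[b]
    scale = max(abs(e1[a]), abs(e1[b]), abs(e2[a]), abs(e2[b]), 1e-300)
    if abs(det) < 1e-14 * scale * scale:
        return None
    ra = point[a] - verts[0][a]
    rb = point[b] - verts[0][b]
    m = (ra * e2[b] - e2[a] * rb) / det
    n = (e1[a] * rb - ra * e1[b]) / det
    return float(m), float(n)


def barycentric_filter(point, tri, eps: float = EPS_BARY) -> tuple[bool, float, float]:
    """Boundary-inclusive point-in-triangle test via barycentric (m, n).

    Returns (inside, m, n); vertices and edges count as inside, with a
    tolerance ``eps`` absorbing float error on shared edges.  Degenerate
    triangles are never "inside".
    """
    mn = barycentric_coordinates(point, tri)
    if mn is None:
        return False, float("nan"), float("nan")
    m, n = mn
    inside = (m >= -eps) and (n >= -eps) and (m + n <= 1.0 + eps)
    return inside, m, n


class _MeshTables:
    """Precomputed per-usable-facet arrays for vectorized projection."""

    def __init__(self, mesh: TriangleMesh):
        ids = mesh.usable_ids
        if len(ids) == 0:
            raise EmptyMeshError("mesh has no usable facets")
        self.ids = ids
        self.planes = mesh.planes[ids]
        verts = mesh.vertices[ids]
        self.t1 = verts[:, 0]
        e1 = verts[:, 1] - verts[:, 0]
        e2 = verts[:, 2] - verts[:, 0]
        normal = self.planes[:, :3]
        self.abc_norm = np.linalg.norm(normal, axis=1)
        drop = np.argmax(np.abs(normal), axis=1)
        axes = np.array([[1, 2], [0, 2], [0, 1]])
        ab = axes[drop]  # (u, 2): the two solve axes per facet
        self.a_idx = ab[:, 0]
        self.b_idx = ab[:, 1]
        rows = np.arange(len(ids))
        self.e1a = e1[rows, self.a_idx]
        self.e1b = e1[rows, self.b_idx]
        self.e2a = e2[rows, self.a_idx]
        self.e2b = e2[rows, self.b_idx]
        self.det = self.e1a * self.e2b - self.e2a * self.e1b
        self.t1a = self.t1[rows, self.a_idx]
        self.t1b = self.t1[rows, self.b_idx]

    def project(self, P, v, cand, eps_bary, tie_tol, forward_only):
        """Nearest valid hit of line P + t*v among candidate rows ``cand``."""
        planes = self.planes[cand]
        den = planes[:, :3] @ v
        num = planes[:, :3] @ P + planes[:, 3]
        ok = np.abs(den) >= EPS_PARALLEL * self.abc_norm[cand]
        t = np.where(ok, -num / np.where(ok, den, 1.0), np.nan)
        if forward_only:
            ok &= t >= 0
        hit = P[None, :] + t[:, None] * v[None, :]
        ra = hit[np.arange(len(cand)), self.a_idx[cand]] - self.t1a[cand]
        rb = hit[np.arange(len(cand)), self.b_idx[cand]] - self.t1b[cand]
        det = self.det[cand]
        m = (ra * self.e2b[cand] - self.e2a[cand] * rb) / det
        n = (self.e1a[cand] * rb - ra * self.e1b[cand]) / det
        ok &= (m >= -eps_bary) & (n >= -eps_bary) & (m + n <= 1.0 + eps_bary)
        if not ok.any():
            return None
        dist = np.where(ok, np.abs(t), np.inf)
        best = dist.min()
        tied = np.flatnonzero(dist <= best + tie_tol)
        winner = tied[np.argmin(self.ids[cand[tied]])]
        fid = int(self.ids[cand[winner]])
        return ProjectionHit(
            hit[winner].copy(), float(t[winner]), float(m[winner]),
            float(n[winner]), fid,
        )


class SpatialGridIndex:
    """Uniform 2D grid over the plane orthogonal to v, binning facet AABBs.

    For any query point, ``candidates`` returns a superset of all facets
    whose plane intersection can pass the containment filter: the hit
    shares the query's coordinates in the (u, w) basis orthogonal to v,
    so it must fall inside the facet's projected bounding box, which is
    padded by a small margin and binned into every cell it overlaps.
    """

    #: padding of projected facet AABBs, absorbs the barycentric tolerance
    PAD = 1e-6

    def __init__(self, mesh: TriangleMesh, v, cells_per_side: int | None = None):
        self.v = normalize_direction(v)
        self.tables = _MeshTables(mesh)
        # orthonormal basis (u, w) spanning the projection plane
        helper = np.zeros(3)
        helper[int(np.argmin(np.abs(self.v)))] = 1.0
        u = np.cross(self.v, helper)
        u /= np.linalg.norm(u)
        w = np.cross(self.v, u)
        self.basis = np.stack([u, w])  # (2, 3)

        verts = mesh.vertices[self.tables.ids]  # (n, 3, 3)
        proj = verts @ self.basis.T  # (n, 3, 2)
        self.lo = proj.min(axis=1) - self.PAD
        self.hi = proj.max(axis=1) + self.PAD
        gmin = self.lo.min(axis=0)
        gmax = self.hi.max(axis=0)
        n = len(self.tables.ids)
        if cells_per_side is None:
            cells_per_side = int(np.clip(np.sqrt(n), 1, 256))
        self.ncell = np.array([cells_per_side, cells_per_side])
        span = np.maximum(gmax - gmin, 1e-9)
        self.origin = gmin
        self.cell = span / self.ncell

        lo_c = self._cell_of(self.lo)
        hi_c = self._cell_of(self.hi)
        bins: dict[tuple[int, int], list[int]] = {}
        for row in range(n):
            for cx in range(lo_c[row, 0], hi_c[row, 0] + 1):
                for cy in range(lo_c[row, 1], hi_c[row, 1] + 1):
                    bins.setdefault((cx, cy), []).append(row)
        self._bins = {k: np.array(sorted(rows)) for k, rows in bins.items()}
        self._empty = np.empty(0, dtype=int)
        self._gmin = gmin
        self._gmax = gmax

    def _cell_of(self, pts: np.ndarray) -> np.ndarray:
        c = np.floor((pts - self.origin) / self.cell).astype(int)
        return np.clip(c, 0, self.ncell - 1)

    def candidates(self, P) -> np.ndarray:
        """Rows (into the usable-facet tables) possibly hit from P."""
        q = self.basis @ np.asarray(P, dtype=np.float64)
        if np.any(q < self._gmin) or np.any(q > self._gmax):
            return self._empty
        cx, cy = self._cell_of(q[None, :])[0]
        return self._bins.get((int(cx), int(cy)), self._empty)


def build_spatial_index(mesh: TriangleMesh, v) -> SpatialGridIndex:
    """Build the uniform-grid facet index for projection along v."""
    return SpatialGridIndex(mesh, v)


def project_point_to_mesh(
    P,
    v,
    mesh: TriangleMesh,
    policy: str = "error",
    index: SpatialGridIndex | None = None,
    eps_bary: float = EPS_BARY,
    tie_tol: float = TIE_TOL,
    forward_only: bool = False,
    point_index: int = 0,
) -> ProjectionHit | None:
    """Nearest valid projection of P along v onto the mesh.

    Traverses all usable facets (or the index's candidate subset, which
    yields identical results), keeps facets whose plane intersection
    passes the containment filter, and returns the hit minimizing |t|.
    With ``policy="error"`` a miss raises :class:`UnmappedPointError`;
    "drop" and "passthrough" return None and leave handling to the
    caller.
    """
    P = np.asarray(P, dtype=np.float64)
    v = normalize_direction(v)
    if index is not None:
        tables = index.tables
        cand = index.candidates(P)
    else:
        tables = _MeshTables(mesh)
        cand = np.arange(len(tables.ids))
    hit = None
    if len(cand):
        hit = tables.project(P, v, cand, eps_bary, tie_tol, forward_only)
    if hit is None and policy == "error":
        raise UnmappedPointError(point_index, float(P[0]), float(P[1]))
    return hit


def project_trajectory(
    traj: PlanarTrajectory,
    mesh: TriangleMesh,
    cfg: PrintConfig,
    index: SpatialGridIndex | None = None,
    layer: int = 0,
) -> ConformalPath:
    """Project a (densified) planar trajectory onto the mesh.

    Points are lifted to z_start = bbox_max_z + lift_margin, projected
    along cfg.vector, and every hit is offset by
    (clearance + layer * layer_height) along -v.  Output order follows
    input order; misses are handled per cfg.no_hit_policy.
    """
    v = cfg.v
    if index is None:
        index = build_spatial_index(mesh, v)
    z_start = float(mesh.bbox[1, 2]) + cfg.lift_margin
    standoff = cfg.clearance + layer * cfg.layer_height
    offset = -standoff * v

    pts_out: list[np.ndarray] = []
    kinds_out: list[str] = []
    fids: list[int] = []
    unmapped: list[int] = []
    for i, (x, y) in enumerate(traj.points):
        P = np.array([x, y, z_start])
        hit = None
        cand = index.candidates(P)
        if len(cand):
            hit = index.tables.project(
                P, v, cand, cfg.eps_bary, cfg.tie_tol, cfg.forward_only
            )
        if hit is not None:
            pts_out.append(hit.point + offset)
            kinds_out.append(traj.kinds[i])
            fids.append(hit.facet_id)
        else:
            if cfg.no_hit_policy == "error":
                raise UnmappedPointError(i, float(x), float(y))
            unmapped.append(i)
            if cfg.no_hit_policy == "passthrough":
                pts_out.append(P)
                kinds_out.append(TRAVEL)
                fids.append(-1)
            # "drop": point omitted
    points = np.vstack(pts_out) if pts_out else np.empty((0, 3))
    if kinds_out:
        kinds_out[0] = TRAVEL
    return ConformalPath(points, kinds_out, np.array(fids, dtype=int), unmapped, len(traj))
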