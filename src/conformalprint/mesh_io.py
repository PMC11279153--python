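"""STL mesh input and per-facet plane equations.

An STL file is a triangle soup: each facet stores a (frequently
unreliable) normal and three vertex coordinates.  All downstream geometry
is derived from the vertices alone; the plane of facet i is

    A*x + B*y + C*z + D = 0

with coefficients computed from the three vertices by the cross-term
expansion (``plane_from_triangle``).  Stored normals are kept for
inspection but never used in computation.

Parsing of both binary and ASCII STL dialects is delegated to
:mod:`trimesh`'s exchange layer with vertex merging disabled, so facet
order equals file order and ``facet_id`` is a stable, deterministic key.
Vertices are promoted from the file's float32 to float64 before any
arithmetic: the projection line parameter t is sensitive to cancellation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from trimesh.exchange import stl as _stl

from .errors import EmptyMeshError, StlFormatError

log = logging.getLogger(__name__)

#: facets with area below this (mm^2) are treated as degenerate slivers
DEGENERATE_AREA = 1e-12

#: relative tolerance for "vertex lies on its own plane" checks
EPS_PLANE = 1e-9


@dataclass(frozen=True)
class Triangle:
    """One mesh facet: three vertices (mm) plus its file-order index."""

    v1: np.ndarray
    v2: np.ndarray
    v3: np.ndarray
    facet_id: int
    stored_normal: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass(frozen=True)
class PlaneCoefficients:
    """Unnormalized coefficients of A*x + B*y + C*z + D = 0."""

    A: float
    B: float
    C: float
    D: float

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.D])


def plane_from_triangle(tri: Triangle) -> PlaneCoefficients:
    """Plane coefficients of a facet from its three vertices.

    A is the y/z cross term, B the x/z term, C the x/y term and
    D = -(A*x1 + B*y1 + C*z1); (A, B, C) equals the cross product
    (v2 - v1) x (v3 - v1).  A degenerate (zero-area) triangle yields
    (A, B, C) = 0, which callers must treat as unusable; no exception
    is raised.
    """
    x1, y1, z1 = tri.v1
    x2, y2, z2 = tri.v2
    x3, y3, z3 = tri.v3
    A = (y2 - y1) * (z3 - z1) - (z2 - z1) * (y3 - y1)
    B = (x3 - x1) * (z2 - z1) - (x2 - x1) * (z3 - z1)
    C = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
    D = -(A * x1 + B * y1 + C * z1)
    return PlaneCoefficients(float(A), float(B), float(C), float(D))


def planes_from_vertices(verts: np.ndarray) -> np.ndarray:
    """Vectorized plane coefficients for a (n, 3, 3) vertex array.

    Returns an (n, 4) array of (A, B, C, D) rows, identical to applying
    :func:`plane_from_triangle` facet by facet.
    """
    v1, v2, v3 = verts[:, 0], verts[:, 1], verts[:, 2]
    n = np.cross(v2 - v1, v3 - v1)
    d = -np.einsum("ij,ij->i", n, v1)
    return np.column_stack([n, d])


@dataclass
class TriangleMesh:
    """Indexed triangle soup with derived plane coefficients.

    Attributes
    ----------
    vertices : (n, 3, 3) float64 array
        Vertex coordinates in mm, facet order = file order.
    planes : (n, 4) float64 array
        Per-facet (A, B, C, D), always rederived from vertices.
    stored_normals : (n, 3) float64 array
        Normals as read from the file; informational only.
    degenerate_ids : (k,) int array
        Facet ids with area < ``DEGENERATE_AREA``; excluded from
        projection queries.
    """

    vertices: np.ndarray
    planes: np.ndarray
    stored_normals: np.ndarray
    degenerate_ids: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.planes = np.ascontiguousarray(self.planes, dtype=np.float64)

    @classmethod
    def from_vertices(
        cls, verts: np.ndarray, stored_normals: np.ndarray | None = None
    ) -> "TriangleMesh":
        verts = np.asarray(verts, dtype=np.float64)
        if verts.ndim != 3 or verts.shape[1:] != (3, 3):
            raise ValueError(f"expected (n, 3, 3) vertex array, got {verts.shape}")
        if not np.all(np.isfinite(verts)):
            raise ValueError("mesh vertices contain non-finite values")
        planes = planes_from_vertices(verts)
        # facet area = |cross| / 2; cross product is the (A, B, C) part
        areas = 0.5 * np.linalg.norm(planes[:, :3], axis=1)
        degenerate = np.flatnonzero(areas < DEGENERATE_AREA)
        if stored_normals is None:
            stored_normals = np.zeros((len(verts), 3))
        return cls(verts, planes, np.asarray(stored_normals, float), degenerate)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def n_facets(self) -> int:
        return len(self.vertices)

    @property
    def usable_ids(self) -> np.ndarray:
        mask = np.ones(len(self.vertices), dtype=bool)
        mask[self.degenerate_ids] = False
        return np.flatnonzero(mask)

    @property
    def bbox(self) -> np.ndarray:
        """(2, 3) array of axis-aligned min/max corners."""
        flat = self.vertices.reshape(-1, 3)
        return np.vstack([flat.min(axis=0), flat.max(axis=0)])

    def triangle(self, facet_id: int) -> Triangle:
        v = self.vertices[facet_id]
        return Triangle(v[0], v[1], v[2], int(facet_id), self.stored_normals[facet_id])

    def plane(self, facet_id: int) -> PlaneCoefficients:
        A, B, C, D = self.planes[facet_id]
        return PlaneCoefficients(A, B, C, D)


def read_stl(path: str | Path) -> TriangleMesh:
    """Read a binary or ASCII STL file into a :class:`TriangleMesh`.

    The dialect is auto-detected.  Facets are kept in file order;
    degenerate facets are recorded in ``degenerate_ids`` (with a logged
    count) rather than raising, because scanned anatomical meshes
    routinely contain slivers.  A mesh with zero usable facets raises
    :class:`EmptyMeshError`.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"STL file not found: {path}")
    try:
        with open(path, "rb") as fh:
            kwargs = _stl.load_stl(fh)
    except OSError:
        raise
    except Exception as exc:  # struct errors, header/count mismatch, ...
        raise StlFormatError(f"cannot parse {path} as STL: {exc}") from exc

    if "vertices" not in kwargs or "faces" not in kwargs:
        raise StlFormatError(f"cannot parse {path} as STL (truncated or malformed)")
    verts = np.asarray(kwargs["vertices"], dtype=np.float64)
    faces = np.asarray(kwargs["faces"])
    normals = np.asarray(kwargs.get("face_normals", np.zeros((len(faces), 3))), float)
    if len(faces) == 0:
        raise EmptyMeshError(f"{path} contains no facets")
    tri_verts = verts[faces]
    mesh = TriangleMesh.from_vertices(tri_verts, normals)
    if len(mesh.degenerate_ids):
        log.warning(
            "%s: skipped %d degenerate facet(s) of %d",
            path.name,
            len(mesh.degenerate_ids),
            mesh.n_facets,
        )
    if len(mesh.usable_ids) == 0:
        raise EmptyMeshError(f"{path} has no usable (non-degenerate) facets")
    return mesh


def write_stl(mesh: TriangleMesh, path: str | Path, binary: bool = True) -> None:
    """Export a mesh to STL (for fixture inspection in external viewers)."""
    import trimesh

    n = mesh.n_facets
    tm = trimesh.Trimesh(
        vertices=mesh.vertices.reshape(-1, 3),
        faces=np.arange(3 * n).reshape(-1, 3),
        process=False,
    )
    data = tm.export(file_type="stl" if binary else "stl_ascii")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
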