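"""Synthetic substrate surfaces and trajectories with known closed forms.

Real conformal-printing substrates (free-form CAD surfaces, scanned
anatomy) are not redistributable, so every test surface here is generated
from an analytic height function z(x, y) sampled on a regular grid and
triangulated two facets per cell.  ``make_surface`` returns both the
mesh and the height callable, so tests can compare projected z values
against exact geometry: planes and tilted planes are reproduced exactly
by the mesh, curved surfaces (hemisphere, sinusoid) only to within the
chordal deviation (sagitta) of the tessellation, for which an analytic
bound is provided.

The hemisphere is an open cap (no base disk) so each vertical line hits
it exactly once; the closed-box fixture (two horizontal sheets) exists
to exercise nearest-hit selection between top and bottom surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .mesh_io import TriangleMesh
from .trajectory import PRINT, TRAVEL, PlanarTrajectory

Extent = tuple[float, float, float, float]  # xmin, xmax, ymin, ymax

KINDS = ("plane", "tilted_plane", "hemisphere", "sinusoid")


@dataclass
class SurfaceSpec:
    """Parametric description of a synthetic substrate surface.

    kind/params:
      - plane: ``z0``
      - tilted_plane: ``a, b, c`` of z = a*x + b*y + c
      - hemisphere: ``radius``, optional ``center`` (cx, cy) at z = 0
      - sinusoid: ``amplitude``, ``wavelength_x``, ``wavelength_y``,
        optional ``z0``
    """

    kind: str
    params: dict = field(default_factory=dict)
    nu: int = 16
    nv: int = 16
    extent: Extent = (0.0, 10.0, 0.0, 10.0)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown surface kind {self.kind!r}; choose from {KINDS}")
        if self.nu < 2 or self.nv < 2:
            raise ValueError("tessellation counts nu, nv must be >= 2")
        xmin, xmax, ymin, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"degenerate extent {self.extent}")
        if self.kind == "hemisphere":
            R = float(self.params.get("radius", 0))
            if R <= 0:
                raise ValueError("hemisphere requires radius > 0")
            cx, cy = self.params.get("center", (0.0, 0.0))
            corners = np.array(
                [[xmin, ymin], [xmin, ymax], [xmax, ymin], [xmax, ymax]]
            )
            rr = np.hypot(corners[:, 0] - cx, corners[:, 1] - cy)
            if rr.max() >= R:
                raise ValueError(
                    "hemisphere extent must lie strictly inside the footprint "
                    f"radius (corner r={rr.max():.3f} >= R={R})"
                )

    def height_function(self) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
        """Analytic z(x, y) used as the test oracle."""
        p = self.params
        if self.kind == "plane":
            z0 = float(p.get("z0", 0.0))
            return lambda x, y: np.full_like(np.asarray(x, float), z0)
        if self.kind == "tilted_plane":
            a = float(p.get("a", 0.0))
            b = float(p.get("b", 0.0))
            c = float(p.get("c", 0.0))
            return lambda x, y: a * np.asarray(x, float) + b * np.asarray(y, float) + c
        if self.kind == "hemisphere":
            R = float(p["radius"])
            cx, cy = p.get("center", (0.0, 0.0))
            return lambda x, y: np.sqrt(
                R**2 - (np.asarray(x, float) - cx) ** 2 - (np.asarray(y, float) - cy) ** 2
            )
        # sinusoid
        amp = float(p.get("amplitude", 1.0))
        lx = float(p.get("wavelength_x", 10.0))
        ly = float(p.get("wavelength_y", 10.0))
        z0 = float(p.get("z0", 0.0))
        return lambda x, y: z0 + amp * np.sin(
            2 * np.pi * np.asarray(x, float) / lx
        ) * np.sin(2 * np.pi * np.asarray(y, float) / ly)


def grid_mesh_from_height(
    height: Callable, extent: Extent, nu: int, nv: int
) -> TriangleMesh:
    """Triangulate z = height(x, y) on a regular nu x nv vertex grid."""
    xmin, xmax, ymin, ymax = extent
    xs = np.linspace(xmin, xmax, nu)
    ys = np.linspace(ymin, ymax, nv)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = height(X, Y)
    V = np.stack([X, Y, Z], axis=-1)  # (nu, nv, 3)
    a = V[:-1, :-1]
    b = V[1:, :-1]
    c = V[1:, 1:]
    d = V[:-1, 1:]
    lower = np.stack([a, b, c], axis=2).reshape(-1, 3, 3)
    upper = np.stack([a, c, d], axis=2).reshape(-1, 3, 3)
    tris = np.stack([lower, upper], axis=1).reshape(-1, 3, 3)
    return TriangleMesh.from_vertices(tris)


def make_surface(spec: SurfaceSpec) -> tuple[TriangleMesh, Callable]:
    """Build the fixture mesh and return it with its analytic height."""
    height = spec.height_function()
    mesh = grid_mesh_from_height(height, spec.extent, spec.nu, spec.nv)
    return mesh, height


def make_closed_box(
    extent: Extent = (0.0, 10.0, 0.0, 10.0),
    z_bottom: float = 1.0,
    z_top: float = 3.0,
    nu: int = 2,
    nv: int = 2,
) -> TriangleMesh:
    """Two stacked horizontal sheets; regression fixture for nearest-hit.

    A lifted downward projection must always land on the top sheet
    (shortest spatial distance), never the bottom one.
    """
    top = grid_mesh_from_height(lambda x, y: np.full_like(x, z_top), extent, nu, nv)
    bot = grid_mesh_from_height(lambda x, y: np.full_like(x, z_bottom), extent, nu, nv)
    verts = np.concatenate([top.vertices, bot.vertices])
    return TriangleMesh.from_vertices(verts)


def hemisphere_error_bound(
    spec: SurfaceSpec, query_extent: Extent | None = None
) -> float:
    """Analytic sagitta bound on |z_mesh - z_sphere| over a query region.

    For a facet whose three vertices lie on a sphere of radius R, the
    sphere's centre projects onto the plane at the circumcentre, so the
    plane sits at distance h = sqrt(R^2 - r_c^2) from the centre
    (r_c = circumradius) and the spherical patch deviates from it by at
    most the sagitta R - h along the plane normal.  The vertical
    deviation at any (x, y) inside the facet is that sagitta divided by
    the normal's tilt cosine |C| / ||(A, B, C)||.  The bound returned is
    the maximum over all facets whose XY footprint can answer a query
    in the region.
    """
    if spec.kind != "hemisphere":
        raise ValueError("bound applies to hemisphere fixtures")
    R = float(spec.params["radius"])
    mesh, _ = make_surface(spec)
    verts = mesh.vertices
    if query_extent is not None:
        qx0, qx1, qy0, qy1 = query_extent
        xy_lo = verts[:, :, :2].min(axis=1)
        xy_hi = verts[:, :, :2].max(axis=1)
        keep = (
            (xy_hi[:, 0] >= qx0) & (xy_lo[:, 0] <= qx1)
            & (xy_hi[:, 1] >= qy0) & (xy_lo[:, 1] <= qy1)
        )
        verts = verts[keep]
    ea = np.linalg.norm(verts[:, 1] - verts[:, 0], axis=1)
    eb = np.linalg.norm(verts[:, 2] - verts[:, 1], axis=1)
    ec = np.linalg.norm(verts[:, 0] - verts[:, 2], axis=1)
    normal = np.cross(verts[:, 1] - verts[:, 0], verts[:, 2] - verts[:, 0])
    area2 = np.linalg.norm(normal, axis=1)  # twice the facet area
    r_c = ea * eb * ec / (2.0 * area2)
    h = np.sqrt(np.maximum(R**2 - r_c**2, 0.0))
    sagitta = R - h
    cos_tilt = np.abs(normal[:, 2]) / area2
    return float(np.max(sagitta / cos_tilt))


def make_raster_trajectory(
    extent: Extent, pitch: float, travel_turnarounds: bool = False
) -> PlanarTrajectory:
    """Boustrophedon (serpentine) raster covering a rectangle.

    Print lines run along x at y = ymin, ymin + pitch, ...; alternate
    lines reverse direction.  Turnaround connectors are print moves by
    default, or travel moves when ``travel_turnarounds`` is set.
    """
    if pitch <= 0:
        raise ValueError(f"pitch must be > 0, got {pitch}")
    xmin, xmax, ymin, ymax = extent
    n_lines = int(np.floor((ymax - ymin) / pitch + 1e-9)) + 1
    pts: list[tuple[float, float]] = []
    kinds: list[str] = []
    for j in range(n_lines):
        y = ymin + j * pitch
        x0, x1 = (xmin, xmax) if j % 2 == 0 else (xmax, xmin)
        pts.append((x0, y))
        kinds.append(TRAVEL if (j > 0 and travel_turnarounds) else PRINT)
        pts.append((x1, y))
        kinds.append(PRINT)
    return PlanarTrajectory(np.array(pts), kinds, source_z=0.0)
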