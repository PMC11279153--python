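"""End-to-end conformal planning: STL + planar trajectory -> G-code.

Stages: read the substrate STL, load the trajectory (CSV or the first
layer of an existing G-code file), densify to spacing d, project each
point onto the surface along the projection vector, stack the conformal
passes at standoffs clearance + i * layer_height, recompute extrusion
from 3D segment lengths, and write Marlin/RepRap-flavoured G-code.
Two runs on identical inputs and config produce byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .config import PrintConfig
from .errors import TrajectoryFormatError
from .gcode import ExtrusionModel, compute_extrusion, write_gcode
from .mesh_io import read_stl
from .projection import ConformalPath, build_spatial_index, project_trajectory
from .trajectory import TRAVEL, PlanarTrajectory, densify, extract_first_layer, load_csv

log = logging.getLogger(__name__)


@dataclass
class RunSummary:
    """Machine-readable account of one planning run."""

    n_facets: int
    n_degenerate: int
    points_in: int          # densified points per layer
    n_layers: int
    points_out: int         # total output points across layers
    points_unmapped: int    # per-layer misses (dropped or passed through)
    z_min: float
    z_max: float
    total_extrusion: float
    print_length: float     # total 3D printed length, mm
    out_path: str

    def as_dict(self) -> dict:
        return asdict(self)


def load_trajectory(source: str | Path) -> PlanarTrajectory:
    """Load a planar trajectory from .csv or from a G-code file."""
    source = Path(source)
    suffix = source.suffix.lower()
    if suffix == ".csv":
        return load_csv(source)
    if suffix in (".gcode", ".gco", ".g", ".nc"):
        return extract_first_layer(source)
    raise TrajectoryFormatError(
        f"{source}: unrecognised trajectory format {suffix!r} "
        "(expected .csv or .gcode)"
    )


def stack_layers(base: ConformalPath, cfg: PrintConfig) -> ConformalPath:
    """Concatenate n_layers copies of the projected path at rising standoffs.

    The base path already includes the clearance standoff; layer i is the
    base shifted by i * layer_height along -v.  The move into the first
    point of each pass is a travel (positioning) move.
    """
    if cfg.n_layers == 1:
        return base
    v = cfg.v
    parts = [base.with_offset(-(i * cfg.layer_height) * v) for i in range(cfg.n_layers)]
    points = np.concatenate([p.points for p in parts])
    kinds: list[str] = []
    for p in parts:
        k = list(p.kinds)
        if k:
            k[0] = TRAVEL
        kinds.extend(k)
    facet_ids = np.concatenate([p.facet_ids for p in parts])
    unmapped = [i for p in parts for i in p.unmapped]
    return ConformalPath(points, kinds, facet_ids, unmapped, base.n_input * cfg.n_layers)


def run_conformal(
    cfg: PrintConfig,
    stl_path: str | Path,
    traj_source: str | Path | PlanarTrajectory,
    out_path: str | Path,
) -> RunSummary:
    """Execute the full pipeline and write G-code to ``out_path``."""
    mesh = read_stl(stl_path)
    log.info("mesh: %d facets (%d degenerate)", mesh.n_facets, len(mesh.degenerate_ids))

    if isinstance(traj_source, PlanarTrajectory):
        traj = traj_source
    else:
        traj = load_trajectory(traj_source)
    traj = densify(traj, cfg.d)
    log.info("trajectory: %d points after densification at d=%g mm", len(traj), cfg.d)

    index = build_spatial_index(mesh, cfg.v)
    base = project_trajectory(traj, mesh, cfg, index=index, layer=0)
    if base.unmapped:
        log.warning(
            "%d point(s) had no projection (policy=%s)",
            len(base.unmapped),
            cfg.no_hit_policy,
        )
    path = stack_layers(base, cfg)

    model = ExtrusionModel(cfg.nozzle_diameter, cfg.filament_diameter)
    points = compute_extrusion(path, model, cfg.print_speed, cfg.travel_speed)
    write_gcode(points, cfg, out_path)

    zs = path.points[:, 2] if len(path) else np.array([np.nan])
    return RunSummary(
        n_facets=mesh.n_facets,
        n_degenerate=len(mesh.degenerate_ids),
        points_in=len(traj),
        n_layers=cfg.n_layers,
        points_out=len(path),
        points_unmapped=len(base.unmapped),
        z_min=float(zs.min()),
        z_max=float(zs.max()),
        total_extrusion=points[-1].e if points else 0.0,
        print_length=path.path_length("print"),
        out_path=str(out_path),
    )
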