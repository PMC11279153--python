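"""G-code generation with conformal extrusion recomputation.

Because the conformal path moves in z within a layer, the extrusion for
each segment must be recomputed from the full 3D segment length

    l_i = sqrt((x_i - x_{i-1})^2 + (y_i - y_{i-1})^2 + (z_i - z_{i-1})^2),

accumulated in absolute mode as E_i = E_{i-1} + k * l_i for print moves
(E unchanged across travels), with the extrusion ratio k = D / W —
nozzle diameter over filament (wire) diameter.  This is a deliberately
simple volumetric model: no layer-height/width area correction is
applied (see docs/methods.md for the reading of the recurrence and its
limits).

Output dialect is RepRap/Marlin-flavoured: absolute positioning (G90),
absolute extrusion (M82), one G1 per print move with X/Y/Z/E/F words and
one G0 per travel move with X/Y/Z.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PrintConfig
from .projection import ConformalPath
from .trajectory import PRINT

__all__ = ["ExtrusionModel", "ToolpathPoint", "compute_extrusion", "write_gcode"]


@dataclass(frozen=True)
class ExtrusionModel:
    """Length-to-filament conversion: k = D / W."""

    D: float  # nozzle diameter, mm
    W: float  # filament (wire) diameter, mm

    def __post_init__(self) -> None:
        if not (self.D > 0 and self.W > 0):
            raise ValueError(f"diameters must be > 0, got D={self.D}, W={self.W}")

    @property
    def k(self) -> float:
        return self.D / self.W


@dataclass(frozen=True)
class ToolpathPoint:
    """One output move target with cumulative absolute extrusion."""

    x: float
    y: float
    z: float
    e: float  # cumulative extrusion, mm of filament (absolute mode)
    f: float  # feed rate, mm/min
    kind: str  # "print" | "travel"


def compute_extrusion(
    path: ConformalPath,
    model: ExtrusionModel,
    print_speed: float = 400.0,
    travel_speed: float = 1200.0,
) -> list[ToolpathPoint]:
    """Assign cumulative extrusion and feed rates to a conformal path.

    E_0 = 0; each print segment adds k times its 3D length, travel
    segments add nothing, so E is non-decreasing and the final E equals
    k times the total printed path length.
    """
    pts = np.asarray(path.points, dtype=np.float64)
    if len(pts) == 0:
        return []
    if not np.all(np.isfinite(pts)):
        raise ValueError("path contains non-finite coordinates")
    out = [
        ToolpathPoint(
            float(pts[0, 0]), float(pts[0, 1]), float(pts[0, 2]),
            0.0,
            print_speed if path.kinds[0] == PRINT else travel_speed,
            path.kinds[0],
        )
    ]
    e = 0.0
    for i in range(1, len(pts)):
        kind = path.kinds[i]
        if kind == PRINT:
            l = float(np.linalg.norm(pts[i] - pts[i - 1]))
            e += model.k * l
            f = print_speed
        else:
            f = travel_speed
        out.append(
            ToolpathPoint(
                float(pts[i, 0]), float(pts[i, 1]), float(pts[i, 2]), e, f, kind
            )
        )
    return out


def format_move(p: ToolpathPoint, xyz_decimals: int = 3, e_decimals: int = 5) -> str:
    """One G-code line for a move, fixed-decimal formatting."""
    xyz = f"X{p.x:.{xyz_decimals}f} Y{p.y:.{xyz_decimals}f} Z{p.z:.{xyz_decimals}f}"
    if p.kind == PRINT:
        return f"G1 {xyz} E{p.e:.{e_decimals}f} F{p.f:g}"
    return f"G0 {xyz}"


def write_gcode(
    points: list[ToolpathPoint], cfg: PrintConfig, path: str | Path
) -> None:
    """Write the toolpath to a G-code file.

    Header: G90 + M82 followed by any configured preamble lines; then
    one line per move; then the configured footer.
    """
    if not points:
        raise ValueError("cannot write G-code for an empty toolpath")
    lines = ["G90", "M82"]
    lines.extend(cfg.preamble)
    lines.extend(
        format_move(p, cfg.xyz_decimals, cfg.e_decimals) for p in points
    )
    lines.extend(cfg.footer)
    Path(path).write_text("\n".join(lines) + "\n")
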