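"""Planar target trajectories: CSV / G-code loading and densification.

The target trajectory is an ordered polyline of XY points on the build
plane.  Before projection it is densified so that no print segment is
longer than the spacing d (default 1 mm): a segment of length L > d gets
ceil(L/d) - 1 equally spaced interior points, leaving uniform gaps of
L / ceil(L/d) <= d.  Smaller d makes the projected track follow the
substrate surface more closely; overly long segments can even collide
with the nozzle on curved substrates.

Point kinds: ``kinds[i]`` describes the move *into* point i ("print" or
"travel").  The move into the first point is always a positioning travel.
Travel segments are projected but never densified and carry no extrusion.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyLayerError, GcodeParseError, TrajectoryFormatError

PRINT = "print"
TRAVEL = "travel"


@dataclass
class PlanarTrajectory:
    """Ordered polyline of target points on the build plane.

    Attributes
    ----------
    points : (n, 2) float64 array
        XY coordinates in mm, in path order.
    kinds : list of str
        ``kinds[i]`` is the move kind into point i; ``kinds[0]`` is
        always "travel" (initial positioning).
    source_z : float
        The z at which the points are considered to lie before lifting.
    d : float or None
        Densification spacing applied, if any.
    """

    points: np.ndarray
    kinds: list[str] = field(default_factory=list)
    source_z: float = 0.0
    d: float | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.shape[1] != 2:
            raise ValueError("trajectory points must be (n, 2)")
        if not self.kinds:
            self.kinds = [PRINT] * len(self.points)
        if len(self.kinds) != len(self.points):
            raise ValueError("kinds length must match points")
        if len(self.kinds):
            self.kinds[0] = TRAVEL
        bad = set(self.kinds) - {PRINT, TRAVEL}
        if bad:
            raise ValueError(f"unknown move kinds: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.points)

    def path_length(self) -> float:
        """Total polyline length over all segments (mm)."""
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def densify(traj: PlanarTrajectory, d: float) -> PlanarTrajectory:
    """Insert points so every print-segment gap is <= d.

    A segment of length L > d is subdivided into ceil(L/d) equal parts,
    so all resulting gaps equal L / ceil(L/d).  Endpoints are preserved
    exactly (original points remain in the output, in order), segments
    with L <= d are untouched, and travel segments are never densified.
    Idempotent: densifying an already-densified trajectory is a no-op.
    """
    if d <= 0:
        raise ValueError(f"densification spacing d must be > 0, got {d}")
    if len(traj) < 2:
        return PlanarTrajectory(traj.points.copy(), list(traj.kinds), traj.source_z, d)

    out_pts: list[np.ndarray] = [traj.points[0]]
    out_kinds: list[str] = [traj.kinds[0]]
    for i in range(1, len(traj)):
        p0, p1 = traj.points[i - 1], traj.points[i]
        kind = traj.kinds[i]
        L = float(np.linalg.norm(p1 - p0))
        # small slack keeps gaps that round to exactly d from re-splitting
        k = math.ceil(L / d - 1e-12) - 1 if kind == PRINT and L > d else 0
        if k > 0:
            frac = np.arange(1, k + 1) / (k + 1)
            interior = p0 + frac[:, None] * (p1 - p0)
            out_pts.extend(interior)
            out_kinds.extend([kind] * k)
        out_pts.append(p1)
        out_kinds.append(kind)
    return PlanarTrajectory(np.vstack(out_pts), out_kinds, traj.source_z, d)


def load_csv(path: str | Path) -> PlanarTrajectory:
    """Load a trajectory from a CSV with header columns x,y[,kind]."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TrajectoryFormatError(f"{path}: empty CSV") from None
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise TrajectoryFormatError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    if len(df) == 0:
        raise TrajectoryFormatError(f"{path}: no data rows")
    pts = np.empty((len(df), 2))
    for j, col in enumerate(("x", "y")):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise TrajectoryFormatError(
                f"{path}: non-numeric value in column '{col}' at data row {row}"
            )
        pts[:, j] = vals.to_numpy(dtype=np.float64)
    if "kind" in df.columns:
        kinds = [str(k).strip().lower() for k in df["kind"]]
        bad = sorted(set(kinds) - {PRINT, TRAVEL})
        if bad:
            raise TrajectoryFormatError(f"{path}: unknown kind value(s) {bad}")
    else:
        kinds = [PRINT] * len(df)
    return PlanarTrajectory(pts, kinds, source_z=0.0)


# one G-code word: letter + signed decimal number
_WORD_RE = re.compile(r"([A-Za-z])\s*([-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)")
_COMMENT_RE = re.compile(r";.*|\(.*?\)")


def _parse_moves(text: str):
    """Yield (x, y, z, e, line_no) for each G0/G1 move, modal words applied."""
    state = {"X": 0.0, "Y": 0.0, "Z": 0.0, "E": 0.0}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = _COMMENT_RE.sub("", raw).strip()
        if not line:
            continue
        words = _WORD_RE.findall(line)
        if not words:
            continue
        letter0 = words[0][0].upper()
        num0 = float(words[0][1])
        if (letter0, num0) == ("G", 91.0) or (letter0, num0) == ("M", 83.0):
            raise GcodeParseError(
                f"line {line_no}: relative "
                f"{'positioning (G91)' if letter0 == 'G' else 'extrusion (M83)'} "
                f"is not supported; absolute-mode G-code required"
            )
        if letter0 != "G" or num0 not in (0.0, 1.0):
            continue
        has_xy = False
        for letter, value in words[1:]:
            letter = letter.upper()
            if letter in state:
                state[letter] = float(value)
                if letter in ("X", "Y"):
                    has_xy = True
        yield state["X"], state["Y"], state["Z"], state["E"], has_xy


def extract_first_layer(path: str | Path) -> PlanarTrajectory:
    """Extract the first printed layer of a G-code file as a trajectory.

    The first layer is the Z at which extrusion (an increasing E word)
    first occurs; all moves at that Z (within 1e-6 mm) are returned in
    order, flagged "print" when their E increased and "travel" otherwise.
    Modal coordinates are handled: absent words inherit the last value.
    Raises :class:`EmptyLayerError` when no extruding move exists.
    """
    path = Path(path)
    text = path.read_text()
    moves = list(_parse_moves(text))

    layer_z = None
    prev_e = 0.0
    for x, y, z, e, _ in moves:
        if e > prev_e + 1e-12:
            layer_z = z
            break
        prev_e = e
    if layer_z is None:
        raise EmptyLayerError(f"{path}: no extruding move found")

    pts: list[tuple[float, float]] = []
    kinds: list[str] = []
    prev_e = 0.0
    for x, y, z, e, has_xy in moves:
        if has_xy and abs(z - layer_z) <= 1e-6:
            pts.append((x, y))
            kinds.append(PRINT if e > prev_e + 1e-12 else TRAVEL)
        prev_e = e
    if len(pts) < 2:
        raise EmptyLayerError(f"{path}: first layer has fewer than 2 XY positions")
    return PlanarTrajectory(np.array(pts), kinds, source_z=float(layer_z))
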