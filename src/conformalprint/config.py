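"""Run configuration for the conformal planning pipeline.

All lengths are millimetres, speeds mm/min.  Defaults follow the printing
setup the algorithm was developed for: projection straight down
v = (0, 0, -1), densification spacing d = 1 mm, a 0.2 mm nozzle standoff
reserved during z calibration, and a 0.4 mm conformal layer height.
Nozzle and filament diameters have no sensible universal default and must
be supplied (e.g. 0.4 / 1.75 for an FDM printer, 0.39 for a hydrogel
needle).
"""

from __future__ import annotations

from typing import Literal, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

from .errors import ConfigError

NoHitPolicy = Literal["error", "drop", "passthrough"]


class PrintConfig(BaseModel):
    """Validated configuration for one conformal planning run."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    #: projection direction (normalized on validation); (0,0,-1) casts
    #: trajectory points straight down so only Z is transformed
    vector: Tuple[float, float, float] = (0.0, 0.0, -1.0)
    #: densification spacing d, mm
    d: float = 1.0
    #: nozzle diameter D, mm (required)
    nozzle_diameter: float
    #: filament (wire) diameter W, mm (required)
    filament_diameter: float
    #: standoff between nozzle tip and substrate, mm
    clearance: float = 0.2
    #: conformal layer thickness, mm
    layer_height: float = 0.4
    #: number of conformal passes
    n_layers: int = 1
    print_speed: float = 400.0
    travel_speed: float = 1200.0
    #: what to do with trajectory points that miss the mesh
    no_hit_policy: NoHitPolicy = "error"
    #: lift above the mesh bbox top before projecting, mm
    lift_margin: float = 1.0
    #: restrict projection to forward hits (t >= 0) only
    forward_only: bool = False
    #: barycentric boundary tolerance of the containment filter
    eps_bary: float = 1e-9
    #: |t| tie window for nearest-hit facet_id tie-breaking, mm
    tie_tol: float = 1e-9
    # G-code output dialect knobs
    xyz_decimals: int = 3
    e_decimals: int = 5
    preamble: Tuple[str, ...] = ()
    footer: Tuple[str, ...] = ()

    @field_validator(
        "d", "nozzle_diameter", "filament_diameter", "layer_height",
        "print_speed", "travel_speed", "lift_margin",
    )
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if not v > 0:
            raise ValueError(f"{info.field_name} must be > 0, got {v}")
        return v

    @field_validator("clearance")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"clearance must be >= 0, got {v}")
        return v

    @field_validator("n_layers")
    @classmethod
    def _at_least_one(cls, v: int) -> int:
        if v < 1:
            raise ValueError(f"n_layers must be >= 1, got {v}")
        return v

    @model_validator(mode="after")
    def _normalize_vector(self) -> "PrintConfig":
        v = np.asarray(self.vector, dtype=float)
        norm = float(np.linalg.norm(v))
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("projection vector must be non-zero and finite")
        object.__setattr__(self, "vector", tuple((v / norm).tolist()))
        return self

    @property
    def v(self) -> np.ndarray:
        """Unit projection vector as an array."""
        return np.asarray(self.vector, dtype=np.float64)

    @property
    def extrusion_ratio(self) -> float:
        """k = D / W, the length-to-filament conversion factor."""
        return self.nozzle_diameter / self.filament_diameter


def validate_config(raw: dict) -> PrintConfig:
    """Build a :class:`PrintConfig` from a raw key-value mapping.

    Unknown keys and out-of-range values raise :class:`ConfigError`
    listing the offending key(s).
    """
    try:
        return PrintConfig(**raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc']) or '<config>'}: {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {details}") from None
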