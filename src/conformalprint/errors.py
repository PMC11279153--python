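"""Exception hierarchy for the conformal toolpath pipeline.

Exit-code mapping used by the CLI: configuration problems -> 2,
projection failures -> 3, file I/O and format problems -> 4.
"""


class ConformalError(Exception):
    """Base class for all package errors."""


class ConfigError(ConformalError):
    """Invalid run configuration (bad parameter value or unknown key)."""


class StlFormatError(ConformalError):
    """File is not a readable binary or ASCII STL."""


class EmptyMeshError(ConformalError):
    """Mesh contains no usable (non-degenerate) facets."""


class TrajectoryFormatError(ConformalError):
    """Trajectory CSV is malformed (missing columns, non-numeric cells)."""


class GcodeParseError(ConformalError):
    """G-code input cannot be parsed or uses an unsupported mode."""


class EmptyLayerError(GcodeParseError):
    """No extruding move found when extracting the first layer."""


class UnmappedPointError(ConformalError):
    """A trajectory point has no valid projection onto the mesh.

    Carries the densified input index and XY coordinates of the first
    offending point so the user can locate it.
    """

    def __init__(self, index: int, x: float, y: float):
        self.index = index
        self.x = x
        self.y = y
        super().__init__(
            f"trajectory point {index} at (x={x:.4f}, y={y:.4f}) has no "
            f"projection onto the mesh (outside the substrate footprint?)"
        )
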