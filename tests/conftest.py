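import numpy as np
import pytest

from conformalprint import PrintConfig, TriangleMesh


@pytest.fixture
def unit_triangle_verts():
    """Right triangle in the z=0 plane: (0,0,0), (1,0,0), (0,1,0)."""
    return np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


@pytest.fixture
def make_config():
    """Config factory with the required diameters filled in."""

    def _make(**overrides):
        base = {"nozzle_diameter": 0.4, "filament_diameter": 1.75}
        base.update(overrides)
        return PrintConfig(**base)

    return _make


def mesh_from_tris(tris) -> TriangleMesh:
    return TriangleMesh.from_vertices(np.asarray(tris, dtype=float))


ASCII_ONE_FACET = """solid fixture
facet normal 0 0 1
 outer loop
  vertex 0 0 0
  vertex 1 0 0
  vertex 0 1 0
 endloop
endfacet
endsolid fixture
"""
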