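# Methods

## Problem and model

Conformal 3D printing deposits material along a curved substrate rather
than in flat layers. The planner takes (a) the substrate surface as an
STL triangle soup and (b) a planar target trajectory — an ordered XY
polyline, either from a CSV or extracted from the first layer of sliced
G-code — and produces a 3D toolpath on the surface plus printable
G-code. The geometric model is a *global parallel projection*: every
trajectory point is cast along one fixed direction **v** onto the mesh.
This suits shallow free-form substrates (skin, bone surfaces, domes
well inside the equator); it is not a geodesic or normal-offset method
and makes no attempt to preserve on-surface spacing on steep flanks,
where a 1 mm planar gap stretches to 1/cos φ mm on a surface inclined
by φ.

## Pipeline and numerical choices

**Plane derivation.** Facet planes A x + B y + C z + D = 0 are always
rederived from vertices via the cross-product expansion; stored STL
normals are ignored because they are unreliable in the wild. STL's
float32 vertices are promoted to float64 before any arithmetic — the
line parameter t is a ratio of near-cancelling dot products and loses
several digits in single precision. Facets with area < 1e−12 mm² are
recorded as degenerate and excluded from projection (scanned anatomical
meshes routinely contain slivers); they are logged, not fatal.

**Densification.** A print segment of length L > d is split into
⌈L/d⌉ equal parts, giving uniform gaps L/⌈L/d⌉ ≤ d and no short
residual piece at one end. A 1e−12 relative slack in the ceiling stops
gaps that round to exactly d from re-splitting, making densification
idempotent. Travel segments are not densified: they gain no
conformality and carry no extrusion. Default d = 1 mm.

**Trajectory lift.** The planar points are lifted to
z_start = (mesh bbox top) + lift_margin (default 1 mm) before
projection. Without this, the shortest-distance rule on a *closed* mesh
could select the underside. Lifting makes the nearest hit the upper
surface; a `forward_only` flag additionally restricts hits to t ≥ 0.
The closed-box fixture (sheets at z = 1 and z = 3) regression-tests
this choice.

**Containment filter.** Barycentric (m, n) are solved from a 2×2
system in the two coordinate axes least aligned with the facet normal
(dropping the largest normal component), which keeps the system well
conditioned for near-vertical facets. The inside test
m ≥ −ε, n ≥ −ε, m + n ≤ 1 + ε uses ε = 1e−9: strictly positive
thresholds would lose points that land exactly on an edge shared by two
facets due to float error. Boundary points may then pass in *both*
facets; the nearest-hit rule with lowest-facet-id tie-break (tie window
1e−9 mm) dedupes them deterministically. Degenerate facets never pass.

**Nearest hit and spatial index.** All candidate facets are scored by
|t| (the spatial distance for unit **v**). The uniform 2D grid index
bins each facet's AABB — projected onto the plane orthogonal to
**v** and padded by 1e−6 mm to absorb the barycentric tolerance — into
√n × √n cells (capped at 256). Because a hit shares the query's
coordinates in that plane, the candidate set is a strict superset of
all true hits, so indexed and exhaustive traversal give bit-identical
results; the index only changes runtime.

**Standoff and layers.** Every hit is offset by
clearance + i·layer_height along −**v** for layer i. The default
0.2 mm clearance reproduces a nozzle-height reservation typical of
z-axis calibration against soft substrates. Multi-layer conformal
printing is approximated by stacking the *same* projected path at
standoffs 0.2, 0.6, 1.0, … mm (e.g. 5 layers × 0.4 mm); this emulates
surface-offset shelling well for shallow surfaces but, unlike a true
CAD offset, does not re-project onto the previously printed layer.

**Extrusion.** The cumulative absolute extrusion is
E_i = E_{i−1} + k·l_i with l_i the 3D segment length and k = D/W. A
literal reading of the recurrence "e(i) = k·[l + Σe(i−1)]" would
re-scale the already-scaled accumulated extrusion by k at every step
and diverges from any physical interpretation for k ≠ 1; the
implementation uses the standard cumulative form, which coincides with
that recurrence when the bracketed sum is understood as accumulated
unscaled length. No strict-literal mode is provided. k = D/W is a
deliberately simplified volumetric model (no layer-height/width area
correction): fidelity to the simple published relation was preferred
over slicer realism, and the G-code is expected to be re-tuned per
material anyway (hydrogels are driven by air pressure, not E values).

**G-code dialect.** Output: G90, M82, configurable preamble, one
`G1 X Y Z E F` per print move (3 decimals XYZ, 5 decimals E by
default), one `G0 X Y Z` per travel, configurable footer. Input parsing
(first-layer extraction) is regex-based with modal words; relative
positioning (G91) or relative extrusion (M83) input is rejected with a
clear error, and arc moves are out of scope. The first layer is
detected as the Z of the first move with increasing E, which works
across slicer dialects without relying on layer comments.

## Synthetic fixtures and what they show

`fixtures` generates substrates with exact closed forms: plane, tilted
plane z = a x + b y + c, open hemispherical cap, and a doubly-sinusoidal
sheet, each as a regular grid triangulated two facets per cell, returned
together with the analytic height z(x, y). Planes are reproduced by the
mesh exactly, so projection must agree to ≤ 1e−9 mm; curved surfaces
agree only to the tessellation's chordal error, for which
`hemisphere_error_bound` computes an analytic bound: a facet with
vertices on a sphere of radius R lies at distance √(R²−r_c²) from the
centre (r_c = circumradius), deviates from the sphere by at most the
sagitta R − √(R²−r_c²), and the vertical error divides by the normal's
tilt cosine. A 128×128 cap of R = 20 mm gives a ≈ 5.6 µm bound over a
24 mm query window; the measured error is ≈ 2 µm.

These fixtures exercise every algorithmic path (projection, filtering,
nearest-hit, indexing, extrusion) but are tame compared to real scans:
no self-overlapping facets from noisy reconstruction, no holes or
non-manifold edges, no steep overhangs, single-valued height fields
(except the closed box). Passing tests therefore demonstrate
correctness of the geometry kernel, not robustness to arbitrary scan
defects — though degenerate facets, duplicate/overlapping facets and
shared-edge hits are covered by dedicated unit tests.

Problem sizes in the test suite and acceptance script (hemisphere at
128×128 ≈ 32k facets with 1000 query points; ten randomized ≤ 5000-facet
meshes × 1000 points for index equivalence) were chosen to exercise the
index at realistic mesh densities while keeping a full run in seconds.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `vector` | (0, 0, −1) | — | global projection direction (normalized) |
| `d` | 1.0 | mm | max gap between densified print points |
| `nozzle_diameter` (D) | required | mm | e.g. 0.4 (FDM), 0.39 (hydrogel needle) |
| `filament_diameter` (W) | required | mm | e.g. 1.75 |
| `clearance` | 0.2 | mm | nozzle standoff above the substrate |
| `layer_height` | 0.4 | mm | per-pass offset for multi-layer jobs |
| `n_layers` | 1 | — | number of stacked conformal passes |
| `print_speed` / `travel_speed` | 400 / 1200 | mm/min | feed rates |
| `no_hit_policy` | error | — | error \| drop \| passthrough for misses |
| `lift_margin` | 1.0 | mm | lift above bbox top before projecting |
| `eps_bary` | 1e−9 | — | containment boundary tolerance |
| `tie_tol` | 1e−9 | mm | nearest-hit tie window |

All tolerances are part of the public contract and configurable.

## Known limitations

- Single global projection direction; no per-point surface-normal
  projection, no collision checking of the physical nozzle body.
- Multi-layer passes re-use the layer-0 projection (offset stacking),
  not a re-projection onto the grown surface.
- k = D/W extrusion ignores layer geometry; E values are nominal for
  pressure-driven extruders.
- G-code input must be absolute-mode G0/G1; arcs (G2/G3) unsupported.
- Points outside the mesh footprint are an error by default; "drop"
  changes path connectivity (the neighbouring segment inherits the
  surviving point's kind) and "passthrough" leaves points hovering at
  the lift height as travel targets.
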