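# conformalprint

Toolpath planning for **conformal 3D printing**: instead of depositing
material in flat layers, the printing trajectory follows the curved
surface of the substrate — the key path-planning step for printing onto
free-form objects, in particular for *in situ* bioprinting of hydrogels
onto skin or bone defects. Given a substrate surface as an STL triangle
mesh and a planar target trajectory, `conformalprint` projects the
trajectory onto the surface and emits ready-to-print G-code with
extrusion recomputed from true 3D path lengths.

## The algorithm

1. **Densify** the planar XY trajectory so no print segment exceeds a
   spacing *d* (default 1 mm): a segment of length *L* > *d* is split
   into ⌈*L*/*d*⌉ equal parts. Smaller *d* makes the printed track
   follow the substrate more closely.
2. **Derive facet planes.** Each STL facet with vertices
   (x₁,y₁,z₁),(x₂,y₂,z₂),(x₃,y₃,z₃) defines a plane
   *A*x + *B*y + *C*z + *D* = 0 with (A, B, C) = (v₂−v₁)×(v₃−v₁)
   and D = −(A x₁ + B y₁ + C z₁). Stored STL normals are ignored.
3. **Project** each trajectory point P along a global direction
   **v** (default (0, 0, −1)): the line P + t**v** meets a facet plane at
   t = −(A·Pₓ + B·P_y + C·P_z + D)/(A·vₓ + B·v_y + C·v_z).
4. **Filter** intersections by barycentric containment: solving
   P_hit = (1−m−n)·T₁ + m·T₂ + n·T₃, the hit lies inside the facet iff
   m ≥ 0, n ≥ 0, m + n ≤ 1 (boundary inclusive, with a 1e−9 tolerance
   so points on shared edges are never lost).
5. **Select** the hit with the shortest spatial distance |t| from P;
   ties go to the lowest facet id, so overlapping facets resolve
   deterministically. A uniform 2D grid index over the plane ⊥ **v**
   prunes candidate facets without changing any result.
6. **Offset** each hit by the nozzle standoff (default 0.2 mm) along
   −**v**; layer *i* of a multi-layer job adds *i*·layer_height more.
7. **Recompute extrusion** in absolute mode:
   Eᵢ = Eᵢ₋₁ + k·lᵢ with lᵢ the full 3D segment length (Δz included —
   that is the point of conformal extrusion correction) and
   k = D/W the nozzle-to-filament diameter ratio. Travel moves leave E
   unchanged. Output is RepRap/Marlin-flavoured G-code (G90/M82, G1
   print moves with X/Y/Z/E/F, G0 travels).

## Worked example

Export a synthetic hemispherical dome (radius 20 mm), build a 2 mm-pitch
serpentine patch trajectory, and plan a conformal layer:

```sh
conformal fixture --kind hemisphere --out dome.stl \
    --nu 64 --nv 64 --extent=-13,13,-13,13 --param radius=20

python -c "
from conformalprint import make_raster_trajectory
t = make_raster_trajectory((-10,10,-10,10), 2)
open('patch.csv','w').write('x,y\n' + '\n'.join(f'{x},{y}' for x,y in t.points) + '\n')
"

conformal plan --stl dome.stl --traj patch.csv --out dome.gcode \
    --nozzle 0.4 --filament 1.75
```

which prints the run summary

```json
{
  "n_facets": 7938,
  "n_degenerate": 0,
  "points_in": 241,
  "n_layers": 1,
  "points_out": 241,
  "points_unmapped": 0,
  "z_min": 14.337481883211572,
  "z_max": 20.19787139892578,
  "total_extrusion": 57.87047232032463,
  "print_length": 253.18331640142026,
  "out_path": "dome.gcode"
}
```

All 241 densified points found a projection; the toolpath climbs from
z ≈ 14.34 mm at the patch rim to z ≈ 20.20 mm at the dome apex (the
0.2 mm standoff above the 20 mm sphere), and the 253.2 mm of printed
path needs 57.87 mm of filament (253.18 × 0.4/1.75). The G-code starts

```gcode
G90
M82
G0 X-10.000 Y-10.000 Z14.337
G1 X-9.000 Y-10.000 Z14.995 E0.27355 F400
G1 X-8.000 Y-10.000 Z15.560 E0.53606 F400
```

— XY are exactly the input trajectory coordinates (straight-down
projection only transforms Z), and E grows by k times each segment's
3D length.

Trajectories can also be pulled from the first layer of an existing
sliced G-code file (`--traj part.gcode`), the way a conventional slicer
output is repurposed as the planar target.

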