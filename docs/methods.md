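# Methods

## Problem and scope

A hematoma segmented from head CT is represented as a triangle surface mesh,
and its volume is the clinically relevant quantity.  The package implements
the three estimators commonly applied to such meshes — the projection
(divergence-theorem) method, two slice-accumulation rules, and octree
voxelization with boundary refinement — together with everything needed to
compare them under controlled conditions: benchmark solids of known volume,
star-shaped hematoma phantoms spanning the clinical shape classes, damage
operators (holes, flipped windings), diagnostics, and two independent volume
oracles.  DICOM ingestion and image segmentation are out of scope: the mesh
is the input.

## The estimators

**Projection.** Each face contributes, per coordinate axis, Heron area times
the unit-normal component times the centroid coordinate — the signed volume
of the prism between the face and the coordinate plane.  For a closed,
consistently oriented surface the three axis sums V_x, V_y, V_z each equal
the enclosed volume (divergence theorem), so any convex combination
k_x V_x + k_y V_y + k_z V_z is exact; equal weights 1/3 are the default.  A
`normal_weighted` mode weights each axis by the magnitude of the net
area-weighted normal, which is non-zero only when the surface has a hole;
on closed meshes it falls back to equal weights, so the two modes differ
only on invalid input, where the method is unreliable either way.  Open or
mis-oriented meshes produce a warning, not an error: the failure mode must
be runnable to be measurable.

**Slicing.**  2^s + 1 planes perpendicular to the slicing axis (z by
default, the CT axial direction) uniformly span the mesh extent.  Each
plane-triangle intersection yields a segment keyed by the mesh edge it
crosses, so segments from the two faces sharing an edge meet at bit-identical
points and contour chaining is exact graph traversal.  Loop areas come from
the shoelace formula, with nesting parity deciding hole signs.  Consecutive
areas accumulate by the conical-frustum rule (method 1, exact whenever
cross-sections are similar — pyramids and cones at any slice count) or the
trapezoid rule (method 2, error O(step²)).

**Voxelization.**  The bounding cube (side = largest bbox extent, anchored
at the bbox minimum corner so grid-aligned solids voxelize exactly) is
subdivided wherever a cell meets the surface (separating-axis triangle-box
test, touching counts as overlap) down to depth s − 1, giving the
boundary-voxel edge max_extent/2^(s−1) that pairs with the 2^s slice count.
Cells free of surface become leaves immediately and are classified inside or
outside by point-in-contour parity at their center plane; for a leaf the
surface is at least half a cell side away from the center, so the test is
robust, and because it uses gap-closed contours and never reads face
orientation it works unchanged on open and flipped-winding meshes.  The
boundary-voxel volume is refined with the slice rule in one of two modes:

* `slice_aligned` (default): the global trapezoid slice stack is evaluated
  over the complement of the inside-leaf region, so the total coincides with
  slice method 2 at the same resolution by construction.  This mirrors the
  observed behaviour of the two methods, whose results agree to the printed
  precision in every benchmark configuration.
* `sub_slices(k)`: each boundary cell is integrated independently from
  cross-sections clipped to the cell footprint, k trapezoid intervals per
  cell — the literal per-voxel reading of boundary refinement.  Its error at
  least halves per depth increment on smooth phantoms.

**ABC/2 comparator.**  `tada_volume` is the bedside formula V = A·B·C/2;
`tada_from_mesh` measures A (longest diameter of the maximal-area slice),
B (perpendicular width on that slice) and C (axial extent) from the mesh the
way a clinician reads a CT stack.  On an ellipsoid with diameters A = 2a,
B = 2b, C = 2c it returns 4abc against the true (4/3)πabc — a systematic
3/π ≈ −4.5% — and degrades further on irregular and lobular shapes.

**Oracles.**  The signed tetrahedron sum Σ det(P0, P1, P2)/6 is the exact
reference for closed meshes; Monte-Carlo rejection sampling in the bounding
box (ray-parity inside test, seeded jittered re-casts on degenerate hits)
reports its estimate with the binomial standard error
bbox_volume·√(p(1−p)/n).

## Numerical choices

* **Plane-through-vertex handling: symbolic perturbation.**  Vertices lying
  exactly on a slicing plane are classified to a fixed side, equivalent to
  moving the plane by an infinitesimal.  Intersection parameters on touching
  edges then evaluate to exactly 0 or 1, so sections through vertex rings
  and flat caps are exact — no numeric nudge, hence no O(ε) bias, which is
  what keeps the frustum rule exact to 1e-9 on pyramids at every slice
  count.  Endpoint planes use the perturbation direction pointing into the
  solid, so the first and last sections are the limiting sections from
  inside (a cube's top plane reports area a², not 0, even with the top cap
  removed).
* **Gap closing.**  Contour chains left open by mesh boundary are joined
  nearest-endpoint-first into forced loops and counted
  (`open_chain_count`).  For a hole lying in a plane parallel to the slices
  (the cap-removed benchmarks) this reconstructs the closed contours
  exactly, which is why the slice and voxel columns are unchanged between
  closed and unclosed benchmark rows.
* **Vertex merging on input**: tolerance 1e-8 × bbox diagonal (STL stores
  per-facet vertices; merging is required before topology analysis).
  File-stored normals are always discarded — winding is the only
  self-consistent orientation source.
* **Degenerate faces** (Heron area ≤ 1e-12 × bbox diagonal²) are flagged and
  skipped by estimators, counted in the topology report, never fatal.
* **Ray-parity ties**: hits within barycentric 1e-10 of a triangle boundary
  trigger a re-cast in a seeded jittered direction (deterministic for a
  fixed seed).

## Benchmark and phantom conditions

The standard models are the quadrangular pyramid l = w = 30, h = 20 (volume
l·w·h/3 = 6000) and the cube a = 10 (volume 1000), both dimensionless model
units; measurements run at segments = 7 (128 slice intervals, boundary-voxel
edges 30/64 = 0.46875 and 10/64 = 0.15625).  The triangulation density is a
free parameter: midpoint subdivision leaves the surfaces — and therefore all
results — unchanged, and the suite proves subdivision-independence instead
of matching any particular facet count.  At these settings the trapezoid
rule's analytic error on the pyramid is n·h³·S″/12 = 128·(20/128)³·4.5/12 =
0.18310546875, the value the benchmark table prints as 6000.18.  The open
variants remove the pyramid's base cap and the cube's top cap — holes in
planes parallel to the slices, the only removal consistent with unchanged
slice/voxel estimates.

Phantoms are star-shaped blobs: an icosphere (subdivided icosahedron) whose
vertices are moved to the ellipsoid radius along their direction times
(1 + Σ Gaussian bumps at seeded random directions).  Star-shapedness
guarantees closed, self-intersection-free, consistently oriented meshes with
no repair step.  Shape-class presets: regular — no bumps; irregular — 24
bumps of relative amplitude 0.06, width 0.25 rad (frayed margins); lobular —
3 bumps of amplitude 0.4, width 0.6 rad.  Default semi-axes (12, 10, 9) mm
give ≈ 4.5 ml, with larger presets reaching the 10–20 ml and > 20 ml
clinical size groups.  The phantom is placed at (60, 60, 40) mm,
scanner-like coordinates: CT reconstructions are never centred on the
lesion, and the open-mesh projection error grows with the removed patch's
coordinates, so an origin-centred phantom would be an unrealistically
favourable special case for exactly the failure mode under study.

What the phantoms do not emulate: segmentation noise (sliver triangles,
staircase artifacts), non-star-shaped or multi-component hematomas, and
hole shapes other than removed caps/disks.  Passing tests therefore
demonstrate the estimators' mathematical behaviour and their relative
robustness ordering, not clinical accuracy on patient data, which requires
the imaging pipeline this package deliberately excludes.

Cohort runs keep the convention that the reference method (projection by
default) is evaluated on the intact closed mesh and every compared method on
the damaged variant; error = estimate − reference per phantom, summarised as
mean signed and mean absolute error per shape class and, when units are
declared, per ml size group (< 10, 10–20, > 20 ml).

## Problem sizes

The default suite and the reproduction script use midpoint-subdivided
benchmarks (96-face pyramid, 192-face cube), 1280-face phantoms
(icosphere level 3; level 4, 5120 faces, where sub-percent ellipsoid
agreement is asserted), slice counts up to 256, octree depths up to 6, and
2·10⁵ Monte-Carlo samples — sizes chosen so every quantity is resolved far
beyond its assertion tolerance while the whole suite runs in about a minute.

## Known limitations

* `reorient` requires a closed, edge-manifold mesh; it does not repair holes
  or non-manifold fins.
* Gap closing is nearest-endpoint greedy; pathological multi-hole contours
  could be re-joined differently than the true surface.
* The octree is built in Python; depths beyond ~7 get slow (minutes).
* `normal_weighted` projection weights are one plausible reading of the
  underdetermined weight definition; on closed meshes all weightings agree,
  and no claim is made about matching any particular implementation's
  open-mesh output.
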