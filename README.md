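# hemavol

Triangle-mesh volumetry for intracerebral-hemorrhage (ICH) models.

The volume of a hematoma segmented from CT guides treatment and prognosis,
and in practice it is read off a triangulated surface model.  The common
estimators disagree in exactly the situations real segmentations produce:
surfaces with holes (non-closed meshes) and surfaces with wrong normal
orientation.  `hemavol` implements the three estimators side by side, with
watertightness diagnostics, benchmark solids of known volume, star-shaped
hematoma phantoms, damage operators, and a cohort comparison harness, so the
failure modes can be measured rather than guessed at.

## Methods

For a mesh with faces of Heron area `A_f`, unit normal `u_f` (from the
winding) and centroid `c_f`:

* **Projection (divergence-theorem) method** — the rule 3D-Slicer/VTK uses:
  `V_axis = Σ_f A_f · u_f,axis · c_f,axis`, combined as
  `V = k_x V_x + k_y V_y + k_z V_z` with weights summing to 1 (equal weights
  by default).  Exact for closed, consistently oriented meshes; silently
  wrong, and origin-dependent, otherwise.
* **Slice method** — cut by `2^s` uniform planes along the CT axial axis,
  measure each cross-section area `S_i` (shoelace over gap-closed contour
  polygons), and accumulate either by the conical-frustum rule
  `V_i = (S_i1 + S_i2 + √(S_i1 S_i2)) · step / 3` (method 1) or the
  trapezoid rule `V_i = (S_i1 + S_i2) · step / 2` (method 2).  Orientation-
  and closure-insensitive.
* **Octree voxelization** — subdivide the bounding cube around the surface
  to boundary-voxel edge `max_extent / 2^(s−1)`, classify leaves inside or
  outside by contour parity, and refine the boundary-voxel volume with the
  slice rule.  Also orientation- and closure-insensitive.
* **ABC/2 (Tada) comparator** — the bedside formula `V = A·B·C/2`.

Two oracles validate everything: the signed tetrahedron sum
`V = Σ_f det(P0, P1, P2)/6` and Monte-Carlo rejection sampling with its
binomial standard error.

## Worked example

Generate the benchmark pyramid (length 30, width 30, height 20; true volume
`l·w·h/3 = 6000`) and measure it:

```sh
$ hemavol generate pyramid --l 30 --w 30 --h 20 -o pyr.stl
wrote pyr.stl: 50 vertices, 96 faces, closed=True
$ hemavol measure pyr.stl --method slice1 --segments 7
slice1: volume = 6000.000000
$ hemavol measure pyr.stl --method slice2 --segments 7
slice2: volume = 6000.183105
$ hemavol measure pyr.stl --method projection
projection: volume = 6000.000000
```

The frustum rule is exact for a pyramid (similar cross-sections); the
trapezoid rule carries its analytic `n·h³·S″/12 = 0.18310546875` error at
128 intervals; the projection method is exact because the mesh is closed.

A lobular hematoma phantom in mm, measured by voxelization:

```sh
$ hemavol generate blob --shape-class lobular --seed 4 -o blob.stl
wrote blob.stl: 642 vertices, 1280 faces, closed=True
$ hemavol measure blob.stl --method voxel --segments 6 --units mm
voxel: volume = 5968.454475 mm^3 = 5.968454 ml
```

Cohort comparisons take a JSON list of phantom specs (optionally with a
`"open_patch"` hole or `"flip_fraction"` winding damage) and write per-mesh,
per-method errors against a reference method as CSV:

```sh
$ hemavol compare --cohort cohort.json --methods slice2,voxel,projection \
      --segments 5 --reference projection -o results.csv --verbose
```

On damaged meshes the projection error is one to two orders of magnitude
above the slice/voxelization error; on intact meshes all methods agree to a
fraction of a percent.

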