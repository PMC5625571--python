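# hullcarve

Fast, high-resolution **visual-hull reconstruction** of plant shoots (and
other turntable-imaged objects) by **octree volume carving** with
**integral-image occupancy tests**.

## The problem

Indoor phenotyping platforms image a plant rotating on a calibrated
turntable in front of one or more fixed cameras. Each view yields a binary
silhouette mask **M**ᵢ; the *visual hull* is the largest volume consistent
with all silhouettes — the intersection of the back-projected silhouette
cones — and is a useful non-invasive surrogate for shoot volume, biomass
and per-leaf structure. Classic carving tests every voxel **X** of an
equidistant grid against every mask,

&nbsp;&nbsp;&nbsp;&nbsp;V(**X**) = ∏ᵢ **M**ᵢ(**x**ᵢ), &nbsp; **x**ᵢ = **P**ᵢ**X**,
&nbsp; **P**ᵢ = **K**(**R** | **t** + **t₀**) · diag(**R**αᵢ, 1),

which is hopeless at sub-millimeter resolution: a 1 m³ working volume at
0.25 mm needs 6.4·10¹⁰ voxels. `hullcarve` instead refines an **octree**:
a voxel's 8 corners are projected into a view, and the integer bounding box
of the projection is queried against the view's **summed-area table** —
foreground count R and box area A in four lookups, O(1) for any voxel size.
R = A keeps the voxel as *object*, R = 0 carves it (*empty*), anything else
*refines* it into its 8 children (a *partial* surface voxel at the finest
level, counted at half volume in the unbiased hull-volume estimate).

The order in which voxels meet views does not change the result, but it
changes the work by orders of magnitude. All four refinement schedules are
implemented and instrumented (`depth_first`, `breadth_first`,
`refining_resolution`, `mark_and_refine`); `mark_and_refine` — classify
every live voxel against *all* views, then split once per round — generates
the fewest transient voxels and is the default.

Everything is testable without data: `hullcarve.scenes` renders exact
silhouettes of analytic solids (spheres, cylinders, unions) through fully
calibrated virtual turntable rigs, and a dense brute-force carve serves as
an independent oracle for the octree result.

## Worked example

Generate a synthetic 9-view dataset (3 cameras × 4 turntable angles,
top camera at 0° only) of a stylized seedling, then carve it:

```bash
hullcarve synth --out demo --image-size 256 --focal 1100 --distance 0.9
hullcarve carve --calib demo/calibration.json --out demo_out \
                --max-depth 7 --volume-edge 0.32 --volume-center 0,0,0.05
```

prints

```json
{
  "n_views": 9,
  "strategy": "mark_and_refine",
  "max_depth": 7,
  "volume_edge_m": 0.32,
  "finest_voxel_mm": 2.5,
  "n_leaves": 4573,
  "hull_volume_m3": 6.071093750000001e-05,
  "hull_volume_cm3": 60.71093750000001,
  "total_iterations": 81
}
```

The 0.32 m working volume refined 7 times gives 2.5 mm voxels; the carved
hull keeps 4,573 octree leaves whose volumes (surface voxels at half
weight) sum to 60.7 cm³ — slightly above the 53.2 cm³ of the analytic
plant, as a visual hull must be, since it also contains occluded volume.
81 iterations means 81 passes of "project all live voxels onto one image".
`demo_out/` additionally contains the point cloud (`hull.ply`, with a
per-vertex leaf edge length), the per-iteration trace
(`stats_mark_and_refine.csv`; summarize with `hullcarve stats --in demo_out`)
and the volume report (`volume.json`).

Run `hullcarve carve --strategy all ...` to carve with all four schedules
and verify their leaf sets are identical. From Python, see
`hullcarve.carve`, `hullcarve.densify`, `hullcarve.dense_carve_oracle`,
`hullcarve.estimate_volume`, `hullcarve.colorize` and
`hullcarve.label_leaves` (top-down slice-clustering leaf segmentation).

## Scope notes

Camera calibration is consumed (JSON schema in `hullcarve/calib.py`), not
estimated; masks are assumed undistorted. Segmentation is HSV interval
thresholding plus speck removal/hole filling — no trainable segmentation.
See `docs/methods.md` for the model, parameter and design details.
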