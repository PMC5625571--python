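# Methods

## Model and geometry

A turntable rig is modeled as pinhole cameras with intrinsics **K** (zero
skew, positive focals, principal point in the third column) and pose
(**R**, **t**, **t₀**) relative to the rotation center of the table, which
is the world origin. The world frame is right-handed with z up along the
rotation axis and *rotates with the object*: the view at table angle α
projects static object coordinates through
**P** = **K**[**R** | **t** + **t₀**]·diag(**R**α, 1), where **R**α rotates
about z. Positive α turns the object counter-clockwise seen from above;
the sign is a rig parameter (`rotation_sign`) because physical tables
differ. Pixel coordinates are 0-based, x right, y down, integer
coordinates at pixel centers; angles are degrees everywhere; lengths are
meters (reports also print mm and cm³).

## Occupancy test

For a cubic voxel, the 8 corners are projected and the integer pixel box
[floor(min u), ceil(max u)] × [floor(min v), ceil(max v)] is formed, then
clamped to the image. The floor/ceil envelope guarantees the box contains
the true projected hexagon, so the three-way verdict is conservative: the
voxel is *object* only if the box is entirely foreground (R = A), *empty*
only if entirely background (R = 0), otherwise *refine*. R is read from
the view's summed-area table in four lookups with the convention
I(−1,·) = I(·,−1) = 0. Counts are int64 and compared exactly — masks are
binary, so no epsilon is involved. The box area counts pixels inclusively,
(x_max−x_min+1)·(y_max−y_min+1); with any other convention R/A could not
reach 1 on fully-foreground boxes.

Two markers leave the three-way scheme: a box with no overlap with the
image is *empty* when `outside_is_background` (default; the product over
views treats unseen space as background — appropriate when every camera
frames the plant) and *object* otherwise (for rigs whose images do not
cover the working volume); a voxel with any corner at or behind the camera
plane is *refine* (never carve on unreliable geometry), becoming a
retained *partial* leaf at maximum depth.

## Carving and refinement strategies

The octree root covers the working volume and starts as a single live
*object* node. Classification of a (voxel, view) pair is deterministic and
a child's projected box is nested in its parent's, so the surviving leaf
set is a fixpoint independent of scheduling; the four strategies differ
only in transient work:

* **depth_first** — for each image in turn, `max_depth` unconditional
  refinement passes (the bound that guarantees the finest level is reached
  from any state), then one background-removal pass per image at finest
  resolution. For N images this is exactly N·(max_depth+1) iterations.
  Within one image's pass sequence, voxels already classified against that
  image are not re-evaluated (the verdict cannot change); the trace still
  counts `projected` as all live voxels per pass — that is the definition
  of an iteration — and reports actual evaluations separately as
  `classified`. Should a removal pass ever split a node (possible only in
  pathological geometry such as cameras inside the volume), breadth-first
  rounds run to convergence afterwards and are counted honestly.
* **breadth_first** — one pass per image, round-robin, until a full round
  produces zero state changes.
* **refining_resolution** — breadth-first with the depth capped: converge
  at a coarse cap (`coarse_start_depth`, default 2), then raise the cap by
  one level per round over all images; at the final cap, run to
  convergence (needed so the fixpoint is reached and all strategies agree).
  A *refine* verdict at the cap leaves the node live and unsplit.
* **mark_and_refine** — per round, classify every live voxel against all
  views without splitting; a voxel is emptied if any view says empty,
  split if any says refine (none empty), kept if all say object. All
  splits then happen at once. Fewest transient voxels: every level is
  fully carved by every view before deepening. In the trace, the round's
  splits are attributed to its last per-view record.

A *refine* verdict at `max_depth` makes the leaf *partial* (surface
voxel); partials stay live and can still be emptied by later views. Hull
volume = Σ edge³ over object leaves + ½·Σ edge³ over partial leaves; the
half weight is unbiased for a locally flat surface cutting voxels at
uniform offsets. A finest-level voxel that is fully foreground in all
views counts at full volume — only genuinely mixed voxels are halved.

Node storage is flat numpy arrays (centers, depths, states) rebuilt per
pass in amortized-constant chunks; children replace their parent in place
in a fixed octant order (x fastest), and views are processed in input
order, so runs are bit-reproducible. `parallel_workers > 1` distributes
classification chunks over threads (splitting stays serial); chunk results
are concatenated in fixed order, so parallel output is bit-identical to
serial (verified by test).

## Verification oracle

`dense_carve_oracle` classifies every cell of the full 2^depth grid
independently with the identical box test and per-view aggregation — no
octree bookkeeping — and must equal `densify(carve(...))` cell for cell,
including the partial flags. The test suite asserts this equality, and the
bit-identity of all four strategies, on 50 randomized synthetic scenes per
run, plus hull conservativeness (eroded object ⊆ hull) and view
monotonicity on the toy plant.

## Synthetic scenes

Silhouettes are rendered by intersecting the ray through each pixel center
with analytic solids (sphere; solid vertical cylinder; unions), exact up
to half-pixel sampling at the boundary: a pixel whose center ray misses a
shape that covers part of the pixel renders background. Conservative
geometric assertions therefore compare against shapes eroded by roughly
one projected-pixel footprint plus half a voxel diagonal. There is no
anti-aliasing, no lens distortion, no segmentation noise, no calibration
error — passing tests certify the carving machinery, not robustness to
real imaging defects, which on physical rigs is limited mainly by
calibration precision and mask quality.

The default `toy_plant` is a stylized seedling: a stem cylinder (radius
2.5 mm, height 9 cm) carrying three spherical leaf blobs (radius 16 mm)
that touch the stem at distinct heights and azimuths, so a top-down slice
scan sees each leaf separately before it merges — and the carve spans many
octree levels. Seeded jitter (≤0.5 mm lateral, ≤3 mm vertical) varies
repeated runs without changing that structure.

## Problem sizes used

Chosen once as representative desk-scale configurations:

* Strategy/oracle sweeps: 50 random scenes, 4–6 views, 160² images,
  depths 4–6 in a 0.24 m volume.
* Depth-first schedule measurement: the 9-view screening rig (3 cameras at
  20°/55°/90° elevation × angles 0/90/180/270°, top camera once), 512²
  images at f = 4200 px and 1.35 m distance — pixel footprint ≈ 0.32 mm at
  working distance, matching the physical rigs' 0.3–0.4 mm — 1 m³ volume,
  depth 12 (finest voxel 0.244 mm). Runs in ~2–3 minutes, ~2.7 GB peak.
* Sphere volume estimate: r = 0.1 m, 36 views on an 8°-elevation ring,
  900² images at f = 3400 px (again ~0.3 mm footprint), 0.4 m volume,
  depth 8. The estimate must land in [V_true, 1.1·V_true]: the hull
  contains the sphere and the 36-view wedge slack plus half-weighted shell
  stay below 10%. Pixel footprint matters here: with markedly coarser
  pixels, half-pixel silhouette sampling biases the hull inward by more
  than the wedge slack.
* Leaf labeling: the 60-image two-camera turntable configuration typical
  of maize screening, depth 8 (1.25 mm voxels), where the hull is tight
  enough to preserve the plant's component structure.

## Leaf labeling

`label_leaves` scans horizontal one-voxel slices from top to bottom;
clusters (8-connectivity in-slice, configurable) inherit the label of
overlapping clusters in the slice above via their vertical footprints, a
cluster with no overlap starts a new label, and on merges the smaller
(older) label is transferred. Labels are contiguous 1..L in creation
order, so the top-most structure carries label 1 and the stem region ends
up with the label of the top-most leaf. Stem/leaf separation, leaf length
via skeletonization and leaf-area flattening are deliberately out of
scope; reported leaf counts carry the stem-merge caveat.

## Known limitations

* The visual hull is a superset of the object; occluded and concave
  volume is included (for the toy plant, ~5–10% excess).
* `breadth_first` without a depth cap explodes exponentially; the cap is
  mandatory (`max_depth` is always enforced).
* Colorization picks the nearest camera's pixel at the projected box
  center with no visibility test — a visualization aid only.
* HSV segmentation thresholds and speck/hole sizes are rig-dependent and
  exposed as parameters with neutral defaults (no cleaning unless asked).
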