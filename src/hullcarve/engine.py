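"""Octree volume carving with integral-image occupancy tests.

The carver maintains a set of live octree leaves (center, depth, state) over
a cubic working volume.  Each leaf is classified against a view by
projecting its 8 corners, taking the clamped integer bounding box of the
projection and reading the foreground count R and area A of that box from
the view's integral image:

* ``R == A``  -> the leaf projects to pure foreground: *object*,
* ``R == 0``  -> pure background: *empty* (the leaf is carved away),
* otherwise   -> mixed: *refine* (split into 8 children, or kept as a
  half-weighted *partial* surface leaf at maximum depth).

Classification of a given (leaf, view) pair is deterministic, and a child's
projected box is contained in its parent's, so the final leaf set is a
fixpoint independent of the order in which leaves meet views.  The four
refinement *strategies* only schedule that order and differ (enormously) in
how many transient leaves they generate:

``depth_first``
    Refine fully against view 1, then view 2, ...; each image is visited
    for ``max_depth`` refinement passes plus one final background-removal
    pass at finest resolution.  Simple but generates the most voxels.
``breadth_first``
    One pass per image, round-robin over images, until a full round changes
    nothing.
``refining_resolution``
    Breadth-first with the octree depth capped: converge at a coarse cap,
    then raise the cap one level per round; converge at the final cap.
``mark_and_refine``
    Per round, classify every live leaf against *all* views without
    splitting, combine the verdicts (empty in any view wins, else refine in
    any view), then split all refine leaves at once.  Generates the fewest
    voxels: each level is fully carved by every view before deepening.

"One iteration" throughout means projecting all current live leaves onto
one image once; :class:`CarveStats` records exactly this.
"""

from __future__ import annotations

import csv
import json
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera import (
    BboxStatus,
    OCTANT_OFFSETS,
    Voxel,
    camera_center,
    project_voxel_bboxes,
)
from .silhouettes import IntegralImage, box_sums, integral_image

__all__ = [
    "CameraView",
    "CarveConfig",
    "CarveStats",
    "DenseGrid",
    "IterationRecord",
    "NodeState",
    "Octree",
    "OctreeNode",
    "RgbView",
    "STRATEGIES",
    "carve",
    "classify_node",
    "colorize",
    "dense_carve_oracle",
    "dense_voxel_count",
    "densify",
    "estimate_volume",
    "leaf_edge",
    "load_dense_grid",
    "save_dense_grid",
]

STRATEGIES = ("depth_first", "breadth_first", "refining_resolution", "mark_and_refine")

_CHUNK = 1 << 20  # leaves classified per chunk; bounds transient memory


class NodeState:
    """Occupancy states of octree nodes (kept as plain ints for array use)."""

    EMPTY = 0
    OBJECT = 1
    REFINE = 2
    PARTIAL = 3  # mixed at maximum depth: surface voxel, half volume


@dataclass(eq=False)
class CameraView:
    """One calibrated silhouette: binary mask, projection matrix, integral image."""

    mask: np.ndarray
    P: np.ndarray
    integral: IntegralImage | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2D array")
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (3, 4):
            raise ValueError("P must be 3x4")
        if self.integral is None:
            self.integral = integral_image(self.mask)

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]


@dataclass(eq=False)
class RgbView:
    """An RGB image with its projection matrix, for voxel colorization."""

    image: np.ndarray
    P: np.ndarray

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] < 3:
            raise ValueError("image must be (H, W, 3)")
        self.P = np.asarray(self.P, dtype=float)

    @property
    def center(self) -> np.ndarray:
        return camera_center(self.P)


@dataclass
class CarveConfig:
    """Working-volume geometry and carving schedule.

    Parameters
    ----------
    root_center, root_edge
        Center (meters) and edge length (meters) of the cubic working
        volume, i.e. the octree root.
    max_depth
        Subdivision depth; finest leaf edge is ``root_edge / 2**max_depth``.
    strategy
        One of :data:`STRATEGIES`.
    outside_is_background
        If true (default) a leaf projecting entirely outside an image is
        carved, consistent with treating every view's product term as
        background there; set false for rigs whose images do not cover the
        working volume.
    parallel_workers
        Threads used for the (embarrassingly parallel) classification step;
        splitting stays serial and results are bit-identical to serial runs.
    coarse_start_depth
        Initial depth cap of the refining-resolution strategy.
    """

    root_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    root_edge: float = 1.0
    max_depth: int = 8
    strategy: str = "mark_and_refine"
    outside_is_background: bool = True
    parallel_workers: int = 1
    coarse_start_depth: int = 2

    def __post_init__(self) -> None:
        self.root_center = np.asarray(self.root_center, dtype=float).reshape(3)
        if self.root_edge <= 0:
            raise ValueError("root_edge must be positive")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if self.parallel_workers < 1:
            raise ValueError("parallel_workers must be >= 1")


@dataclass
class IterationRecord:
    """Trace of one iteration (= one projection pass of all live leaves onto one image)."""

    iteration: int
    image: int
    live_nodes: int
    projected: int  # == live_nodes by definition of an iteration
    classified: int  # classifications actually evaluated (memoization may skip)
    split: int
    emptied: int


@dataclass
class CarveStats:
    """Per-iteration instrumentation of a carving run."""

    records: list[IterationRecord] = field(default_factory=list)

    @property
    def total_iterations(self) -> int:
        return len(self.records)

    @property
    def total_projected(self) -> int:
        return sum(r.projected for r in self.records)

    @property
    def total_classified(self) -> int:
        return sum(r.classified for r in self.records)

    def live_per_iteration(self) -> np.ndarray:
        return np.array([r.live_nodes for r in self.records], dtype=np.int64)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "image", "live_nodes", "projected", "classified", "split", "emptied"])
            for r in self.records:
                w.writerow([r.iteration, r.image, r.live_nodes, r.projected, r.classified, r.split, r.emptied])


@dataclass
class OctreeNode:
    """Materialized tree node; children (0 or 8) tile the parent exactly."""

    center: np.ndarray
    depth: int
    state: int
    children: list["OctreeNode"] = field(default_factory=list)


@dataclass(eq=False)
class Octree:
    """Carved octree, stored as its leaf set (internal nodes carry no occupancy)."""

    root_center: np.ndarray
    root_edge: float
    max_depth: int
    leaf_centers: np.ndarray  # (n, 3) float64
    leaf_depths: np.ndarray  # (n,) int
    leaf_states: np.ndarray  # (n,) uint8, OBJECT or PARTIAL

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_depths)

    def leaf_edges(self) -> np.ndarray:
        return self.root_edge / np.exp2(self.leaf_depths.astype(float))

    def sorted_leaves(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Leaves in canonical (lexicographic) order, for comparisons."""
        if self.n_leaves == 0:
            return self.leaf_centers, self.leaf_depths, self.leaf_states
        order = np.lexsort(
            (self.leaf_states, self.leaf_centers[:, 0], self.leaf_centers[:, 1], self.leaf_centers[:, 2], self.leaf_depths)
        )
        return self.leaf_centers[order], self.leaf_depths[order], self.leaf_states[order]

    def node_tree(self) -> OctreeNode:
        """Materialize the explicit node hierarchy from the leaf set."""
        root = OctreeNode(self.root_center.copy(), 0, NodeState.EMPTY)
        if self.n_leaves == 0:
            return root
        origin = self.root_center - self.root_edge / 2.0
        for center, depth, state in zip(self.leaf_centers, self.leaf_depths, self.leaf_states):
            node = root
            for d in range(1, int(depth) + 1):
                edge = self.root_edge / 2.0**d
                octant = ((center - origin) // edge).astype(int) % 2
                idx = int(octant[0] + 2 * octant[1] + 4 * octant[2])
                if not node.children:
                    for off in OCTANT_OFFSETS:
                        child_edge = self.root_edge / 2.0 ** (node.depth)
                        node.children.append(
                            OctreeNode(node.center + off * child_edge, node.depth + 1, NodeState.EMPTY)
                        )
                node = node.children[idx]
            node.state = int(state)
        return root


@dataclass(eq=False)
class DenseGrid:
    """Equidistant occupancy grid, indexed ``[ix, iy, iz]`` with z vertical.

    ``occupancy`` is 1 wherever the visual hull is present; ``partial``
    additionally flags mixed (surface) cells.
    """

    occupancy: np.ndarray
    partial: np.ndarray
    origin: np.ndarray  # min corner, meters
    voxel_edge: float

    @property
    def shape(self) -> tuple[int, ...]:
        return self.occupancy.shape

    def cell_centers(self, where: np.ndarray | None = None) -> np.ndarray:
        idx = np.argwhere(self.occupancy > 0 if where is None else where)
        return self.origin + (idx + 0.5) * self.voxel_edge


def leaf_edge(root_edge: float, depth: int) -> float:
    """Edge length (meters) of a leaf after ``depth`` subdivisions."""
    if root_edge <= 0 or depth < 0:
        raise ValueError("root_edge must be > 0 and depth >= 0")
    return root_edge / 2.0**depth


def dense_voxel_count(volume_edge: float, voxel_edge: float) -> int:
    """Number of cells an equidistant grid needs for the same volume."""
    if volume_edge <= 0 or voxel_edge <= 0:
        raise ValueError("edges must be positive")
    return round(volume_edge / voxel_edge) ** 3


# ---------------------------------------------------------------------------
# classification


def _classify_arrays(
    centers: np.ndarray,
    edges: np.ndarray,
    view: CameraView,
    outside_is_background: bool,
    workers: int = 1,
) -> np.ndarray:
    """Three-way verdicts (OBJECT / EMPTY / REFINE) for a batch of leaves."""
    n = len(centers)
    if n == 0:
        return np.empty(0, dtype=np.uint8)

    def run(sl: slice) -> np.ndarray:
        status, boxes = project_voxel_bboxes(view.P, centers[sl], edges[sl], view.width, view.height)
        out = np.empty(len(status), dtype=np.uint8)
        vis = status == BboxStatus.VISIBLE
        if vis.any():
            b = boxes[vis]
            r, a = box_sums(view.integral, b[:, 0], b[:, 1], b[:, 2], b[:, 3])
            out[vis] = np.where(r == a, NodeState.OBJECT, np.where(r == 0, NodeState.EMPTY, NodeState.REFINE))
        out[status == BboxStatus.OUT_OF_VIEW] = (
            NodeState.EMPTY if outside_is_background else NodeState.OBJECT
        )
        out[status == BboxStatus.BEHIND] = NodeState.REFINE  # never carve on unreliable geometry
        return out

    slices = [slice(i, min(i + _CHUNK, n)) for i in range(0, n, _CHUNK)]
    if workers > 1 and len(slices) > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            parts = list(pool.map(run, slices))
    else:
        parts = [run(sl) for sl in slices]
    return parts[0] if len(parts) == 1 else np.concatenate(parts)


def classify_node(
    voxel: Voxel, view: CameraView, outside_is_background: bool = True
) -> int:
    """Classify a single live voxel against one view (Eq.-8-style three-way test)."""
    v = _classify_arrays(
        voxel.center[None, :], np.array([voxel.edge]), view, outside_is_background
    )
    return int(v[0])


# ---------------------------------------------------------------------------
# the carver


@dataclass
class _PassResult:
    changed: int
    n_split: int
    n_empty: int
    new_eval: np.ndarray  # boolean over the *new* leaf arrays


class _Carver:
    def __init__(self, views: list[CameraView], config: CarveConfig):
        if not views:
            raise ValueError("at least one view is required")
        for i, v in enumerate(views):
            if v.mask.shape != views[0].mask.shape:
                pass  # views may have different sizes; each carries its own dims
        self.views = views
        self.cfg = config
        self.centers = config.root_center[None, :].astype(float).copy()
        self.depths = np.zeros(1, dtype=np.int64)
        self.states = np.full(1, NodeState.OBJECT, dtype=np.uint8)
        self.stats = CarveStats()
        self._iter = 0

    # -- helpers ----------------------------------------------------------

    @property
    def n_live(self) -> int:
        return len(self.depths)

    def edges(self, idx: np.ndarray | slice = slice(None)) -> np.ndarray:
        return self.cfg.root_edge / np.exp2(self.depths[idx].astype(float))

    def _record(self, image: int, live: int, classified: int, split: int, emptied: int) -> None:
        self._iter += 1
        self.stats.records.append(
            IterationRecord(self._iter, image, live, live, classified, split, emptied)
        )

    def _rebuild(self, keep_split: np.ndarray, remove: np.ndarray) -> np.ndarray:
        """Drop removed leaves and replace split leaves by their 8 children.

        Children are emitted in place of their parent, in the fixed octant
        order, so traversal stays deterministic.  Returns a boolean array
        over the new leaves marking freshly created children.
        """
        counts = np.where(remove, 0, np.where(keep_split, 8, 1))
        idx = np.repeat(np.arange(self.n_live), counts)
        starts = np.cumsum(counts) - counts
        rank = np.arange(len(idx)) - np.repeat(starts, counts)
        is_child = keep_split[idx]
        parent_edges = self.edges(idx)
        new_centers = self.centers[idx] + np.where(
            is_child[:, None], OCTANT_OFFSETS[rank] * parent_edges[:, None], 0.0
        )
        new_depths = self.depths[idx] + is_child
        new_states = np.where(is_child, NodeState.OBJECT, self.states[idx]).astype(np.uint8)
        self.centers, self.depths, self.states = new_centers, new_depths, new_states
        return is_child

    # -- one projection pass ----------------------------------------------

    def do_pass(
        self,
        view_index: int,
        depth_cap: int | None = None,
        eval_mask: np.ndarray | None = None,
    ) -> _PassResult:
        """Project all live leaves onto one image; carve, split, mark.

        ``eval_mask`` restricts which leaves are actually (re)classified
        (memoization within a depth-first image phase); skipped leaves keep
        their verdict by determinism of the test.  The iteration is recorded
        with ``projected`` equal to the full live count regardless.
        """
        n = self.n_live
        cap = self.cfg.max_depth if depth_cap is None else min(depth_cap, self.cfg.max_depth)
        if n == 0:
            self._record(view_index, 0, 0, 0, 0)
            return _PassResult(0, 0, 0, np.zeros(0, dtype=bool))

        if eval_mask is None:
            eval_mask = np.ones(n, dtype=bool)
        ev = np.flatnonzero(eval_mask)
        verdict = np.full(n, NodeState.OBJECT, dtype=np.uint8)
        verdict[ev] = _classify_arrays(
            self.centers[ev],
            self.edges(ev),
            self.views[view_index],
            self.cfg.outside_is_background,
            self.cfg.parallel_workers,
        )

        remove = verdict == NodeState.EMPTY
        refine = verdict == NodeState.REFINE
        split = refine & (self.depths < cap)
        to_partial = refine & ~split & (self.depths >= self.cfg.max_depth)
        newly_partial = to_partial & (self.states == NodeState.OBJECT)

        changed = int(remove.sum() + split.sum() + newly_partial.sum())
        n_split = int(split.sum())
        n_empty = int(remove.sum())
        self.states[newly_partial] = NodeState.PARTIAL
        self._record(view_index, n, len(ev), n_split, n_empty)

        if n_split or n_empty:
            new_eval = self._rebuild(split, remove)
        else:
            new_eval = np.zeros(n, dtype=bool)
        return _PassResult(changed, n_split, n_empty, new_eval)

    # -- strategies --------------------------------------------------------

    def run_breadth_first(self, depth_cap: int | None = None) -> None:
        while True:
            changed = 0
            for vi in range(len(self.views)):
                changed += self.do_pass(vi, depth_cap=depth_cap).changed
            if changed == 0 or self.n_live == 0:
                break

    def run_refining_resolution(self) -> None:
        cap = min(self.cfg.coarse_start_depth, self.cfg.max_depth)
        self.run_breadth_first(depth_cap=cap)
        while cap < self.cfg.max_depth and self.n_live:
            cap += 1
            for vi in range(len(self.views)):
                self.do_pass(vi, depth_cap=cap)
        if self.n_live:
            self.run_breadth_first(depth_cap=self.cfg.max_depth)

    def run_depth_first(self) -> None:
        # Per image: max_depth unconditional refinement passes (the schedule
        # bound that guarantees the finest resolution is reached), with
        # within-image memoization of already-settled leaves.  Then one
        # removal pass per image at finest resolution.
        for vi in range(len(self.views)):
            eval_mask: np.ndarray | None = None  # first pass evaluates everything
            for _ in range(self.cfg.max_depth):
                if self.n_live == 0:
                    break
                res = self.do_pass(vi, eval_mask=eval_mask)
                eval_mask = res.new_eval
            if self.n_live == 0:
                break
        stray_splits = 0
        for vi in range(len(self.views)):
            stray_splits += self.do_pass(vi).n_split
        if stray_splits:  # pathological geometry (e.g. cameras inside the volume)
            self.run_breadth_first()

    def run_mark_and_refine(self) -> None:
        while self.n_live:
            n = self.n_live
            edges = self.edges()
            empty_any = np.zeros(n, dtype=bool)
            refine_any = np.zeros(n, dtype=bool)
            for vi, view in enumerate(self.views):
                v = _classify_arrays(
                    self.centers, edges, view, self.cfg.outside_is_background, self.cfg.parallel_workers
                )
                newly_empty = (v == NodeState.EMPTY) & ~empty_any
                empty_any |= v == NodeState.EMPTY
                refine_any |= v == NodeState.REFINE
                self._record(vi, n, n, 0, int(newly_empty.sum()))

            refine = refine_any & ~empty_any
            split = refine & (self.depths < self.cfg.max_depth)
            to_partial = refine & ~split
            newly_partial = to_partial & (self.states == NodeState.OBJECT)
            changed = int(empty_any.sum() + split.sum() + newly_partial.sum())
            self.states[newly_partial] = NodeState.PARTIAL
            # splits happen after the whole marking round; attribute them to
            # the round's last record
            self.stats.records[-1].split = int(split.sum())
            if split.any() or empty_any.any():
                self._rebuild(split, empty_any)
            if changed == 0:
                break

    def run(self) -> None:
        {
            "depth_first": self.run_depth_first,
            "breadth_first": self.run_breadth_first,
            "refining_resolution": self.run_refining_resolution,
            "mark_and_refine": self.run_mark_and_refine,
        }[self.cfg.strategy]()

    def result(self) -> Octree:
        return Octree(
            root_center=self.cfg.root_center.copy(),
            root_edge=self.cfg.root_edge,
            max_depth=self.cfg.max_depth,
            leaf_centers=self.centers,
            leaf_depths=self.depths,
            leaf_states=self.states,
        )


def carve(views: list[CameraView], config: CarveConfig) -> tuple[Octree, CarveStats]:
    """Carve the visual hull of the silhouettes into an octree.

    Returns the carved tree (leaves are OBJECT, fully foreground in every
    view, or PARTIAL, mixed surface voxels at maximum depth) and the full
    per-iteration instrumentation trace.
    """
    carver = _Carver(views, config)
    carver.run()
    return carver.result(), carver.stats


# ---------------------------------------------------------------------------
# downstream computations


def estimate_volume(tree: Octree) -> float:
    """Visual-hull volume in cubic meters.

    Sums full leaf volumes over OBJECT leaves; PARTIAL (surface) leaves at
    finest resolution have unknown filling and are counted at half volume,
    which makes the estimate unbiased for a locally flat surface.
    """
    e3 = tree.leaf_edges() ** 3
    obj = tree.leaf_states == NodeState.OBJECT
    part = tree.leaf_states == NodeState.PARTIAL
    return float(e3[obj].sum() + 0.5 * e3[part].sum())


def densify(tree: Octree, depth: int, cell_budget: int = 2**24) -> DenseGrid:
    """Stamp the octree leaves into an equidistant grid at ``2**depth`` per axis."""
    if depth > tree.max_depth:
        raise ValueError("densify depth exceeds the tree's max_depth")
    if tree.n_leaves and int(tree.leaf_depths.max()) > depth:
        raise ValueError("tree has leaves finer than the requested grid")
    n = 2**depth
    if n**3 > cell_budget:
        raise ValueError(f"grid {n}^3 exceeds the cell budget {cell_budget}")
    occ = np.zeros((n, n, n), dtype=np.uint8)
    part = np.zeros((n, n, n), dtype=bool)
    origin = tree.root_center - tree.root_edge / 2.0
    cell = tree.root_edge / n
    for d in np.unique(tree.leaf_depths):
        sel = tree.leaf_depths == d
        span = 2 ** (depth - int(d))
        edge_d = tree.root_edge / 2.0 ** int(d)
        k = np.floor((tree.leaf_centers[sel] - origin) / edge_d + 1e-9).astype(np.int64)
        starts = k * span
        is_part = tree.leaf_states[sel] == NodeState.PARTIAL
        if span == 1:
            occ[starts[:, 0], starts[:, 1], starts[:, 2]] = 1
            part[starts[:, 0], starts[:, 1], starts[:, 2]] = is_part
        else:
            for (x, y, z), p in zip(starts, is_part):
                occ[x : x + span, y : y + span, z : z + span] = 1
                part[x : x + span, y : y + span, z : z + span] = p
    return DenseGrid(occ, part, origin, cell)


def dense_carve_oracle(
    views: list[CameraView], depth: int, config: CarveConfig, cell_budget: int = 2**21
) -> DenseGrid:
    """Carve by exhaustively classifying every finest-resolution voxel.

    Applies the identical bounding-box/integral-image test to each cell of
    the full ``2**depth`` grid independently of any octree bookkeeping; used
    to certify octree results on small problems (default budget 2^21 cells,
    i.e. depth <= 7).
    """
    n = 2**depth
    if n**3 > cell_budget:
        raise ValueError(f"oracle grid {n}^3 exceeds the cell budget {cell_budget}")
    origin = config.root_center - config.root_edge / 2.0
    cell = config.root_edge / n
    idx = np.stack(np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij"), axis=-1)
    centers = origin + (idx.reshape(-1, 3) + 0.5) * cell
    edges = np.full(len(centers), cell)
    empty_any = np.zeros(len(centers), dtype=bool)
    refine_any = np.zeros(len(centers), dtype=bool)
    for view in views:
        v = _classify_arrays(centers, edges, view, config.outside_is_background, config.parallel_workers)
        empty_any |= v == NodeState.EMPTY
        refine_any |= v == NodeState.REFINE
    occ = (~empty_any).reshape(n, n, n).astype(np.uint8)
    part = (refine_any & ~empty_any).reshape(n, n, n)
    return DenseGrid(occ, part, origin, cell)


def colorize(
    tree: Octree,
    rgb_views: list[RgbView],
    default_color: tuple[int, int, int] = (128, 128, 128),
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each retained leaf the RGB of its projected box center.

    Each leaf is colored from the view whose camera center is nearest to the
    voxel center (Euclidean); leaves out of view fall back to the
    next-nearest camera and finally to ``default_color``.  This is a
    visualization aid, not a radiometric measurement: no visibility test is
    performed.

    Returns ``(points (n, 3) float, colors (n, 3) uint8)``.
    """
    n = tree.n_leaves
    points = tree.leaf_centers
    colors = np.tile(np.asarray(default_color, dtype=np.uint8), (n, 1))
    if n == 0 or not rgb_views:
        return points, colors
    cam_centers = np.stack([v.center for v in rgb_views])
    d = np.linalg.norm(points[:, None, :] - cam_centers[None, :, :], axis=2)
    order = np.argsort(d, axis=1, kind="stable")
    edges = tree.leaf_edges()
    uncolored = np.ones(n, dtype=bool)
    for rank in range(len(rgb_views)):
        if not uncolored.any():
            break
        for vi, view in enumerate(rgb_views):
            sel = np.flatnonzero(uncolored & (order[:, rank] == vi))
            if len(sel) == 0:
                continue
            h, w = view.image.shape[:2]
            status, boxes = project_voxel_bboxes(view.P, points[sel], edges[sel], w, h)
            vis = status == BboxStatus.VISIBLE
            if not vis.any():
                continue
            b = boxes[vis]
            px = np.rint((b[:, 0] + b[:, 2]) / 2.0).astype(np.int64)
            py = np.rint((b[:, 1] + b[:, 3]) / 2.0).astype(np.int64)
            hit = sel[vis]
            colors[hit] = view.image[py, px, :3]
            uncolored[hit] = False
    return points, colors


# ---------------------------------------------------------------------------
# dense-grid persistence (flat binary + JSON sidecar)


def save_dense_grid(prefix: str | Path, grid: DenseGrid) -> tuple[Path, Path]:
    """Write ``<prefix>.bin`` (occupancy bytes, C order; 2 marks partial cells)
    and ``<prefix>.json`` (dimensions, voxel edge, origin)."""
    prefix = Path(prefix)
    data = grid.occupancy.astype(np.uint8).copy()
    data[grid.partial] = 2
    bin_path = prefix.with_suffix(".bin")
    json_path = prefix.with_suffix(".json")
    data.tofile(bin_path)
    json_path.write_text(
        json.dumps(
            {
                "shape": list(grid.shape),
                "voxel_edge_m": grid.voxel_edge,
                "origin_m": list(map(float, grid.origin)),
                "dtype": "uint8",
                "order": "C",
                "encoding": {"0": "empty", "1": "object", "2": "partial"},
            },
            indent=2,
        )
    )
    return bin_path, json_path


def load_dense_grid(prefix: str | Path) -> DenseGrid:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.fromfile(prefix.with_suffix(".bin"), dtype=np.uint8).reshape(meta["shape"])
    return DenseGrid(
        occupancy=(data > 0).astype(np.uint8),
        partial=data == 2,
        origin=np.asarray(meta["origin_m"], dtype=float),
        voxel_edge=float(meta["voxel_edge_m"]),
    )
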