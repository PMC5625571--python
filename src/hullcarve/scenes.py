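"""Synthetic turntable scenes: analytic solids, virtual rigs, exact silhouettes.

Every other module is testable without any external data: a scene is a
union of analytic solids (spheres and vertical cylinders) with exact
point-membership and ray-intersection tests, and a virtual rig places
calibrated pinhole cameras on a circle around the turntable axis.
Silhouettes are rendered by shooting one ray through each *pixel center*
and asking whether it hits the solid -- exact up to half-pixel sampling at
the silhouette boundary, with no rasterization approximation.  Conservative
geometric tests therefore compare against shapes eroded by about one
projected-pixel footprint.

The default test scene (:func:`toy_plant`) is a stylized seedling: a thin
vertical stem cylinder carrying a few spherical leaf blobs, sized so that a
carve spans many octree levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .camera import (
    CameraExtrinsics,
    CameraIntrinsics,
    build_projection,
    camera_center,
    look_at_rotation,
    rotation_about_vertical,
)
from .silhouettes import write_mask

__all__ = [
    "SceneShape",
    "ShapeUnion",
    "Sphere",
    "TurntableRig",
    "VerticalCylinder",
    "make_camera",
    "make_rig",
    "phenotyping_rig",
    "render_rgb",
    "render_silhouette",
    "scene_from_json",
    "scene_to_json",
    "toy_plant",
    "write_dataset",
]

_EPS = 1e-12


class SceneShape:
    """Analytic solid with exact membership and ray tests."""

    def contains(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def ray_first(self, origin: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """Smallest ray parameter ``s > 0`` hitting the solid (inf if none)."""
        raise NotImplementedError

    def ray_hits(self, origin: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        return np.isfinite(self.ray_first(origin, dirs))

    def rotated_z(self, angle_deg: float, sign: float = 1.0) -> "SceneShape":
        """The shape rotated about the vertical axis through the origin."""
        raise NotImplementedError

    def eroded(self, margin: float) -> "SceneShape":
        """The shape shrunk inward by ``margin`` (for conservative tests)."""
        raise NotImplementedError


def _interval_first(s_lo: np.ndarray, s_hi: np.ndarray) -> np.ndarray:
    """First positive s of the interval [s_lo, s_hi]; inf where empty/negative."""
    lo = np.maximum(s_lo, 0.0)
    hit = (s_hi >= lo) & np.isfinite(s_lo)
    return np.where(hit, np.where(s_lo > 0, s_lo, lo), np.inf)


@dataclass(frozen=True)
class Sphere(SceneShape):
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))

    def contains(self, points: np.ndarray) -> np.ndarray:
        d2 = ((np.atleast_2d(points) - self.center) ** 2).sum(axis=1)
        return d2 <= self.radius**2

    def ray_first(self, origin: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        dirs = np.atleast_2d(dirs)
        oc = np.asarray(origin, dtype=float) - self.center
        a = (dirs**2).sum(axis=1)
        b = 2.0 * dirs @ oc
        c = oc @ oc - self.radius**2
        disc = b**2 - 4 * a * c
        sq = np.sqrt(np.maximum(disc, 0.0))
        s_lo = (-b - sq) / (2 * a)
        s_hi = (-b + sq) / (2 * a)
        s_lo = np.where(disc >= 0, s_lo, np.inf)
        s_hi = np.where(disc >= 0, s_hi, -np.inf)
        return _interval_first(s_lo, s_hi)

    def rotated_z(self, angle_deg: float, sign: float = 1.0) -> "Sphere":
        R = rotation_about_vertical(angle_deg, sign)
        return Sphere(R @ self.center, self.radius)

    def eroded(self, margin: float) -> "Sphere":
        r = self.radius - margin
        return Sphere(self.center, max(r, _EPS))


@dataclass(frozen=True)
class VerticalCylinder(SceneShape):
    """Solid cylinder with vertical axis: base center, radius, height (upward)."""

    base: np.ndarray
    radius: float
    height: float

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("cylinder radius and height must be positive")
        object.__setattr__(self, "base", np.asarray(self.base, dtype=float).reshape(3))

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        radial = ((p[:, :2] - self.base[:2]) ** 2).sum(axis=1) <= self.radius**2
        z = p[:, 2]
        return radial & (z >= self.base[2]) & (z <= self.base[2] + self.height)

    def ray_first(self, origin: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        dirs = np.atleast_2d(dirs).astype(float)
        o = np.asarray(origin, dtype=float)
        oc = o[:2] - self.base[:2]
        a = (dirs[:, :2] ** 2).sum(axis=1)
        b = 2.0 * dirs[:, :2] @ oc
        c = oc @ oc - self.radius**2
        # radial constraint interval
        with np.errstate(divide="ignore", invalid="ignore"):
            disc = b**2 - 4 * a * c
            sq = np.sqrt(np.maximum(disc, 0.0))
            r_lo = np.where(a > _EPS, (-b - sq) / (2 * a), -np.inf)
            r_hi = np.where(a > _EPS, (-b + sq) / (2 * a), np.inf)
        # a ~ 0: ray parallel to the axis -- inside or outside for all s
        par_inside = (a <= _EPS) & (c <= 0)
        r_lo = np.where(a <= _EPS, np.where(par_inside, -np.inf, np.inf), r_lo)
        r_hi = np.where(a <= _EPS, np.where(par_inside, np.inf, -np.inf), r_hi)
        miss = (a > _EPS) & (disc < 0)
        r_lo = np.where(miss, np.inf, r_lo)
        r_hi = np.where(miss, -np.inf, r_hi)
        # z-slab interval
        dz = dirs[:, 2]
        z0, z1 = self.base[2], self.base[2] + self.height
        with np.errstate(divide="ignore", invalid="ignore"):
            s1 = (z0 - o[2]) / dz
            s2 = (z1 - o[2]) / dz
        z_lo = np.minimum(s1, s2)
        z_hi = np.maximum(s1, s2)
        flat = np.abs(dz) <= _EPS
        in_slab = flat & (o[2] >= z0) & (o[2] <= z1)
        z_lo = np.where(flat, np.where(in_slab, -np.inf, np.inf), z_lo)
        z_hi = np.where(flat, np.where(in_slab, np.inf, -np.inf), z_hi)
        return _interval_first(np.maximum(r_lo, z_lo), np.minimum(r_hi, z_hi))

    def rotated_z(self, angle_deg: float, sign: float = 1.0) -> "VerticalCylinder":
        R = rotation_about_vertical(angle_deg, sign)
        return VerticalCylinder(R @ self.base, self.radius, self.height)

    def eroded(self, margin: float) -> "VerticalCylinder":
        return VerticalCylinder(
            self.base + np.array([0.0, 0.0, margin]),
            max(self.radius - margin, _EPS),
            max(self.height - 2 * margin, _EPS),
        )


@dataclass(frozen=True)
class ShapeUnion(SceneShape):
    shapes: tuple[SceneShape, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "shapes", tuple(self.shapes))

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        out = np.zeros(len(p), dtype=bool)
        for s in self.shapes:
            out |= s.contains(p)
        return out

    def ray_first(self, origin: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        dirs = np.atleast_2d(dirs)
        out = np.full(len(dirs), np.inf)
        for s in self.shapes:
            out = np.minimum(out, s.ray_first(origin, dirs))
        return out

    def rotated_z(self, angle_deg: float, sign: float = 1.0) -> "ShapeUnion":
        return ShapeUnion(tuple(s.rotated_z(angle_deg, sign) for s in self.shapes))

    def eroded(self, margin: float) -> "ShapeUnion":
        return ShapeUnion(tuple(s.eroded(margin) for s in self.shapes))


# ---------------------------------------------------------------------------
# rigs


@dataclass
class TurntableRig:
    """Calibrated cameras plus the list of (camera, table angle) views."""

    cameras: list[tuple[CameraIntrinsics, CameraExtrinsics]]
    views: list[tuple[int, float]]  # (camera index, angle in degrees)
    rotation_sign: float = 1.0

    @property
    def n_views(self) -> int:
        return len(self.views)

    def projection(self, view_index: int) -> np.ndarray:
        ci, angle = self.views[view_index]
        intr, extr = self.cameras[ci]
        return build_projection(intr, extr, angle, rotation_sign=self.rotation_sign)

    def projections(self) -> list[np.ndarray]:
        return [self.projection(i) for i in range(self.n_views)]

    def image_size(self, view_index: int) -> tuple[int, int]:
        intr, _ = self.cameras[self.views[view_index][0]]
        return intr.width, intr.height


def make_camera(
    position: np.ndarray,
    target: np.ndarray,
    focal_px: float,
    width: int,
    height: int,
) -> tuple[CameraIntrinsics, CameraExtrinsics]:
    """Pinhole camera at ``position`` looking at ``target`` (principal point centered)."""
    K = np.array(
        [[focal_px, 0.0, (width - 1) / 2.0], [0.0, focal_px, (height - 1) / 2.0], [0.0, 0.0, 1.0]]
    )
    R = look_at_rotation(position, target)
    t = -R @ np.asarray(position, dtype=float)
    return CameraIntrinsics(K, width, height), CameraExtrinsics(R, t)


def make_rig(
    n_cameras: int = 1,
    n_angles: int = 4,
    focal_px: float = 400.0,
    width: int = 256,
    height: int = 256,
    camera_distance: float = 1.0,
    elevations_deg: list[float] | None = None,
    target: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
    single_view_cameras: tuple[int, ...] = (),
) -> TurntableRig:
    """Place ``n_cameras`` on a vertical arc and image at equidistant table angles.

    Cameras sit in the x = 0 half-plane at the given elevation angles above
    the horizon (defaults spread between 15 deg and 75 deg), all at
    ``camera_distance`` from ``target`` and looking at it.  Angles are
    equidistant over 360 deg starting at 0.  Cameras listed in
    ``single_view_cameras`` contribute only the 0-degree view (the usual
    role of a top camera, whose view is rotation-invariant).
    """
    if n_cameras < 1 or n_angles < 1:
        raise ValueError("need at least one camera and one angle")
    if camera_distance <= 0:
        raise ValueError("camera distance must be positive")
    target = np.asarray(target, dtype=float).reshape(3)
    if elevations_deg is None:
        elevations_deg = list(np.linspace(15.0, 75.0, n_cameras))
    if len(elevations_deg) != n_cameras:
        raise ValueError("one elevation per camera required")
    cameras = []
    for elev in elevations_deg:
        e = np.deg2rad(elev)
        pos = target + camera_distance * np.array([0.0, -np.cos(e), np.sin(e)])
        cameras.append(make_camera(pos, target, focal_px, width, height))
    angles = [360.0 * i / n_angles for i in range(n_angles)]
    views: list[tuple[int, float]] = []
    for ci in range(n_cameras):
        if ci in single_view_cameras:
            views.append((ci, 0.0))
        else:
            views.extend((ci, a) for a in angles)
    return TurntableRig(cameras, views)


def phenotyping_rig(
    focal_px: float = 400.0,
    width: int = 256,
    height: int = 256,
    camera_distance: float = 1.0,
    target: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.05),
) -> TurntableRig:
    """The standard screening layout: 3 cameras x 4 angles (0/90/180/270),
    with the top camera used at angle 0 only -- 9 views per plant."""
    return make_rig(
        n_cameras=3,
        n_angles=4,
        focal_px=focal_px,
        width=width,
        height=height,
        camera_distance=camera_distance,
        elevations_deg=[20.0, 55.0, 90.0],
        target=target,
        single_view_cameras=(2,),
    )


# ---------------------------------------------------------------------------
# rendering


def _pixel_rays(P: np.ndarray, width: int, height: int) -> tuple[np.ndarray, np.ndarray]:
    """Camera center and per-pixel-center ray directions for projection P."""
    Minv = np.linalg.inv(P[:, :3])
    C = camera_center(P)
    xs = np.arange(width, dtype=float)
    ys = np.arange(height, dtype=float)
    u, v = np.meshgrid(xs, ys)  # (H, W)
    dirs = (
        u[..., None] * Minv[:, 0] + v[..., None] * Minv[:, 1] + Minv[:, 2]
    )  # (H, W, 3)
    return C, dirs.reshape(-1, 3)


def render_silhouette(shape: SceneShape, P: np.ndarray, width: int, height: int) -> np.ndarray:
    """Exact silhouette by pixel-center ray casting; returns a (H, W) uint8 mask."""
    C, dirs = _pixel_rays(P, width, height)
    return shape.ray_hits(C, dirs).reshape(height, width).astype(np.uint8)


def render_rgb(
    shapes_with_colors: list[tuple[SceneShape, tuple[int, int, int]]],
    P: np.ndarray,
    width: int,
    height: int,
    background: tuple[int, int, int] = (0, 0, 0),
) -> np.ndarray:
    """Flat-color rendering: each pixel takes the color of the first solid hit."""
    C, dirs = _pixel_rays(P, width, height)
    best = np.full(len(dirs), np.inf)
    img = np.tile(np.asarray(background, dtype=np.uint8), (len(dirs), 1))
    for shape, color in shapes_with_colors:
        s = shape.ray_first(C, dirs)
        closer = s < best
        best = np.where(closer, s, best)
        img[closer] = np.asarray(color, dtype=np.uint8)
    return img.reshape(height, width, 3)


def render_views(shape: SceneShape, rig: TurntableRig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Render all rig views; returns a list of ``(mask, P)`` pairs."""
    out = []
    for i in range(rig.n_views):
        P = rig.projection(i)
        w, h = rig.image_size(i)
        out.append((render_silhouette(shape, P, w, h), P))
    return out


# ---------------------------------------------------------------------------
# canned scenes


def toy_plant(seed: int | None = None) -> ShapeUnion:
    """Stylized seedling: a vertical stem cylinder plus three leaf spheres.

    With a seed, leaf positions are jittered slightly (deterministically) so
    repeated runs explore different but equally realistic geometries.
    """
    rng = np.random.default_rng(seed)
    if seed is not None:
        jitter = lambda: rng.uniform(-1, 1, 3) * [0.0005, 0.0005, 0.003]
    else:
        jitter = lambda: np.zeros(3)
    stem = VerticalCylinder(base=(0.0, 0.0, 0.0), radius=0.0025, height=0.09)
    # leaf blobs touch the stem (lateral offset < r_leaf + r_stem) at distinct
    # heights and azimuths; their tips stand clear of the stem column so a
    # top-down slice scan sees each leaf separately before it merges
    leaves = []
    for z, azim in ((0.085, 0.0), (0.060, 120.0), (0.035, 240.0)):
        a = np.deg2rad(azim)
        center = np.array([0.0175 * np.cos(a), 0.0175 * np.sin(a), z]) + jitter()
        leaves.append(Sphere(center, 0.016))
    return ShapeUnion((stem, *leaves))


# ---------------------------------------------------------------------------
# scene (de)serialization and dataset emission


def scene_to_json(shape: SceneShape) -> dict:
    def enc(s: SceneShape) -> dict:
        if isinstance(s, Sphere):
            return {"type": "sphere", "center": list(map(float, s.center)), "radius": s.radius}
        if isinstance(s, VerticalCylinder):
            return {
                "type": "cylinder",
                "base": list(map(float, s.base)),
                "radius": s.radius,
                "height": s.height,
            }
        if isinstance(s, ShapeUnion):
            return {"type": "union", "shapes": [enc(c) for c in s.shapes]}
        raise TypeError(f"cannot serialize shape {type(s).__name__}")

    return enc(shape)


def scene_from_json(doc: dict) -> SceneShape:
    kind = doc.get("type")
    if kind == "sphere":
        return Sphere(np.asarray(doc["center"], dtype=float), float(doc["radius"]))
    if kind == "cylinder":
        return VerticalCylinder(
            np.asarray(doc["base"], dtype=float), float(doc["radius"]), float(doc["height"])
        )
    if kind == "union":
        return ShapeUnion(tuple(scene_from_json(s) for s in doc["shapes"]))
    raise ValueError(f"unknown shape type {kind!r}")


def write_dataset(out_dir: str | Path, shape: SceneShape, rig: TurntableRig) -> Path:
    """Emit masks plus a calibration file the ``carve`` command consumes.

    Returns the path of the calibration JSON.  Mask paths inside it are
    relative to the dataset directory.
    """
    from .calib import save_calibration  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    view_entries = []
    for i in range(rig.n_views):
        P = rig.projection(i)
        w, h = rig.image_size(i)
        mask = render_silhouette(shape, P, w, h)
        name = f"mask_{i:03d}.png"
        write_mask(out_dir / name, mask)
        ci, angle = rig.views[i]
        view_entries.append({"camera_index": ci, "angle_deg": angle, "mask_path": name})
    calib_path = out_dir / "calibration.json"
    save_calibration(calib_path, rig.cameras, view_entries, rotation_sign=rig.rotation_sign)
    (out_dir / "scene.json").write_text(json.dumps(scene_to_json(shape), indent=2))
    return calib_path
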