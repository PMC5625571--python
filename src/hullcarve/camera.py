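"""Pinhole projection geometry for a calibrated turntable rig.

Conventions
-----------
* Right-handed world frame with the z axis pointing up along the turntable
  rotation axis; the world origin sits at the rotation center.  The world
  frame rotates *with* the object, so each view's projection matrix folds
  the table rotation in and every view projects the same, static object
  coordinates.
* Image coordinates are 0-based, x rightward, y downward, with integer
  coordinates at pixel centers.
* Positive turntable angle rotates the object counter-clockwise seen from
  above (equivalently: the camera orbits clockwise).  The sign is
  configurable via ``rotation_sign`` since rigs differ.
* Angles are degrees in all interfaces.

For a camera with intrinsics ``K`` and pose ``(R, t, t0)`` relative to the
rotation center, the view at table angle alpha projects homogeneous world
points X through ``P = K [R | t + t0] diag(R_alpha, 1)`` where ``R_alpha``
rotates about the vertical axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .silhouettes import PixelBox

__all__ = [
    "BboxStatus",
    "CameraExtrinsics",
    "CameraIntrinsics",
    "Voxel",
    "build_projection",
    "camera_center",
    "look_at_rotation",
    "project_point",
    "project_points",
    "project_voxel_bbox",
    "project_voxel_bboxes",
    "rotation_about_vertical",
    "voxel_corners",
]

_ORTHO_TOL = 1e-9

# Fixed corner/child octant order: x fastest, then y, then z.  Both the
# 8 cube corners (half-edge offsets) and the 8 child-center offsets
# (quarter-edge offsets) use this order so traversal is deterministic.
_SIGNS = np.array(
    [[sx, sy, sz] for sz in (-1.0, 1.0) for sy in (-1.0, 1.0) for sx in (-1.0, 1.0)]
)
CORNER_OFFSETS = 0.5 * _SIGNS  # multiply by edge
OCTANT_OFFSETS = 0.25 * _SIGNS  # multiply by parent edge


class BboxStatus(IntEnum):
    """Outcome of projecting a voxel's corners into one image."""

    VISIBLE = 0  # clamped pixel box available
    OUT_OF_VIEW = 1  # projected box has no overlap with the image
    BEHIND = 2  # some corner at or behind the camera plane; box undefined


@dataclass(frozen=True)
class CameraIntrinsics:
    """3x3 intrinsic matrix plus the image dimensions it refers to."""

    K: np.ndarray
    width: int
    height: int

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        if K.shape != (3, 3):
            raise ValueError("K must be 3x3")
        if not np.isfinite(K).all():
            raise ValueError("K must be finite")
        if abs(K[2, 2] - 1.0) > _ORTHO_TOL or K[2, 0] != 0 or K[2, 1] != 0:
            raise ValueError("last row of K must be (0, 0, 1)")
        if K[0, 0] <= 0 or K[1, 1] <= 0:
            raise ValueError("focal entries must be positive")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        object.__setattr__(self, "K", K)


@dataclass(frozen=True)
class CameraExtrinsics:
    """Camera pose: rotation ``R``, translation ``t`` and world-origin offset ``t0``.

    ``t`` is the translation with respect to the reference camera and ``t0``
    the additional offset that places the world origin at the turntable
    rotation center; only their sum enters the projection, the split mirrors
    how rig calibrations are usually reported.
    """

    R: np.ndarray
    t: np.ndarray
    t0: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        t = np.asarray(self.t, dtype=float).reshape(3)
        t0 = np.asarray(self.t0, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("R must be 3x3")
        if not (np.isfinite(R).all() and np.isfinite(t).all() and np.isfinite(t0).all()):
            raise ValueError("extrinsics must be finite")
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-8 or abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("R must be a proper rotation (orthonormal, det +1)")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "t0", t0)


@dataclass(frozen=True)
class Voxel:
    """Axis-aligned cube given by its center (meters) and edge length (meters)."""

    center: np.ndarray
    edge: float

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        if self.edge <= 0:
            raise ValueError("voxel edge must be positive")
        object.__setattr__(self, "center", c)


def rotation_about_vertical(angle_deg: float, sign: float = 1.0) -> np.ndarray:
    """Rotation matrix about the world z axis by ``sign * angle_deg`` degrees."""
    a = np.deg2rad(sign * (angle_deg % 360.0))
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_projection(
    intrinsics: CameraIntrinsics,
    extrinsics: CameraExtrinsics,
    angle_deg: float = 0.0,
    rotation_sign: float = 1.0,
) -> np.ndarray:
    """3x4 projection matrix for one view at the given turntable angle.

    ``P = K [R | t + t0] diag(R_alpha, 1)``; at angle 0 this reduces to
    ``K [R | t + t0]``.
    """
    Rt = np.hstack([extrinsics.R, (extrinsics.t + extrinsics.t0)[:, None]])
    M = np.eye(4)
    M[:3, :3] = rotation_about_vertical(angle_deg, sign=rotation_sign)
    P = intrinsics.K @ Rt @ M
    if np.linalg.matrix_rank(P) != 3:
        raise ValueError("degenerate projection matrix (rank < 3)")
    return P


def camera_center(P: np.ndarray) -> np.ndarray:
    """World-space camera center, the null direction of P: ``-M^{-1} p4``."""
    return -np.linalg.solve(P[:, :3], P[:, 3])


def project_points(P: np.ndarray, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project ``(n, 3)`` world points; returns ``(uv (n, 2), w (n,))``.

    ``uv`` is garbage wherever ``w <= 0`` (point at or behind the camera
    plane); callers must check ``w``.
    """
    pts = np.asarray(points, dtype=float)
    uvw = pts @ P[:, :3].T + P[:, 3]
    w = uvw[:, 2]
    safe = np.where(w != 0.0, w, 1.0)
    return uvw[:, :2] / safe[:, None], w


def project_point(P: np.ndarray, X: np.ndarray) -> tuple[np.ndarray | None, float]:
    """Project one homogeneous 4-vector; returns ``(pixel, w)``.

    ``pixel`` is ``None`` when ``w == 0`` exactly (degenerate); a negative
    ``w`` flags a point behind the camera plane (the pixel coordinate is
    still returned but is not geometrically meaningful).
    """
    X = np.asarray(X, dtype=float).reshape(4)
    uvw = P @ X
    w = float(uvw[2])
    if w == 0.0:
        return None, w
    return uvw[:2] / w, w


def voxel_corners(center: np.ndarray, edge: float) -> np.ndarray:
    """The 8 corner points of a voxel, in the fixed octant order."""
    return np.asarray(center, dtype=float) + edge * CORNER_OFFSETS


def project_voxel_bboxes(
    P: np.ndarray,
    centers: np.ndarray,
    edges: np.ndarray,
    width: int,
    height: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Project many voxels to clamped integer pixel boxes (vectorized).

    For each voxel the 8 corners are projected; the box is the floor/ceil
    envelope ``[floor(min u), ceil(max u)] x [floor(min v), ceil(max v)]``,
    clamped to the image.  The envelope (rather than rounding) guarantees the
    integer box contains the true projected hexagon, which keeps the
    occupancy test conservative.

    Returns
    -------
    status : (n,) uint8 array of :class:`BboxStatus` codes
    boxes : (n, 4) int64 array of ``x_min, y_min, x_max, y_max`` (clamped);
        only meaningful where status is VISIBLE.
    """
    centers = np.asarray(centers, dtype=float)
    edges = np.broadcast_to(np.asarray(edges, dtype=float), (len(centers),))
    corners = centers[:, None, :] + edges[:, None, None] * CORNER_OFFSETS
    uvw = corners @ P[:, :3].T + P[:, 3]
    w = uvw[..., 2]
    behind = (w <= 0.0).any(axis=1)
    safe_w = np.where(w > 0.0, w, 1.0)
    u = uvw[..., 0] / safe_w
    v = uvw[..., 1] / safe_w

    x_min = np.floor(u.min(axis=1)).astype(np.int64)
    x_max = np.ceil(u.max(axis=1)).astype(np.int64)
    y_min = np.floor(v.min(axis=1)).astype(np.int64)
    y_max = np.ceil(v.max(axis=1)).astype(np.int64)

    out = (x_max < 0) | (x_min > width - 1) | (y_max < 0) | (y_min > height - 1)
    status = np.zeros(len(centers), dtype=np.uint8)
    status[out] = BboxStatus.OUT_OF_VIEW
    status[behind] = BboxStatus.BEHIND  # behind takes precedence

    boxes = np.stack(
        [
            np.clip(x_min, 0, width - 1),
            np.clip(y_min, 0, height - 1),
            np.clip(x_max, 0, width - 1),
            np.clip(y_max, 0, height - 1),
        ],
        axis=1,
    )
    boxes[status != BboxStatus.VISIBLE] = 0
    return status, boxes


def project_voxel_bbox(
    P: np.ndarray, voxel: Voxel, width: int, height: int
) -> tuple[BboxStatus, PixelBox | None]:
    """Single-voxel convenience wrapper around :func:`project_voxel_bboxes`."""
    status, boxes = project_voxel_bboxes(
        P, voxel.center[None, :], np.array([voxel.edge]), width, height
    )
    if status[0] != BboxStatus.VISIBLE:
        return BboxStatus(int(status[0])), None
    x0, y0, x1, y1 = (int(b) for b in boxes[0])
    return BboxStatus.VISIBLE, PixelBox(x0, y0, x1, y1)


def look_at_rotation(position: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World-to-camera rotation for a camera at ``position`` looking at ``target``.

    The camera z axis points at the target; the image y axis points downward
    in the world (so upright objects appear upright).  For near-vertical
    viewing directions the image x axis falls back to the world x axis.
    """
    position = np.asarray(position, dtype=float)
    target = np.asarray(target, dtype=float)
    fwd = target - position
    n = np.linalg.norm(fwd)
    if n == 0:
        raise ValueError("camera position coincides with target")
    z = fwd / n
    down = np.array([0.0, 0.0, -1.0])
    x = np.cross(down, z)
    if np.linalg.norm(x) < 1e-8:  # looking straight up/down
        x = np.array([1.0, 0.0, 0.0])
    else:
        x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    # re-orthonormalize against accumulated rounding
    u, _, vt = np.linalg.svd(R)
    return u @ vt
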