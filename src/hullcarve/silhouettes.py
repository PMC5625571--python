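"""Binary silhouette masks, cleanup, and integral-image region queries.

A silhouette mask is a 2D array indexed ``[y, x]`` with 1 at plant
(foreground) and 0 at background pixels.  The integral image (summed-area
table) of a mask stores at ``(x, y)`` the number of foreground pixels with
``x' <= x`` and ``y' <= y``, so the foreground count inside any axis-aligned
pixel box can be read off with four table lookups in O(1) -- the primitive
that makes coarse-voxel occupancy tests constant time regardless of how
large the projected voxel is.

All box semantics are inclusive: a :class:`PixelBox` with
``x_min == x_max`` and ``y_min == y_max`` covers exactly one pixel, and the
box area counts pixels, ``(x_max - x_min + 1) * (y_max - y_min + 1)``.  This
is required for the occupancy ratio to reach exactly 1 on fully-foreground
boxes under integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.color import rgb2hsv
from skimage.transform import integral_image as _sk_integral_image

__all__ = [
    "HsvThresholds",
    "IntegralImage",
    "PixelBox",
    "RegionQueryResult",
    "box_sum",
    "box_sums",
    "clean_mask",
    "hsv_threshold",
    "integral_image",
    "read_mask",
    "write_mask",
]


@dataclass(frozen=True)
class PixelBox:
    """Axis-aligned pixel rectangle with inclusive integer bounds."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError(f"inverted pixel box: {self}")

    @property
    def area(self) -> int:
        """Number of pixels covered (inclusive bounds)."""
        return (self.x_max - self.x_min + 1) * (self.y_max - self.y_min + 1)


@dataclass(frozen=True)
class RegionQueryResult:
    """Foreground count and pixel area of one rectangular region query."""

    foreground: int
    area: int

    def __post_init__(self) -> None:
        if not (0 <= self.foreground <= self.area):
            raise ValueError(f"inconsistent region query: {self}")


@dataclass(eq=False)
class IntegralImage:
    """Summed-area table of a binary mask.

    ``table[y, x]`` holds the (integer-exact, int64) count of foreground
    pixels with coordinates ``<= (x, y)``.  The bottom-right entry is the
    total foreground count.
    """

    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table)
        if self.table.ndim != 2:
            raise ValueError("integral table must be 2D")
        if not np.issubdtype(self.table.dtype, np.integer):
            raise ValueError("integral table must be integer-typed")

    @property
    def height(self) -> int:
        return self.table.shape[0]

    @property
    def width(self) -> int:
        return self.table.shape[1]

    @property
    def total(self) -> int:
        return int(self.table[-1, -1])

    @cached_property
    def padded(self) -> np.ndarray:
        """Table with an extra zero row/column at the top/left.

        Implements the convention ``I(-1, .) = I(., -1) = 0`` so the
        four-term lookup needs no branching.
        """
        p = np.zeros((self.height + 1, self.width + 1), dtype=np.int64)
        p[1:, 1:] = self.table
        return p


@dataclass(frozen=True)
class HsvThresholds:
    """Six-value HSV gate: hue in degrees [0, 360), saturation/value in [0, 1].

    A pixel is foreground iff every channel lies inside its closed interval.
    A hue interval with ``h_lo > h_hi`` wraps around 0/360 (common when the
    foreground hue band straddles red).
    """

    h_lo: float
    h_hi: float
    s_lo: float
    s_hi: float
    v_lo: float
    v_hi: float

    def __post_init__(self) -> None:
        for name in ("h_lo", "h_hi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 360.0:
                raise ValueError(f"{name}={v} outside [0, 360]")
        for name in ("s_lo", "s_hi", "v_lo", "v_hi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def hsv_threshold(rgb: np.ndarray, thresholds: HsvThresholds) -> np.ndarray:
    """Segment an RGB image into a binary mask by HSV interval gating.

    Parameters
    ----------
    rgb
        ``(H, W, 3)`` image, uint8 or float in [0, 1].
    thresholds
        Per-channel closed intervals; hue wraps when ``h_lo > h_hi``.

    Returns
    -------
    ``(H, W)`` uint8 mask, 1 = foreground.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {rgb.shape}")
    hsv = rgb2hsv(rgb)
    h = hsv[..., 0] * 360.0
    s = hsv[..., 1]
    v = hsv[..., 2]
    t = thresholds
    if t.h_lo <= t.h_hi:
        h_ok = (h >= t.h_lo) & (h <= t.h_hi)
    else:  # wrap-around interval, e.g. [330, 30]
        h_ok = (h >= t.h_lo) | (h <= t.h_hi)
    mask = h_ok & (s >= t.s_lo) & (s <= t.s_hi) & (v >= t.v_lo) & (v <= t.v_hi)
    return mask.astype(np.uint8)


def clean_mask(mask: np.ndarray, min_object_px: int = 0, max_hole_px: int = 0) -> np.ndarray:
    """Remove small foreground specks and fill small enclosed holes.

    Foreground connected components (8-connectivity) with area strictly below
    ``min_object_px`` are removed; background components (4-connectivity) that
    do not touch the image border and have area strictly below ``max_hole_px``
    are filled.  The 8/4 connectivity pairing is the standard duality for
    binary images.
    """
    if min_object_px < 0 or max_hole_px < 0:
        raise ValueError("size thresholds must be >= 0")
    m = np.asarray(mask).astype(bool)
    if min_object_px > 1:
        # removes components with area <= max_size, hence the -1: the
        # contract keeps components with area >= min_object_px
        m = morphology.remove_small_objects(m, max_size=min_object_px - 1, connectivity=2)
    if max_hole_px > 1:
        bg_labels, n = ndimage.label(~m)  # 4-connectivity (cross structure)
        if n:
            border = np.zeros_like(m)
            border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
            border_ids = np.unique(bg_labels[border & (bg_labels > 0)])
            sizes = np.bincount(bg_labels.ravel(), minlength=n + 1)
            fill = (sizes < max_hole_px) & (np.arange(n + 1) > 0)
            fill[border_ids] = False
            m = m | fill[bg_labels]
    return m.astype(np.uint8)


def integral_image(mask: np.ndarray) -> IntegralImage:
    """Build the summed-area table of a binary mask (integer exact)."""
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2D")
    return IntegralImage(_sk_integral_image(m.astype(np.int64)))


def box_sum(integral: IntegralImage, box: PixelBox) -> RegionQueryResult:
    """Exact foreground count and area of one inclusive pixel box.

    Uses the four-term lookup with the convention that the table is zero at
    index -1; the result equals direct summation of the mask over the box.
    """
    if box.x_min < 0 or box.y_min < 0 or box.x_max >= integral.width or box.y_max >= integral.height:
        raise ValueError(f"box {box} outside {integral.width}x{integral.height} image")
    p = integral.padded
    r = int(
        p[box.y_max + 1, box.x_max + 1]
        - p[box.y_min, box.x_max + 1]
        - p[box.y_max + 1, box.x_min]
        + p[box.y_min, box.x_min]
    )
    return RegionQueryResult(foreground=r, area=box.area)


def box_sums(
    integral: IntegralImage,
    x_min: np.ndarray,
    y_min: np.ndarray,
    x_max: np.ndarray,
    y_max: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`box_sum` over arrays of inclusive box bounds.

    Bounds must already be clamped to the image.  Returns ``(counts, areas)``
    as int64 arrays.
    """
    p = integral.padded
    r = (
        p[y_max + 1, x_max + 1]
        - p[y_min, x_max + 1]
        - p[y_max + 1, x_min]
        + p[y_min, x_min]
    )
    a = (x_max - x_min + 1) * (y_max - y_min + 1)
    return r.astype(np.int64), a.astype(np.int64)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask image (PNG/PGM); any nonzero pixel becomes foreground."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # tolerate RGB(A)-saved masks
        arr = arr[..., :3].max(axis=2)
    return (arr > 0).astype(np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit image (0 background, 255 foreground)."""
    m = (np.asarray(mask) > 0).astype(np.uint8) * 255
    iio.imwrite(path, m)
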