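"""Calibration-file I/O.

The calibration document is a single JSON file per rig::

    {
      "rotation_sign": 1.0,
      "cameras": [
        {"K": [9 numbers, row-major], "R": [9 numbers, row-major],
         "t": [3], "t0": [3], "width": int, "height": int},
        ...
      ],
      "views": [
        {"camera_index": int, "angle_deg": float, "mask_path": "relative/path.png"},
        ...
      ]
    }

All lengths are meters, angles degrees.  ``mask_path`` is resolved relative
to the calibration file's directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .camera import CameraExtrinsics, CameraIntrinsics

__all__ = ["ViewSpec", "load_calibration", "save_calibration"]


@dataclass(frozen=True)
class ViewSpec:
    camera_index: int
    angle_deg: float
    mask_path: str


def save_calibration(
    path: str | Path,
    cameras: list[tuple[CameraIntrinsics, CameraExtrinsics]],
    views: list[dict],
    rotation_sign: float = 1.0,
) -> None:
    doc = {
        "rotation_sign": rotation_sign,
        "cameras": [
            {
                "K": [float(x) for x in intr.K.ravel()],
                "R": [float(x) for x in extr.R.ravel()],
                "t": [float(x) for x in extr.t],
                "t0": [float(x) for x in extr.t0],
                "width": intr.width,
                "height": intr.height,
            }
            for intr, extr in cameras
        ],
        "views": views,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_calibration(
    path: str | Path,
) -> tuple[list[tuple[CameraIntrinsics, CameraExtrinsics]], list[ViewSpec], float]:
    """Parse a calibration file; returns (cameras, views, rotation_sign)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"calibration file not found: {path}")
    doc = json.loads(path.read_text())
    cameras = []
    for i, cam in enumerate(doc.get("cameras", [])):
        try:
            intr = CameraIntrinsics(
                np.asarray(cam["K"], dtype=float).reshape(3, 3),
                int(cam["width"]),
                int(cam["height"]),
            )
            extr = CameraExtrinsics(
                np.asarray(cam["R"], dtype=float).reshape(3, 3),
                np.asarray(cam["t"], dtype=float),
                np.asarray(cam.get("t0", [0.0, 0.0, 0.0]), dtype=float),
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"invalid camera entry {i} in {path}: {exc}") from exc
        cameras.append((intr, extr))
    if not cameras:
        raise ValueError(f"no cameras in calibration file {path}")
    views = []
    for i, v in enumerate(doc.get("views", [])):
        ci = int(v["camera_index"])
        if not 0 <= ci < len(cameras):
            raise ValueError(f"view {i} references unknown camera {ci} in {path}")
        views.append(ViewSpec(ci, float(v["angle_deg"]), str(v.get("mask_path", ""))))
    if not views:
        raise ValueError(f"no views in calibration file {path}")
    return cameras, views, float(doc.get("rotation_sign", 1.0))
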