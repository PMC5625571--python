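"""Minimal PLY point-cloud writer/reader for carving results.

Writes per-vertex positions (float, meters) plus optional uint8 colors and
scalar properties such as the leaf edge length or an integer leaf label, in
ASCII or binary little-endian form.  The reader understands exactly this
vertex-only subset and exists for round-tripping our own files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_ply", "write_ply"]

_PLY_TYPES = {
    np.dtype("float32"): "float",
    np.dtype("float64"): "double",
    np.dtype("uint8"): "uchar",
    np.dtype("int32"): "int",
    np.dtype("uint32"): "uint",
}
_INV_TYPES = {v: k for k, v in _PLY_TYPES.items()}


def write_ply(
    path: str | Path,
    points: np.ndarray,
    colors: np.ndarray | None = None,
    extra: dict[str, np.ndarray] | None = None,
    binary: bool = False,
) -> None:
    """Write an (n, 3) point cloud with optional colors and scalar properties."""
    points = np.asarray(points, dtype=np.float32).reshape(-1, 3)
    fields: list[tuple[str, np.ndarray]] = [
        ("x", points[:, 0]),
        ("y", points[:, 1]),
        ("z", points[:, 2]),
    ]
    if colors is not None:
        colors = np.asarray(colors, dtype=np.uint8).reshape(-1, 3)
        if len(colors) != len(points):
            raise ValueError("colors and points must have the same length")
        fields += [("red", colors[:, 0]), ("green", colors[:, 1]), ("blue", colors[:, 2])]
    for name, values in (extra or {}).items():
        values = np.asarray(values)
        if values.dtype not in _PLY_TYPES:
            values = values.astype(np.float32 if values.dtype.kind == "f" else np.int32)
        if len(values) != len(points):
            raise ValueError(f"property {name!r} length mismatch")
        fields.append((name, values))

    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0"]
    header.append(f"element vertex {len(points)}")
    for name, values in fields:
        header.append(f"property {_PLY_TYPES[values.dtype]} {name}")
    header.append("end_header")

    rec = np.empty(
        len(points), dtype=[(name, values.dtype.newbyteorder("<")) for name, values in fields]
    )
    for name, values in fields:
        rec[name] = values

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            rec.tofile(fh)
        else:
            fmt_parts = ["%d" if v.dtype.kind in "iu" else "%.9g" for _, v in fields]
            lines = []
            cols = [
                v.astype(np.int64) if v.dtype.kind in "iu" else v.astype(float)
                for _, v in fields
            ]
            for row in zip(*cols):
                lines.append(" ".join(f % x for f, x in zip(fmt_parts, row)))
            fh.write(("\n".join(lines) + ("\n" if lines else "")).encode("ascii"))


def read_ply(path: str | Path) -> dict[str, np.ndarray]:
    """Read a vertex-only PLY written by :func:`write_ply`; returns properties by name."""
    with open(path, "rb") as fh:
        fmt = None
        n_vertex = 0
        props: list[tuple[str, np.dtype]] = []
        while True:
            line = fh.readline().decode("ascii").strip()
            if line.startswith("format"):
                fmt = line.split()[1]
            elif line.startswith("element vertex"):
                n_vertex = int(line.split()[-1])
            elif line.startswith("property"):
                _, tname, pname = line.split()
                props.append((pname, _INV_TYPES[tname]))
            elif line == "end_header":
                break
        dtype = np.dtype([(n, d.newbyteorder("<")) for n, d in props])
        if fmt == "binary_little_endian":
            rec = np.fromfile(fh, dtype=dtype, count=n_vertex)
        else:
            raw = np.loadtxt(fh, ndmin=2) if n_vertex else np.zeros((0, len(props)))
            rec = np.empty(n_vertex, dtype=dtype)
            for i, (name, _) in enumerate(props):
                rec[name] = raw[:, i]
    return {name: rec[name].copy() for name, _ in props}
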