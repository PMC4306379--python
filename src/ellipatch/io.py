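"""Plain-file input/output: CSV tables, binary PLY point clouds, raw volumes.

The native volume format is a raw little-endian scalar array plus a sidecar
text header (``<name>.hdr`` next to ``<name>.raw``) holding dims, spacing,
origin and dtype — deliberately minimal so volumes survive any toolchain.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_PLY_HEADER = """ply
format binary_little_endian 1.0
element vertex {n}
property float64 x
property float64 y
property float64 z
{extra}end_header
"""


def write_ply_points(path, points: np.ndarray, gray: np.ndarray | None = None) -> None:
    """Write a binary little-endian PLY point cloud (float64 xyz, optional gray)."""
    pts = np.ascontiguousarray(points, dtype="<f8")
    extra = "property float64 gray\n" if gray is not None else ""
    header = _PLY_HEADER.format(n=pts.shape[0], extra=extra)
    if gray is not None:
        pts = np.column_stack([pts, np.asarray(gray, dtype="<f8")])
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(pts, dtype="<f8").tobytes())


def write_batch_csv(path, method: str, seed: int, y: np.ndarray, x: np.ndarray,
                    points: np.ndarray) -> None:
    """Sample batch as CSV: method,seed,y1,y2,x1,x2,px,py,pz."""
    n = y.shape[0]
    with open(path, "w") as fh:
        fh.write("method,seed,y1,y2,x1,x2,px,py,pz\n")
        for i in range(n):
            fh.write(f"{method},{seed},{y[i,0]:.17g},{y[i,1]:.17g},"
                     f"{x[i,0]:.17g},{x[i,1]:.17g},"
                     f"{points[i,0]:.17g},{points[i,1]:.17g},{points[i,2]:.17g}\n")


def write_textured_csv(path, points: np.ndarray, gray: np.ndarray,
                       inside: np.ndarray) -> None:
    """Textured cloud as CSV: x,y,z,gray,inside."""
    with open(path, "w") as fh:
        fh.write("x,y,z,gray,inside\n")
        for i in range(points.shape[0]):
            g = gray[i]
            fh.write(f"{points[i,0]:.17g},{points[i,1]:.17g},{points[i,2]:.17g},"
                     f"{g:.17g},{int(inside[i])}\n")


def write_control_net_csv(path, patch) -> None:
    """Rational control net as CSV: i1,i2,i3,x,y,z,w (lexicographic in (i1, i2))."""
    with open(path, "w") as fh:
        fh.write("i1,i2,i3,x,y,z,w\n")
        for idx in sorted(patch.control_points):
            b = patch.control_points[idx]
            w = patch.weights[idx]
            fh.write(f"{idx[0]},{idx[1]},{idx[2]},"
                     f"{b[0]:.17g},{b[1]:.17g},{b[2]:.17g},{w:.17g}\n")


# ---------------------------------------------------------------------------
# native raw+header volume format
# ---------------------------------------------------------------------------

def write_volume(path, volume) -> None:
    """Write a VoxelVolume as ``<path>.raw`` + ``<path>.hdr`` (C-order, little-endian)."""
    base = Path(path)
    raw = base.with_suffix(".raw")
    hdr = base.with_suffix(".hdr")
    values = np.ascontiguousarray(volume.values)
    dtype = values.dtype.newbyteorder("<")
    values.astype(dtype).tofile(raw)
    with open(hdr, "w") as fh:
        fh.write(f"dims = {values.shape[0]} {values.shape[1]} {values.shape[2]}\n")
        fh.write(f"spacing = {volume.spacing[0]:.17g} {volume.spacing[1]:.17g} "
                 f"{volume.spacing[2]:.17g}\n")
        fh.write(f"origin = {volume.origin[0]:.17g} {volume.origin[1]:.17g} "
                 f"{volume.origin[2]:.17g}\n")
        fh.write(f"dtype = {values.dtype.name}\n")
        fh.write("byteorder = little\n")
        fh.write("order = C\n")


def read_volume(path):
    """Read a volume written by :func:`write_volume`; returns a VoxelVolume."""
    from .texturing import VoxelVolume  # local import to avoid a cycle

    base = Path(path)
    hdr = base.with_suffix(".hdr")
    raw = base.with_suffix(".raw")
    fields: dict[str, str] = {}
    for line in hdr.read_text().splitlines():
        key, _, val = line.partition("=")
        fields[key.strip()] = val.strip()
    dims = tuple(int(v) for v in fields["dims"].split())
    spacing = tuple(float(v) for v in fields["spacing"].split())
    origin = tuple(float(v) for v in fields["origin"].split())
    dtype = np.dtype(fields["dtype"]).newbyteorder("<")
    values = np.fromfile(raw, dtype=dtype).reshape(dims)
    return VoxelVolume(values=values.astype(values.dtype.newbyteorder("=")),
                       spacing=np.asarray(spacing), origin=np.asarray(origin))
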