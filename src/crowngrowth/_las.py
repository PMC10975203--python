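"""Minimal LAS 1.2 point-cloud reader/writer.

Implemented in-package because no LAS library is available in the target
environment.  Supports the subset this tool needs: uncompressed LAS,
point data record formats 0-3 on read (XYZ always, RGB for formats 2-3),
and writes format 0 (geometry only) or format 2 (geometry + 16-bit RGB)
with a 1 mm coordinate scale — well below the 0.01-0.03 m accuracy of
the handheld scanners this tool targets.  LAZ compression is not
supported.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .exceptions import FormatError

_HEADER_SIZE = 227
_HEADER_FMT = "<4sHHLHH8sBB32s32sHHHLLBHL5L12d"
_POINT_SIZE = {0: 20, 1: 28, 2: 26, 3: 34}
_RGB_OFFSET = {2: 20, 3: 28}
_SCALE = 0.001  # 1 mm


def read_las(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an LAS file; returns (xyz in meters, RGB uint16 or None)."""
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise FormatError(f"{path}: truncated LAS header")
    if raw[:4] != b"LASF":
        raise FormatError(f"{path}: not an LAS file (bad signature)")
    fields = struct.unpack(_HEADER_FMT, raw[:_HEADER_SIZE])
    offset_to_points = fields[14]
    fmt = fields[16]
    rec_len = fields[17]
    n_points = fields[18]
    sx, sy, sz = fields[24], fields[25], fields[26]
    ox, oy, oz = fields[27], fields[28], fields[29]
    if fmt & 0x80:  # LAZ marks compression in the format bit
        raise FormatError(f"{path}: LAZ-compressed points are not supported")
    if fmt not in _POINT_SIZE:
        raise FormatError(f"{path}: unsupported point format {fmt}")
    if rec_len < _POINT_SIZE[fmt]:
        raise FormatError(f"{path}: record length {rec_len} too small for format {fmt}")
    body = raw[offset_to_points : offset_to_points + n_points * rec_len]
    if len(body) < n_points * rec_len:
        raise FormatError(
            f"{path}: header declares {n_points} points but file is truncated"
        )
    rec = np.frombuffer(body, dtype=np.uint8).reshape(n_points, rec_len)
    ixyz = (
        rec[:, :12].copy().view("<i4").reshape(n_points, 3).astype(np.float64)
    )
    xyz = ixyz * np.array([sx, sy, sz]) + np.array([ox, oy, oz])
    rgb = None
    if fmt in _RGB_OFFSET:
        o = _RGB_OFFSET[fmt]
        rgb = rec[:, o : o + 6].copy().view("<u2").reshape(n_points, 3)
    return xyz, rgb


def write_las(
    path: str | Path, xyz: np.ndarray, rgb: np.ndarray | None = None
) -> None:
    """Write an LAS 1.2 file (format 2 when RGB given, else format 0)."""
    xyz = np.asarray(xyz, dtype=np.float64)
    n = xyz.shape[0]
    fmt = 0 if rgb is None else 2
    rec_len = _POINT_SIZE[fmt]
    offset = xyz.min(axis=0)
    ixyz = np.round((xyz - offset) / _SCALE).astype("<i4")
    mins = ixyz.min(axis=0) * _SCALE + offset
    maxs = ixyz.max(axis=0) * _SCALE + offset

    header = struct.pack(
        _HEADER_FMT,
        b"LASF",
        0,  # file source id
        0,  # global encoding
        0,
        0,
        0,
        b"\0" * 8,  # project GUID
        1,
        2,  # version 1.2
        b"crowngrowth".ljust(32, b"\0"),
        b"crowngrowth".ljust(32, b"\0"),
        1,
        2024,  # day/year of creation (fixed, content-irrelevant)
        _HEADER_SIZE,
        _HEADER_SIZE,  # offset to point data (no VLRs)
        0,  # number of VLRs
        fmt,
        rec_len,
        n,
        n,
        0,
        0,
        0,
        0,
        _SCALE,
        _SCALE,
        _SCALE,
        offset[0],
        offset[1],
        offset[2],
        maxs[0],
        mins[0],
        maxs[1],
        mins[1],
        maxs[2],
        mins[2],
    )
    rec = np.zeros((n, rec_len), dtype=np.uint8)
    rec[:, :12] = ixyz.astype("<i4").view(np.uint8).reshape(n, 12)
    if rgb is not None:
        rgb16 = np.ascontiguousarray(rgb, dtype="<u2")
        rec[:, 20:26] = rgb16.view(np.uint8).reshape(n, 6)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(rec.tobytes())
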