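"""Minimal LAS 1.2 reader/writer (ASPRS layout, point formats 0-3).

Only the fields this package needs are handled: XYZ (via the header
scale/offset) and per-point intensity. Written files use point format 0
with a 0.001 m coordinate scale.
"""

from __future__ import annotations

import struct

import numpy as np

from .errors import CloudIOError, EmptyCloudError

_HEADER_FMT = "<4sHH16sBB32s32sHHHLLBHL5L12d"
_HEADER_SIZE = 227
# point record: x,y,z int32; intensity uint16; then format-dependent tail
_POINT_SIZES = {0: 20, 1: 28, 2: 26, 3: 34}
_WRITE_SCALE = 0.001


def read_las(path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a LAS 1.x file; return (points_m (N,3) float64, intensity or None)."""
    try:
        with open(path, "rb") as fh:
            raw = fh.read()
    except OSError as exc:
        raise CloudIOError(f"cannot read {path}: {exc}") from exc
    if len(raw) < _HEADER_SIZE or raw[:4] != b"LASF":
        raise CloudIOError(f"{path}: not a LAS file (bad signature)")
    hdr = struct.unpack(_HEADER_FMT, raw[:_HEADER_SIZE])
    ver_major, ver_minor = hdr[4], hdr[5]
    if ver_major != 1:
        raise CloudIOError(f"{path}: unsupported LAS version {ver_major}.{ver_minor}")
    offset_to_points = hdr[11]
    point_format = hdr[13]
    point_len = hdr[14]
    n_points = hdr[15]
    scales = np.array(hdr[21:24])
    offsets = np.array(hdr[24:27])
    if point_format not in _POINT_SIZES:
        raise CloudIOError(f"{path}: unsupported point data format {point_format}")
    if point_len < _POINT_SIZES[point_format]:
        raise CloudIOError(f"{path}: point record length {point_len} too small")
    if n_points == 0:
        raise EmptyCloudError(f"{path}: zero point records")
    body = raw[offset_to_points:offset_to_points + n_points * point_len]
    if len(body) < n_points * point_len:
        raise CloudIOError(f"{path}: truncated point data")
    rec = np.frombuffer(body, dtype=np.uint8).reshape(n_points, point_len)
    xyz_i = rec[:, :12].copy().view("<i4").reshape(n_points, 3)
    points = xyz_i.astype(np.float64) * scales + offsets
    intensity = rec[:, 12:14].copy().view("<u2").reshape(n_points).astype(np.float64)
    if not intensity.any():
        intensity = None
    return points, intensity


def write_las(path, points: np.ndarray, intensity: np.ndarray | None = None,
              scale: float = _WRITE_SCALE) -> None:
    """Write points (meters) as LAS 1.2, point format 0, given scale."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) == 0:
        raise EmptyCloudError("write_las requires a non-empty (N,3) array")
    n = len(points)
    offs = np.floor(points.min(axis=0))
    quant = np.round((points - offs) / scale)
    if np.abs(quant).max() >= 2**31:
        raise CloudIOError("coordinates overflow int32 at the given LAS scale")
    xyz_i = quant.astype("<i4")
    mins = points.min(axis=0)
    maxs = points.max(axis=0)
    header = struct.pack(
        _HEADER_FMT,
        b"LASF", 0, 0, b"\0" * 16, 1, 2,
        b"rootqsm".ljust(32, b"\0"), b"rootqsm".ljust(32, b"\0"),
        0, 0, _HEADER_SIZE, _HEADER_SIZE, 0, 0, _POINT_SIZES[0], n,
        n, 0, 0, 0, 0,
        scale, scale, scale, offs[0], offs[1], offs[2],
        maxs[0], mins[0], maxs[1], mins[1], maxs[2], mins[2],
    )
    rec = np.zeros(n, dtype=[("xyz", "<i4", 3), ("intensity", "<u2"),
                             ("flags", "u1"), ("cls", "u1"), ("angle", "i1"),
                             ("user", "u1"), ("src", "<u2")])
    rec["xyz"] = xyz_i
    if intensity is not None:
        rec["intensity"] = np.clip(np.round(np.asarray(intensity)), 0, 65535).astype("<u2")
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(rec.tobytes())
    except OSError as exc:
        raise CloudIOError(f"cannot write {path}: {exc}") from exc
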