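"""Minimal LAS 1.2 reader/writer.

Supports uncompressed LAS point record formats 0-3 (the leading
x/y/z/intensity/flags/classification fields are identical across them).
Coordinates are stored as int32 counts of a scale factor plus an offset,
which is the quantization the round-trip tests allow for.  LAZ compression
is not supported.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_HEADER_SIZE = 227  # LAS 1.2
_SIGNATURE = b"LASF"

# record length of the fixed leading block we care about, per point format
_POINT_RECORD_LENGTHS = {0: 20, 1: 28, 2: 26, 3: 34}

_LEAD_DTYPE = np.dtype(
    [
        ("X", "<i4"),
        ("Y", "<i4"),
        ("Z", "<i4"),
        ("intensity", "<u2"),
        ("flags", "u1"),
        ("classification", "u1"),
        ("scan_angle", "i1"),
        ("user_data", "u1"),
        ("point_source_id", "<u2"),
    ]
)


class LasFormatError(ValueError):
    """Raised when a file is not a readable uncompressed LAS."""


def read_las(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Read a LAS file; return (x, y, z, classification) arrays.

    Coordinates are returned in the file's units (meters for the clouds this
    package targets), de-quantized with the header scale/offset.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise LasFormatError(f"{path}: file too small to hold a LAS header")
    if raw[:4] != _SIGNATURE:
        if raw[:4] == b"LASF"[:4]:  # unreachable; keep branch structure simple
            pass
        raise LasFormatError(f"{path}: missing LASF signature (LAZ is not supported)")

    (offset_to_points,) = struct.unpack_from("<I", raw, 96)
    point_format = raw[104]
    if point_format & 0x80:
        raise LasFormatError(f"{path}: LAZ-compressed point data is not supported")
    (record_len,) = struct.unpack_from("<H", raw, 105)
    (n_points,) = struct.unpack_from("<I", raw, 107)
    sx, sy, sz, ox, oy, oz = struct.unpack_from("<6d", raw, 131)

    if point_format not in _POINT_RECORD_LENGTHS:
        raise LasFormatError(f"{path}: unsupported point format {point_format}")
    if record_len < _LEAD_DTYPE.itemsize:
        raise LasFormatError(f"{path}: point record length {record_len} too short")
    if n_points == 0:
        raise LasFormatError(f"{path}: empty point cloud")

    body = raw[offset_to_points : offset_to_points + n_points * record_len]
    if len(body) < n_points * record_len:
        raise LasFormatError(f"{path}: truncated point data")
    full = np.frombuffer(body, dtype=np.uint8).reshape(n_points, record_len)
    lead = full[:, : _LEAD_DTYPE.itemsize].copy().view(_LEAD_DTYPE).reshape(n_points)

    x = lead["X"] * sx + ox
    y = lead["Y"] * sy + oy
    z = lead["Z"] * sz + oz
    # LAS 1.2: classification lives in the low 5 bits
    cls = (lead["classification"] & 0x1F).astype(np.uint8)
    return x, y, z, cls


def write_las(
    path: str | Path,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    classification: np.ndarray | None = None,
    scale: float = 0.001,
) -> None:
    """Write arrays to an uncompressed LAS 1.2 point-format-0 file.

    The default 1 mm scale keeps the int32 quantization far below every
    geometric tolerance in the pipeline.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    n = x.size
    if classification is None:
        classification = np.zeros(n, np.uint8)

    ox, oy, oz = (float(np.floor(v.min())) if n else 0.0 for v in (x, y, z))
    rec = np.zeros(n, dtype=_LEAD_DTYPE)
    rec["X"] = np.round((x - ox) / scale).astype(np.int64)
    rec["Y"] = np.round((y - oy) / scale).astype(np.int64)
    rec["Z"] = np.round((z - oz) / scale).astype(np.int64)
    rec["classification"] = np.asarray(classification, np.uint8) & 0x1F
    rec["flags"] = 0x08  # single return: return number 1 of 1

    header = bytearray(_HEADER_SIZE)
    header[0:4] = _SIGNATURE
    struct.pack_into("<H", header, 94, _HEADER_SIZE)  # header size
    struct.pack_into("<I", header, 96, _HEADER_SIZE)  # offset to point data
    header[24] = 1  # version major
    header[25] = 2  # version minor
    header[104] = 0  # point data format
    struct.pack_into("<H", header, 105, _LEAD_DTYPE.itemsize)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<I", header, 111, n)  # points by return, return 1
    struct.pack_into("<6d", header, 131, scale, scale, scale, ox, oy, oz)
    if n:
        struct.pack_into(
            "<6d", header, 179, x.max(), x.min(), y.max(), y.min(), z.max(), z.min()
        )

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rec.tobytes())
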