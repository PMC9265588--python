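"""Minimal ImageJ ``.roi`` polygon codec.

Reads and writes the subset of the ImageJ ROI binary format that trace
archives use: polygon ROIs with integer vertex coordinates.  The format
is big-endian: a 64-byte header (magic ``Iout``, version, type byte,
bounding box, vertex count) followed by the x offsets then the y offsets
of the vertices relative to the bounding box corner.
"""

from __future__ import annotations

import struct

import numpy as np

MAGIC = b"Iout"
VERSION = 227
TYPE_POLYGON = 0
HEADER_SIZE = 64


def encode_polygon(xy: np.ndarray) -> bytes:
    """Encode an (N, 2) array of integer (x, y) vertices as a polygon ROI."""
    xy = np.asarray(xy)
    xs = np.round(xy[:, 0]).astype(int)
    ys = np.round(xy[:, 1]).astype(int)
    left, top = int(xs.min()), int(ys.min())
    right, bottom = int(xs.max()), int(ys.max())
    n = len(xs)
    header = bytearray(HEADER_SIZE)
    header[0:4] = MAGIC
    struct.pack_into(">h", header, 4, VERSION)
    header[6] = TYPE_POLYGON
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    body = struct.pack(f">{n}h", *(xs - left)) + struct.pack(f">{n}h", *(ys - top))
    return bytes(header) + body


def decode_polygon(data: bytes) -> np.ndarray:
    """Decode a polygon ROI back to an (N, 2) array of (x, y) vertices."""
    if data[0:4] != MAGIC:
        raise ValueError("not an ImageJ ROI (missing 'Iout' magic)")
    roi_type = data[6]
    if roi_type != TYPE_POLYGON:
        raise ValueError(f"unsupported ROI type {roi_type}; only polygon (0)")
    top, left, _bottom, _right = struct.unpack_from(">hhhh", data, 8)
    (n,) = struct.unpack_from(">h", data, 16)
    xs = np.array(struct.unpack_from(f">{n}h", data, HEADER_SIZE)) + left
    ys = np.array(struct.unpack_from(f">{n}h", data, HEADER_SIZE + 2 * n)) + top
    return np.column_stack([xs, ys]).astype(float)
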