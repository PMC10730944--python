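"""Minimal MRC2014 reader/writer.

Supports mode 2 (float32) and mode 6 (uint16) maps with the voxel size
recorded in the cell dimensions, which covers images, tilt-series stacks
(written as 3D maps, one section per image), and reconstructed volumes.
Data are stored C-contiguous with axis order (sections, rows, columns).
"""

from __future__ import annotations

import struct

import numpy as np

__all__ = ["read_mrc", "write_mrc"]

_MODE_FROM_DTYPE = {np.dtype(np.float32): 2, np.dtype(np.uint16): 6}
_DTYPE_FROM_MODE = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}

_HEADER_SIZE = 1024


def write_mrc(path, data: np.ndarray, voxel_size: float = 1.0) -> None:
    """Write a 2D or 3D array as an MRC map with cubic voxels (Å)."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("data must be 2D or 3D")
    if data.dtype not in _MODE_FROM_DTYPE:
        data = data.astype(np.float32)
    mode = _MODE_FROM_DTYPE[data.dtype]
    nz, ny, nx = data.shape
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)          # NX NY NZ
    struct.pack_into("<i", header, 12, mode)                # MODE
    struct.pack_into("<3i", header, 28, nx, ny, nz)         # MX MY MZ
    struct.pack_into(
        "<3f", header, 40, nx * voxel_size, ny * voxel_size, nz * voxel_size
    )                                                       # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)   # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)            # MAPC MAPR MAPS
    stats = data.astype(np.float64)
    struct.pack_into("<3f", header, 76, float(stats.min()), float(stats.max()), float(stats.mean()))
    header[208:212] = b"MAP "                               # MAP stamp
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])       # little-endian stamp
    struct.pack_into("<f", header, 216, float(stats.std()))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(data).tobytes())


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC map; returns (data[(nz,)ny,nx], voxel size in Å)."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise IOError(f"{path!r}: truncated MRC header")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        if mode not in _DTYPE_FROM_MODE:
            raise IOError(f"{path!r}: unsupported MRC mode {mode}")
        mx = struct.unpack_from("<3i", header, 28)[0]
        cella = struct.unpack_from("<3f", header, 40)
        voxel = cella[0] / mx if mx else 1.0
        dtype = np.dtype(_DTYPE_FROM_MODE[mode]).newbyteorder("<")
        count = nx * ny * nz
        data = np.frombuffer(fh.read(count * dtype.itemsize), dtype=dtype, count=count)
    data = data.reshape(nz, ny, nx)
    if nz == 1:
        data = data[0]
    return np.ascontiguousarray(data), float(voxel)
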