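"""Minimal MRC2014 reader/writer for 2-D gray-scale micrographs.

Supports modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16), single
2-D images only (``nz == 1``).  The pixel size is taken from the cell
dimensions (``cella / mx``).  Writing always emits mode 2 with a
standard 1024-byte header and little-endian byte order.
"""

from __future__ import annotations

import struct

import numpy as np

__all__ = ["read_mrc", "write_mrc", "MrcFormatError"]

_HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


class MrcFormatError(ValueError):
    """Raised for files that are not readable 2-D MRC images."""


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read a 2-D MRC file.

    Returns ``(pixels, pixel_size_A)`` where ``pixels`` is a float64
    array indexed ``[row, col]`` and ``pixel_size_A`` is 0.0 when the
    header carries no cell information.
    """
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise MrcFormatError(f"{path}: truncated MRC header")
        # MAP stamp at word 53 identifies MRC2014; accept legacy files
        # without it as long as the dimensions make sense.
        nx, ny, nz, mode = struct.unpack_from("<4i", header, 0)
        if not (0 < nx < 1 << 20 and 0 < ny < 1 << 20 and nz >= 1):
            raise MrcFormatError(f"{path}: implausible dimensions {nx}x{ny}x{nz}")
        if nz != 1:
            raise MrcFormatError(
                f"{path}: {nz}-image stack; only single 2-D micrographs are supported"
            )
        if mode not in _MODE_DTYPES:
            raise MrcFormatError(f"{path}: unsupported MRC mode {mode}")
        mx = struct.unpack_from("<i", header, 28)[0]
        cella_x = struct.unpack_from("<f", header, 40)[0]
        nsymbt = struct.unpack_from("<i", header, 92)[0]
        fh.seek(_HEADER_SIZE + max(nsymbt, 0))
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
        data = np.frombuffer(fh.read(nx * ny * dtype.itemsize), dtype=dtype)
        if data.size != nx * ny:
            raise MrcFormatError(f"{path}: truncated data block")
    pixel_size = float(cella_x / mx) if mx > 0 and cella_x > 0 else 0.0
    return data.reshape(ny, nx).astype(np.float64), pixel_size


def write_mrc(path, pixels: np.ndarray, pixel_size_A: float = 1.0) -> None:
    """Write a 2-D array as a mode-2 (float32) MRC2014 file."""
    pixels = np.asarray(pixels, dtype=np.float32)
    if pixels.ndim != 2:
        raise MrcFormatError("only 2-D images can be written")
    ny, nx = pixels.shape
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, 1, 2)
    struct.pack_into("<3i", header, 28, nx, ny, 1)  # mx, my, mz
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size_A, ny * pixel_size_A, pixel_size_A
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76, float(pixels.min()), float(pixels.max()), float(pixels.mean())
    )
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(pixels.std()))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(pixels.astype("<f4").tobytes())
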