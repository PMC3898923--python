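"""MRC/CCP4 volume I/O, 8-bit quantization, and Brix export.

The in-memory :class:`DensityMap` is the central object of the package: a 3D
scalar grid with per-axis sampling (Å/voxel), an origin placing voxel
(0, 0, 0) in the model coordinate frame, and values stored in canonical
x-fastest order (``values[z, y, x]``).  Files whose header declares a
different axis permutation are reordered at read time so every downstream
computation can assume the canonical layout.

The MRC2014 header is a fixed 1024-byte binary record; it is read and
written here directly with numpy.  Only modes 0 (int8), 1 (int16) and
2 (float32) are supported, which covers archived single-particle maps,
tomograms and masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DensityMap",
    "QuantizedMap",
    "MapFormatError",
    "UnsupportedModeError",
    "read_map",
    "write_map",
    "quantize_8bit",
    "write_brix",
    "read_brix",
    "brix_payload_size",
]

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32}


class MapFormatError(ValueError):
    """Raised when a map file violates the MRC/CCP4 or Brix format."""


class UnsupportedModeError(MapFormatError):
    """Raised for MRC data modes other than 0, 1 or 2."""


@dataclass
class DensityMap:
    """A 3D density grid.

    Parameters
    ----------
    values : ndarray
        Density values, shape ``(nz, ny, nx)`` — x is the fastest axis,
        matching the canonical MRC column order.
    voxel_size : tuple of float
        Sampling interval (Å) along x, y, z.  All components positive.
    origin : tuple of float
        Position (Å) of voxel index (0, 0, 0) in the model frame.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if any(d < 1 for d in self.values.shape):
            raise ValueError("all grid dimensions must be >= 1")
        vs = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in vs):
            raise ValueError("voxel_size components must be positive")
        self.voxel_size = vs
        self.origin = tuple(float(v) for v in self.origin)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        """Grid dimensions (nx, ny, nz)."""
        nz, ny, nx = self.values.shape
        return (nx, ny, nz)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in Å³."""
        return float(np.prod(self.voxel_size))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical box size (Å) along x, y, z: dims × voxel_size."""
        nx, ny, nz = self.dims
        return (nx * self.voxel_size[0], ny * self.voxel_size[1], nz * self.voxel_size[2])

    def stats(self) -> dict[str, float]:
        v = self.values
        return {
            "min": float(v.min()),
            "max": float(v.max()),
            "mean": float(v.mean(dtype=np.float64)),
            "sd": float(v.std(dtype=np.float64)),
        }


@dataclass
class QuantizedMap:
    """8-bit companion of a :class:`DensityMap`.

    ``dequantized = bytes · scale + offset`` reproduces the source density
    to within half a quantization step (``scale / 2``) at every voxel.
    """

    bytes: np.ndarray  # uint8, shape (nz, ny, nx)
    scale: float
    offset: float
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.bytes = np.asarray(self.bytes, dtype=np.uint8)
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        nz, ny, nx = self.bytes.shape
        return (nx, ny, nz)

    def dequantize(self) -> DensityMap:
        return DensityMap(
            self.bytes.astype(np.float64) * self.scale + self.offset,
            voxel_size=self.voxel_size,
            origin=self.origin,
        )


# ---------------------------------------------------------------------------
# MRC/CCP4 reading and writing


def _header_int(buf: bytes, word: int) -> int:
    return int(np.frombuffer(buf, dtype="<i4", count=1, offset=4 * word)[0])


def _header_float(buf: bytes, word: int) -> float:
    return float(np.frombuffer(buf, dtype="<f4", count=1, offset=4 * word)[0])


def read_map(path) -> DensityMap:
    """Read an MRC/CCP4 map (modes 0, 1, 2) into a :class:`DensityMap`.

    Axis permutations declared by ``mapc/mapr/maps`` are undone so the
    returned values are in canonical x-fastest order.  The origin is the
    MRC origin record when non-zero, otherwise it is derived from
    ``nxstart/nystart/nzstart × voxel_size``.

    Raises
    ------
    MapFormatError
        On a malformed header or truncated data block; the message names
        the offending header field.
    UnsupportedModeError
        For data modes other than 0, 1 or 2.
    """
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise MapFormatError("file shorter than the 1024-byte MRC header")
        ncrs = [_header_int(header, w) for w in (0, 1, 2)]  # cols, rows, sections
        mode = _header_int(header, 3)
        starts = [_header_int(header, w) for w in (4, 5, 6)]
        m_grid = [_header_int(header, w) for w in (7, 8, 9)]
        cella = [_header_float(header, w) for w in (10, 11, 12)]
        axis_map = [_header_int(header, w) for w in (16, 17, 18)]  # mapc, mapr, maps
        nsymbt = _header_int(header, 23)
        origin_rec = [_header_float(header, w) for w in (49, 50, 51)]

        for label, n in zip(("nx", "ny", "nz"), ncrs):
            if n < 1:
                raise MapFormatError(f"header field {label} must be >= 1, got {n}")
        if mode not in _MODE_DTYPES:
            raise UnsupportedModeError(
                f"header field mode = {mode} is not supported (only modes 0, 1, 2)"
            )
        if sorted(axis_map) != [1, 2, 3]:
            raise MapFormatError(
                f"header fields mapc/mapr/maps = {tuple(axis_map)} are not a "
                "permutation of (1, 2, 3)"
            )
        if nsymbt < 0:
            raise MapFormatError(f"header field nsymbt is negative: {nsymbt}")
        if nsymbt:
            sym = fh.read(nsymbt)
            if len(sym) < nsymbt:
                raise MapFormatError("header field nsymbt exceeds the file size")

        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
        nvox = ncrs[0] * ncrs[1] * ncrs[2]
        raw = fh.read(nvox * dtype.itemsize)
        if len(raw) < nvox * dtype.itemsize:
            raise MapFormatError(
                "data block truncated: header fields nx*ny*nz promise "
                f"{nvox} voxels but the file holds fewer"
            )

    # File layout: sections slowest, columns fastest.
    data = np.frombuffer(raw, dtype=dtype).reshape(ncrs[2], ncrs[1], ncrs[0])
    # data dim d (0=sections, 1=rows, 2=cols) runs along xyz axis file_axes[d].
    file_axes = [axis_map[2], axis_map[1], axis_map[0]]
    # Canonical target order for dims (0,1,2) of values[z,y,x] is axes (3,2,1).
    perm = [file_axes.index(a) for a in (3, 2, 1)]
    values = np.ascontiguousarray(np.transpose(data, perm)).astype(np.float32, copy=False)

    # Per-xyz-axis sampling: cella spans m_grid sampling intervals along xyz.
    voxel = []
    nx, ny, nz = values.shape[2], values.shape[1], values.shape[0]
    for axis, n_axis in zip(range(3), (nx, ny, nz)):
        m = m_grid[axis] if m_grid[axis] > 0 else n_axis
        voxel.append(cella[axis] / m if cella[axis] > 0 else 1.0)

    if any(v != 0.0 for v in origin_rec):
        origin = tuple(origin_rec)
    else:
        # starts are per file dim (cols, rows, sections) -> reorder to xyz
        start_xyz = [0, 0, 0]
        for d, axis in zip(range(3), (axis_map[0], axis_map[1], axis_map[2])):
            start_xyz[axis - 1] = starts[d]
        origin = tuple(start_xyz[i] * voxel[i] for i in range(3))

    return DensityMap(values, voxel_size=tuple(voxel), origin=origin)


def write_map(dmap: DensityMap, path, axis_order: tuple[int, int, int] = (1, 2, 3)) -> None:
    """Write a :class:`DensityMap` as MRC2014 mode 2 (float32).

    ``axis_order`` gives (mapc, mapr, maps) and exists so tests can produce
    files with non-canonical axis permutations; the default writes the
    standard x-fastest layout.
    """
    if sorted(axis_order) != [1, 2, 3]:
        raise ValueError("axis_order must be a permutation of (1, 2, 3)")
    nx, ny, nz = dmap.dims
    n_axis = (nx, ny, nz)

    header = np.zeros(256, dtype="<i4")
    fheader = header.view("<f4")
    # counts are per file dim: cols along axis_order[0], etc.
    header[0:3] = [n_axis[axis_order[0] - 1], n_axis[axis_order[1] - 1], n_axis[axis_order[2] - 1]]
    header[3] = 2  # mode 2, float32
    header[7:10] = n_axis  # mx, my, mz along xyz
    fheader[10:13] = [n_axis[i] * dmap.voxel_size[i] for i in range(3)]  # cella
    fheader[13:16] = [90.0, 90.0, 90.0]  # cellb
    header[16:19] = axis_order
    stats = dmap.stats()
    fheader[19] = stats["min"]
    fheader[20] = stats["max"]
    fheader[21] = stats["mean"]
    header[22] = 1  # ispg: implies volume
    header[27] = 20140  # nversion
    fheader[49:52] = dmap.origin
    header[52] = int.from_bytes(b"MAP ", "little")
    header[53] = int.from_bytes(bytes([0x44, 0x44, 0, 0]), "little")  # little-endian stamp
    fheader[54] = stats["sd"]

    # values[z,y,x] has dims along axes (3,2,1); rearrange so the file gets
    # sections along axis_order[2], rows along axis_order[1], cols along [0].
    target_axes = (axis_order[2], axis_order[1], axis_order[0])
    perm = [(3, 2, 1).index(a) for a in target_axes]
    data = np.ascontiguousarray(np.transpose(dmap.values, perm)).astype("<f4")

    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        fh.write(data.tobytes())


# ---------------------------------------------------------------------------
# 8-bit quantization and Brix


def quantize_8bit(dmap: DensityMap) -> QuantizedMap:
    """Linearly map the density range [min, max] onto bytes [0, 255].

    A constant map quantizes to all-zero bytes with scale 1 and offset equal
    to the constant, so dequantization remains exact.
    """
    lo = float(dmap.values.min())
    hi = float(dmap.values.max())
    if hi == lo:
        return QuantizedMap(
            np.zeros_like(dmap.values, dtype=np.uint8),
            scale=1.0,
            offset=lo,
            voxel_size=dmap.voxel_size,
            origin=dmap.origin,
        )
    scale = (hi - lo) / 255.0
    b = np.rint((dmap.values.astype(np.float64) - lo) / scale)
    return QuantizedMap(
        np.clip(b, 0, 255).astype(np.uint8),
        scale=scale,
        offset=lo,
        voxel_size=dmap.voxel_size,
        origin=dmap.origin,
    )


def brix_payload_size(nx: int, ny: int, nz: int) -> int:
    """Bytes of brick payload: 512 per 8×8×8 brick, partial bricks padded."""
    return 512 * math.ceil(nx / 8) * math.ceil(ny / 8) * math.ceil(nz / 8)


def _brick_bytes(b: np.ndarray) -> bytes:
    """Pack a (nz, ny, nx) byte array into zero-padded 8×8×8 bricks.

    Bricks are ordered x-fastest over the brick grid; within a brick the
    layout is also x-fastest.
    """
    nz, ny, nx = b.shape
    pz, py, px = (-nz) % 8, (-ny) % 8, (-nx) % 8
    padded = np.pad(b, ((0, pz), (0, py), (0, px)))
    bz, by, bx = padded.shape[0] // 8, padded.shape[1] // 8, padded.shape[2] // 8
    bricks = padded.reshape(bz, 8, by, 8, bx, 8).transpose(0, 2, 4, 1, 3, 5)
    return np.ascontiguousarray(bricks).tobytes()


def write_brix(qmap: QuantizedMap, path) -> None:
    """Write a :class:`QuantizedMap` in Brix format.

    The 512-byte text header carries the grid origin and extent, the cell,
    and the linear ``prod``/``plus`` scaling with the convention
    ``density = (byte - plus) / prod``.
    """
    nx, ny, nz = qmap.dims
    cell = (
        nx * qmap.voxel_size[0],
        ny * qmap.voxel_size[1],
        nz * qmap.voxel_size[2],
    )
    prod = 1.0 / qmap.scale
    plus = -qmap.offset / qmap.scale
    header = (
        ":-) origin {:.6g} {:.6g} {:.6g} extent {:d} {:d} {:d} grid {:d} {:d} {:d} "
        "cell {:.6g} {:.6g} {:.6g} 90 90 90 prod {:.9g} plus {:.9g} sigma 0"
    ).format(*qmap.origin, nx, ny, nz, nx, ny, nz, *cell, prod, plus)
    raw = header.encode("ascii")
    if len(raw) > 512:
        raise MapFormatError("Brix text header exceeds 512 bytes")
    with open(path, "wb") as fh:
        fh.write(raw.ljust(512))
        fh.write(_brick_bytes(qmap.bytes))


def read_brix(path) -> QuantizedMap:
    """Read a Brix file written by :func:`write_brix` (round-trip check)."""
    with open(path, "rb") as fh:
        header = fh.read(512).decode("ascii", errors="replace")
        payload = fh.read()
    tokens = header.split()
    if not tokens or tokens[0] != ":-)":
        raise MapFormatError("Brix header does not start with the ':-)' magic")

    def after(key: str, n: int) -> list[float]:
        try:
            i = [t.lower() for t in tokens].index(key)
        except ValueError:
            raise MapFormatError(f"Brix header missing field {key}") from None
        return [float(t) for t in tokens[i + 1 : i + 1 + n]]

    origin = tuple(after("origin", 3))
    nx, ny, nz = (int(v) for v in after("extent", 3))
    cell = after("cell", 6)
    prod = after("prod", 1)[0]
    plus = after("plus", 1)[0]

    expected = brix_payload_size(nx, ny, nz)
    if len(payload) < expected:
        raise MapFormatError("Brix data block truncated")
    bz, by, bx = math.ceil(nz / 8), math.ceil(ny / 8), math.ceil(nx / 8)
    bricks = np.frombuffer(payload[:expected], dtype=np.uint8).reshape(bz, by, bx, 8, 8, 8)
    padded = bricks.transpose(0, 3, 1, 4, 2, 5).reshape(bz * 8, by * 8, bx * 8)
    b = padded[:nz, :ny, :nx]
    scale = 1.0 / prod
    offset = -plus * scale
    voxel = (cell[0] / nx, cell[1] / ny, cell[2] / nz)
    return QuantizedMap(b.copy(), scale=scale, offset=offset, voxel_size=voxel, origin=origin)
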