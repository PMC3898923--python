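"""Trilinear down-sampling under a grid cap, and tomogram slice extraction.

Large maps are reduced so that no dimension exceeds a cap (default 160 grid
points) using a single isotropic scale factor, which keeps cubic voxels
cubic.  Output sample ``i`` along an axis maps to input voxel coordinate
``i·(Nin−1)/(Nout−1)`` (endpoints aligned), so the map's bounding box is
preserved and trilinear interpolation is exact on trilinear density fields.

The slice extractor renders one Z plane of a tomogram to 8-bit grayscale
with either an explicit density window or an automatic one at the 1st/99th
percentiles of the plane (robust to hot pixels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .map_io import DensityMap

__all__ = ["SliceImage", "downsample_trilinear", "extract_slice", "write_png"]

DEFAULT_MAX_DIM = 160


@dataclass
class SliceImage:
    """One Z plane rendered to 8-bit grayscale."""

    pixels: np.ndarray  # uint8, shape (height, width)
    z_index: int
    window: tuple[float, float]  # densities mapped to pixel 0 and 255

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


def _output_dims(dims: tuple[int, int, int], max_dim: int) -> tuple[int, ...]:
    s = max_dim / max(dims)
    return tuple(min(max_dim, max(1, int(round(n * s)))) for n in dims)


def downsample_trilinear(dmap: DensityMap, max_dim: int = DEFAULT_MAX_DIM) -> DensityMap:
    """Down-sample a map so no dimension exceeds ``max_dim`` grid points.

    Maps already within the cap are returned unchanged (the operation never
    up-samples).  Otherwise the isotropic factor ``s = max_dim / max(dims)``
    shrinks every axis; voxel size is divided by ``s`` and the origin is
    preserved.
    """
    if max_dim < 2:
        raise ValueError("max_dim must be >= 2")
    nx, ny, nz = dmap.dims
    if max(nx, ny, nz) <= max_dim:
        return dmap

    s = max_dim / max(nx, ny, nz)
    out_x, out_y, out_z = _output_dims((nx, ny, nz), max_dim)

    def axis_coords(n_in: int, n_out: int) -> np.ndarray:
        if n_out == 1:
            return np.zeros(1)
        return np.arange(n_out) * ((n_in - 1) / (n_out - 1))

    cz = axis_coords(nz, out_z)
    cy = axis_coords(ny, out_y)
    cx = axis_coords(nx, out_x)
    grid = np.meshgrid(cz, cy, cx, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    # interpolate in the input dtype: float64 maps stay exact on linear
    # fields, float32 maps avoid a full-precision copy
    values = ndimage.map_coordinates(
        dmap.values, coords, order=1, mode="nearest"
    ).reshape(out_z, out_y, out_x)
    return DensityMap(
        values,
        voxel_size=tuple(v / s for v in dmap.voxel_size),
        origin=dmap.origin,
    )


def extract_slice(dmap: DensityMap, z_index: int, window=None) -> SliceImage:
    """Extract one Z plane as an 8-bit grayscale image.

    With ``window=None`` the display window is guessed automatically from
    the 1st and 99th percentiles of the plane; a constant plane renders as
    uniform mid-gray (128).  With an explicit ``(lo, hi)`` window, densities
    at or below ``lo`` map to 0, at or above ``hi`` to 255, linearly in
    between.
    """
    nz = dmap.values.shape[0]
    if not 0 <= z_index < nz:
        raise IndexError(f"z_index {z_index} out of range for {nz} planes")
    plane = dmap.values[z_index].astype(np.float64)

    if window is None:
        lo, hi = np.percentile(plane, [1.0, 99.0])
    else:
        lo, hi = float(window[0]), float(window[1])
        if lo >= hi:
            raise ValueError("window lower bound must be below the upper bound")
    if lo == hi:  # constant (or near-constant) plane
        return SliceImage(
            np.full(plane.shape, 128, dtype=np.uint8),
            z_index=z_index,
            window=(lo, hi),
        )
    scaled = np.clip((plane - lo) / (hi - lo), 0.0, 1.0)
    pixels = np.rint(scaled * 255.0).astype(np.uint8)
    return SliceImage(pixels, z_index=z_index, window=(lo, hi))


def write_png(image: SliceImage, path) -> None:
    """Save a slice as an 8-bit grayscale PNG."""
    from PIL import Image

    Image.fromarray(image.pixels, mode="L").save(path, format="PNG")
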