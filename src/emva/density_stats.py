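"""Map-level statistics: histogram, contour level, enclosed volume, FSC.

These are the per-entry quantities a validation page shows for a deposited
map: the density distribution (128 bins; a sharp spike at zero flags a
masked volume), the recommended contour level (author-supplied, or the map
mean plus one standard deviation as fallback), the enclosed volume as a
function of contour level, a molecular-weight-based volume estimate at an
assumed mass density of 1.5 g/cm³, and the Fourier shell correlation
between two half-maps.

Volumes are computed in Å³ from the voxel sampling and reported in nm³.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .map_io import DensityMap

__all__ = [
    "Histogram",
    "VolumeCurve",
    "FSCCurve",
    "ContourLevel",
    "ContourSource",
    "DEFAULT_NBINS",
    "DEFAULT_MASS_DENSITY",
    "AVOGADRO",
    "density_histogram",
    "recommended_contour",
    "volume_curve",
    "enclosed_volume",
    "mw_to_volume",
    "fsc_curve",
    "read_fsc_table",
    "write_fsc_table",
]

DEFAULT_NBINS = 128
DEFAULT_MASS_DENSITY = 1.5  # g/cm³, rough average for macromolecular complexes
AVOGADRO = 6.02214076e23  # 1/mol (exact, SI 2019)
A3_PER_NM3 = 1000.0


class ContourSource(enum.Enum):
    AUTHOR = "author"
    EMDB_STAFF = "emdb_staff"
    FALLBACK_MEAN_PLUS_SD = "fallback_mean_plus_sd"


@dataclass
class Histogram:
    """Density histogram with equal-width bins spanning [min, max].

    ``degenerate`` marks the single-bin histogram of a constant map.
    """

    bin_edges: np.ndarray  # nbins + 1 ascending values (density units)
    counts: np.ndarray  # nbins non-negative integers
    degenerate: bool = False

    @property
    def nbins(self) -> int:
        return len(self.counts)

    @property
    def levels(self) -> np.ndarray:
        """Bin left edges, reused as the level axis of companion curves."""
        return self.bin_edges[:-1]


@dataclass
class VolumeCurve:
    """Enclosed volume (nm³) as a function of contour level."""

    levels: np.ndarray  # ascending density values
    volumes: np.ndarray  # nm³, non-increasing


@dataclass
class FSCCurve:
    """Fourier shell correlation between two maps on the same grid."""

    frequencies: np.ndarray  # shell center spatial frequencies (1/Å)
    correlations: np.ndarray  # in [-1, 1]
    shell_counts: np.ndarray  # Fourier voxels per shell


@dataclass
class ContourLevel:
    value: float
    source: ContourSource


def density_histogram(dmap: DensityMap, nbins: int = DEFAULT_NBINS) -> Histogram:
    """Histogram of voxel densities in ``nbins`` equal-width bins.

    Bins span exactly [min, max]; the maximum value falls in the last bin.
    A constant map yields a degenerate single-bin histogram.
    """
    if nbins < 1:
        raise ValueError("nbins must be positive")
    v = dmap.values
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return Histogram(
            bin_edges=np.array([lo, hi]),
            counts=np.array([v.size], dtype=np.int64),
            degenerate=True,
        )
    counts, edges = np.histogram(v, bins=nbins, range=(lo, hi))
    return Histogram(bin_edges=edges, counts=counts.astype(np.int64))


def recommended_contour(dmap: DensityMap, author_level: float | None = None) -> ContourLevel:
    """Contour level to render the map at.

    An author- (or curator-) supplied level is used verbatim; otherwise the
    fallback is the map mean plus one standard deviation.  The fallback is
    sensitive to padding and masking, which is why a supplied level always
    wins.
    """
    if author_level is not None:
        return ContourLevel(float(author_level), ContourSource.AUTHOR)
    s = dmap.stats()
    return ContourLevel(s["mean"] + s["sd"], ContourSource.FALLBACK_MEAN_PLUS_SD)


def _count_at_or_above(sorted_values: np.ndarray, levels: np.ndarray) -> np.ndarray:
    return sorted_values.size - np.searchsorted(sorted_values, levels, side="left")


def volume_curve(dmap: DensityMap, nbins: int = DEFAULT_NBINS) -> VolumeCurve:
    """Enclosed volume at each of ``nbins`` contour levels.

    Levels are the histogram bin left edges over [min, max]; the volume at
    level ℓ is the number of voxels with density ≥ ℓ times the voxel
    volume, in nm³.  At the lowest level this is the full box volume.
    """
    hist = density_histogram(dmap, nbins)
    levels = hist.levels
    sorted_values = np.sort(dmap.values, axis=None)
    counts = _count_at_or_above(sorted_values, levels)
    volumes = counts * dmap.voxel_volume / A3_PER_NM3
    return VolumeCurve(levels=np.asarray(levels, dtype=float), volumes=volumes)


def enclosed_volume(dmap: DensityMap, level: float) -> float:
    """Volume (nm³) enclosed by the isosurface at ``level``.

    Counts voxels with density ≥ level; works for negative levels too, in
    which case every voxel of an all-positive map is counted.
    """
    count = int(np.count_nonzero(dmap.values >= level))
    return count * dmap.voxel_volume / A3_PER_NM3


def mw_to_volume(mw: float, mass_density: float = DEFAULT_MASS_DENSITY) -> float:
    """Rough specimen volume (nm³) from a molecular weight (Da).

    V = MW / (ρ · N_A) with ρ in g/cm³, assuming uniform mass density.
    100 kDa at 1.5 g/cm³ gives ≈ 110.7 nm³.
    """
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    if mass_density <= 0:
        raise ValueError("mass density must be positive")
    volume_cm3 = mw / (mass_density * AVOGADRO)
    return volume_cm3 * 1e21  # cm³ -> nm³


def fsc_curve(map1: DensityMap, map2: DensityMap, shell_width: float = 1.0) -> FSCCurve:
    """Fourier shell correlation between two maps.

    Both maps are Fourier transformed and the normalized correlation

        FSC(s) = Re Σ F₁·F₂* / sqrt(Σ|F₁|² · Σ|F₂|²)

    is accumulated over spherical shells of reciprocal space.  Shells are
    ``shell_width`` Fourier pixels wide (a Fourier pixel being the sampling
    interval 1/(N·a) of the largest axis); shell center frequencies are
    reported in 1/Å up to Nyquist.
    """
    if map1.dims != map2.dims:
        raise ValueError(f"map grids differ: {map1.dims} vs {map2.dims}")
    if not np.allclose(map1.voxel_size, map2.voxel_size):
        raise ValueError("map voxel sizes differ")
    if shell_width <= 0:
        raise ValueError("shell_width must be positive")

    f1 = np.fft.fftn(map1.values.astype(np.float64, copy=False))
    f2 = np.fft.fftn(map2.values.astype(np.float64, copy=False))

    nz, ny, nx = map1.values.shape
    vx, vy, vz = map1.voxel_size
    qz = np.fft.fftfreq(nz, d=vz)[:, None, None]
    qy = np.fft.fftfreq(ny, d=vy)[None, :, None]
    qx = np.fft.fftfreq(nx, d=vx)[None, None, :]
    q = np.sqrt(qx * qx + qy * qy + qz * qz)

    dq = shell_width / (max(nx, ny, nz) * min(map1.voxel_size))  # one Fourier pixel
    shell = np.rint(q / dq).astype(np.int64).ravel()
    nshells = int(shell.max()) + 1

    num = np.bincount(shell, weights=(f1 * np.conj(f2)).real.ravel(), minlength=nshells)
    p1 = np.bincount(shell, weights=(np.abs(f1) ** 2).ravel(), minlength=nshells)
    p2 = np.bincount(shell, weights=(np.abs(f2) ** 2).ravel(), minlength=nshells)
    counts = np.bincount(shell, minlength=nshells)

    nyquist = 1.0 / (2.0 * max(map1.voxel_size))
    freqs = np.arange(nshells) * dq
    keep = (counts > 0) & (freqs <= nyquist + 0.5 * dq)

    denom = np.sqrt(p1[keep] * p2[keep])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num[keep] / denom, 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    return FSCCurve(
        frequencies=np.minimum(freqs[keep], nyquist),
        correlations=corr,
        shell_counts=counts[keep],
    )


def read_fsc_table(path) -> FSCCurve:
    """Read an externally supplied two-column (frequency 1/Å, FSC) table."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 2:
        raise ValueError("FSC table needs two columns: frequency, correlation")
    return FSCCurve(
        frequencies=data[:, 0],
        correlations=data[:, 1],
        shell_counts=np.zeros(len(data), dtype=np.int64),
    )


def write_fsc_table(curve: FSCCurve, path) -> None:
    np.savetxt(
        path,
        np.column_stack([curve.frequencies, curve.correlations]),
        header="frequency_1/A\tfsc",
        fmt="%.8g",
        delimiter="\t",
    )
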