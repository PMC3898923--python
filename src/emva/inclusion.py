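"""Map–model agreement: atom inclusion curves and per-residue inclusion.

An atom counts as *inside* the map surface at contour level ℓ when the
trilinearly interpolated density at its position is at or above ℓ
(matching the isosurface a viewer renders at that level).  Positions
outside the map's bounding box are outside any surface.

The inclusion curve reports, over the map's full dynamic range, the
fraction of atoms inside — separately for all deposited atoms and for the
reduced representation (backbone atoms when present, trace atoms
otherwise).  Per-residue inclusion at a single level colours each residue
on a linear red→green ramp (red fully outside, green fully inside) and
partitions residues into display segments of at most 200.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .density_stats import DEFAULT_NBINS, density_histogram
from .map_io import DensityMap
from .model_tools import Model, backbone_atoms, has_full_backbone, trace_atom

__all__ = [
    "InclusionCurve",
    "ResidueRecord",
    "ResidueInclusion",
    "SEGMENT_SIZE",
    "DEFAULT_DISPLAY_THRESHOLD",
    "density_at",
    "atom_inclusion_curve",
    "residue_inclusion",
    "model_inside_fraction",
    "default_display",
    "inclusion_colour",
]

SEGMENT_SIZE = 200
DEFAULT_DISPLAY_THRESHOLD = 0.40


@dataclass
class InclusionCurve:
    """Fraction of atoms inside the map as a function of contour level."""

    levels: np.ndarray  # ascending density values
    fraction_all: np.ndarray  # all deposited atoms, in [0, 1]
    fraction_reduced: np.ndarray  # backbone or trace atoms, in [0, 1]
    reduced_kind: str = "backbone"  # "backbone" | "trace"


@dataclass
class ResidueRecord:
    chain_id: str
    res_id: int
    fraction: float  # atoms inside / atoms in residue, at the given level
    colour: tuple[int, int, int]


@dataclass
class ResidueInclusion:
    records: list[ResidueRecord]
    level: float

    @property
    def segments(self) -> list[list[ResidueRecord]]:
        """Model-order runs of at most 200 residues each."""
        return [
            self.records[i : i + SEGMENT_SIZE]
            for i in range(0, len(self.records), SEGMENT_SIZE)
        ]


def density_at(dmap: DensityMap, positions, method: str = "trilinear") -> np.ndarray:
    """Interpolated map density at Cartesian positions (Å).

    Positions outside the grid's bounding box return −infinity, so they are
    outside any isosurface.  ``method`` is ``"trilinear"`` (default) or
    ``"nearest"`` (nearest-voxel, for cross-checks).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    voxel = (positions - np.asarray(dmap.origin)) / np.asarray(dmap.voxel_size)
    nx, ny, nz = dmap.dims
    in_bounds = (
        (voxel[:, 0] >= 0)
        & (voxel[:, 0] <= nx - 1)
        & (voxel[:, 1] >= 0)
        & (voxel[:, 1] <= ny - 1)
        & (voxel[:, 2] >= 0)
        & (voxel[:, 2] <= nz - 1)
    )
    out = np.full(len(voxel), -np.inf)
    if np.any(in_bounds):
        coords = voxel[in_bounds][:, ::-1].T  # (z, y, x) index order
        order = 1 if method == "trilinear" else 0
        if method not in ("trilinear", "nearest"):
            raise ValueError(f"unknown interpolation method {method!r}")
        out[in_bounds] = ndimage.map_coordinates(
            dmap.values.astype(np.float64, copy=False), coords, order=order, mode="nearest"
        )
    return out


def _fraction_inside(densities: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Fraction of sites with density ≥ each level (vectorized, sorted)."""
    finite = np.sort(densities)
    n = len(finite)
    counts = n - np.searchsorted(finite, levels, side="left")
    return counts / n


def atom_inclusion_curve(dmap: DensityMap, model: Model, nbins: int = DEFAULT_NBINS) -> InclusionCurve:
    """Atom-inclusion fractions over the map's full dynamic range.

    Levels reuse the 128 histogram levels of the same map so inclusion,
    histogram and volume curves share a density axis.  The reduced series
    uses backbone atoms; for trace-only models (no residue carries a full
    backbone set) it uses trace atoms instead.
    """
    if model.n_atoms == 0:
        raise ValueError("model has no atoms")
    levels = np.asarray(density_histogram(dmap, nbins).levels, dtype=float)

    all_density = density_at(dmap, model.atom_positions())

    trace_only = not any(has_full_backbone(res) for _, res in model.residues())
    if trace_only:
        reduced_pos = [trace_atom(res).position for _, res in model.residues()]
        kind = "trace"
    else:
        reduced_pos = [
            a.position for _, res in model.residues() for a in backbone_atoms(res)
        ]
        kind = "backbone"
    reduced_density = density_at(dmap, np.vstack(reduced_pos))

    return InclusionCurve(
        levels=levels,
        fraction_all=_fraction_inside(all_density, levels),
        fraction_reduced=_fraction_inside(reduced_density, levels),
        reduced_kind=kind,
    )


def inclusion_colour(fraction: float) -> tuple[int, int, int]:
    """Piecewise-linear red→yellow→green ramp.

    Pure red at fraction 0, pure yellow at ½, pure green at 1; linear in
    each half so intermediate inclusion reads as a smooth hue shift.
    """
    f = min(1.0, max(0.0, float(fraction)))
    if f <= 0.5:
        return (255, round(2.0 * f * 255), 0)
    return (round(2.0 * (1.0 - f) * 255), 255, 0)


def residue_inclusion(dmap: DensityMap, model: Model, level: float) -> ResidueInclusion:
    """Per-residue inclusion fractions and colours at one contour level.

    All available atoms of each residue are counted, so trace-only residues
    give a binary result.
    """
    records = []
    for chain, residue in model.residues():
        dens = density_at(dmap, np.vstack([a.position for a in residue.atoms]))
        fraction = float(np.count_nonzero(dens >= level)) / len(residue.atoms)
        records.append(
            ResidueRecord(
                chain_id=chain.chain_id,
                res_id=residue.seq_id,
                fraction=fraction,
                colour=inclusion_colour(fraction),
            )
        )
    return ResidueInclusion(records=records, level=float(level))


def model_inside_fraction(dmap: DensityMap, model: Model, level: float) -> float:
    """Fraction of all model atoms inside the map at ``level``."""
    if model.n_atoms == 0:
        raise ValueError("model has no atoms")
    dens = density_at(dmap, model.atom_positions())
    return float(np.count_nonzero(dens >= level)) / model.n_atoms


def default_display(fraction: float, threshold: float = DEFAULT_DISPLAY_THRESHOLD) -> bool:
    """Whether a fitted model is shown by default: at least 40% inside."""
    return fraction >= threshold


def write_residue_table(result: ResidueInclusion, path) -> None:
    """Export per-residue inclusion as TSV: chain, residue, fraction, hex colour."""
    with open(path, "w") as fh:
        fh.write("chain\tresidue\tfraction\tcolour\n")
        for rec in result.records:
            r, g, b = rec.colour
            fh.write(f"{rec.chain_id}\t{rec.res_id}\t{rec.fraction:.6g}\t#{r:02x}{g:02x}{b:02x}\n")
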