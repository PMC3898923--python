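"""Per-entry analysis orchestration and the machine-readable report.

:func:`analyze_entry` runs every analysis the supplied inputs allow — map
summary, contour level, histogram, enclosed-volume curve, MW-based volume
estimate, FSC, per-model inclusion, per-mask overlap — and aggregates the
results into an :class:`AnalysisReport` serializable as JSON.  Report
generation is deterministic: identical inputs give byte-identical JSON.

Every numeric field in the serialized report carries a units label
("1/A", "nm^3", "count", "density" for map-scale values, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .density_stats import (
    DEFAULT_MASS_DENSITY,
    FSCCurve,
    density_histogram,
    fsc_curve,
    mw_to_volume,
    recommended_contour,
    volume_curve,
)
from .inclusion import (
    DEFAULT_DISPLAY_THRESHOLD,
    atom_inclusion_curve,
    default_display,
    model_inside_fraction,
    residue_inclusion,
)
from .map_io import DensityMap
from .model_tools import Model

__all__ = ["AnalysisReport", "AnalysisError", "analyze_entry", "mask_overlap", "orthogonal_projections"]


class AnalysisError(RuntimeError):
    """An analysis component failed; the message names the component."""


def _q(value, units: str):
    """A number (or list) tagged with its units."""
    if isinstance(value, np.ndarray):
        value = value.tolist()
    return {"value": value, "units": units}


def mask_overlap(dmap: DensityMap, mask: DensityMap, level: float) -> dict:
    """Overlap of a deposited mask with the thresholded map.

    Mask voxels are those with mask value > 0; the summary reports how many
    there are and what fraction of them carry map density ≥ level.
    """
    if dmap.dims != mask.dims:
        raise ValueError(f"mask grid {mask.dims} does not match map grid {dmap.dims}")
    sel = mask.values > 0
    n_mask = int(np.count_nonzero(sel))
    if n_mask == 0:
        frac = 0.0
    else:
        frac = float(np.count_nonzero(dmap.values[sel] >= level)) / n_mask
    return {
        "mask_voxels": _q(n_mask, "count"),
        "fraction_above_level": _q(frac, "fraction"),
        "level": _q(float(level), "density"),
    }


def orthogonal_projections(dmap: DensityMap, mode: str = "sum") -> dict[str, np.ndarray]:
    """Raw 2D arrays of the map viewed along each axis.

    ``mode="sum"`` integrates along the axis (projection); ``mode="central"``
    takes the central section.  These are the numerical substrate of the
    viewer's orthogonal images, returned unrendered.
    """
    v = dmap.values  # (z, y, x)
    if mode == "sum":
        return {"x": v.sum(axis=2), "y": v.sum(axis=1), "z": v.sum(axis=0)}
    if mode == "central":
        nz, ny, nx = v.shape
        return {"x": v[:, :, nx // 2], "y": v[:, ny // 2, :], "z": v[nz // 2]}
    raise ValueError(f"unknown projection mode {mode!r}")


@dataclass
class AnalysisReport:
    """Aggregate of all per-entry statistics; serializes to JSON."""

    data: dict = field(default_factory=dict)

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(self.data, indent=indent, sort_keys=True)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "AnalysisReport":
        with open(path) as fh:
            return cls(json.load(fh))


def _component(name: str):
    """Decorator-free error wrapper: run fn, naming the component on failure."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, AnalysisError):
                raise AnalysisError(f"component '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def analyze_entry(
    dmap: DensityMap,
    models: list[Model] | None = None,
    masks: list[DensityMap] | None = None,
    author_level: float | None = None,
    mw: float | None = None,
    half_maps: tuple[DensityMap, DensityMap] | None = None,
    fsc_table: FSCCurve | None = None,
    mass_density: float = DEFAULT_MASS_DENSITY,
    display_threshold: float = DEFAULT_DISPLAY_THRESHOLD,
) -> AnalysisReport:
    """Run all applicable analyses for one entry.

    The report contains exactly the blocks whose inputs were supplied: map
    statistics, contour level, histogram and volume curve always; an MW
    volume line when ``mw`` is given; an FSC block when half-maps or an
    external FSC table are given; one block per fitted model and per mask.
    """
    report: dict = {
        "tool": {"name": "emva", "version": __version__},
        "parameters": {
            "mass_density": _q(mass_density, "g/cm^3"),
            "display_threshold": _q(display_threshold, "fraction"),
            "inclusion_atom_set": "all_atoms",
        },
    }

    with _component("map_summary"):
        stats = dmap.stats()
        report["map"] = {
            "dims": _q(list(dmap.dims), "voxels"),
            "voxel_size": _q(list(dmap.voxel_size), "A"),
            "origin": _q(list(dmap.origin), "A"),
            "min": _q(stats["min"], "density"),
            "max": _q(stats["max"], "density"),
            "mean": _q(stats["mean"], "density"),
            "sd": _q(stats["sd"], "density"),
        }

    with _component("contour_level"):
        contour = recommended_contour(dmap, author_level)
        report["contour_level"] = {
            "value": _q(contour.value, "density"),
            "source": contour.source.value,
        }

    with _component("histogram"):
        hist = density_histogram(dmap)
        report["histogram"] = {
            "bin_edges": _q(hist.bin_edges, "density"),
            "counts": _q(hist.counts, "count"),
            "degenerate": hist.degenerate,
        }

    with _component("volume_curve"):
        vc = volume_curve(dmap)
        report["volume_curve"] = {
            "levels": _q(vc.levels, "density"),
            "volumes": _q(vc.volumes, "nm^3"),
        }

    if mw is not None:
        with _component("mw_volume"):
            report["mw_volume"] = {
                "molecular_weight": _q(float(mw), "Da"),
                "volume": _q(mw_to_volume(mw, mass_density), "nm^3"),
            }

    if half_maps is not None:
        with _component("fsc"):
            curve = fsc_curve(half_maps[0], half_maps[1])
            report["fsc"] = {
                "source": "half_maps",
                "frequencies": _q(curve.frequencies, "1/A"),
                "correlations": _q(curve.correlations, "fsc"),
                "shell_counts": _q(curve.shell_counts, "count"),
            }
    elif fsc_table is not None:
        with _component("fsc"):
            report["fsc"] = {
                "source": "table",
                "frequencies": _q(fsc_table.frequencies, "1/A"),
                "correlations": _q(fsc_table.correlations, "fsc"),
            }

    if models:
        blocks = []
        for i, model in enumerate(models):
            with _component(f"model[{i}]"):
                curve = atom_inclusion_curve(dmap, model)
                res_inc = residue_inclusion(dmap, model, contour.value)
                frac = model_inside_fraction(dmap, model, contour.value)
                blocks.append(
                    {
                        "model_id": model.model_id,
                        "n_atoms": _q(model.n_atoms, "count"),
                        "n_residues": _q(model.n_residues, "count"),
                        "inclusion_curve": {
                            "levels": _q(curve.levels, "density"),
                            "fraction_all": _q(curve.fraction_all, "fraction"),
                            "fraction_reduced": _q(curve.fraction_reduced, "fraction"),
                            "reduced_kind": curve.reduced_kind,
                        },
                        "residue_inclusion": {
                            "level": _q(res_inc.level, "density"),
                            "n_segments": _q(len(res_inc.segments), "count"),
                            "records": [
                                {
                                    "chain": r.chain_id,
                                    "residue": r.res_id,
                                    "fraction": _q(r.fraction, "fraction"),
                                    "colour": list(r.colour),
                                }
                                for r in res_inc.records
                            ],
                        },
                        "inside_fraction": _q(frac, "fraction"),
                        "default_display": default_display(frac, display_threshold),
                    }
                )
        report["models"] = blocks

    if masks:
        blocks = []
        for i, mask in enumerate(masks):
            with _component(f"mask[{i}]"):
                blocks.append(mask_overlap(dmap, mask, contour.value))
        report["masks"] = blocks

    return AnalysisReport(report)
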