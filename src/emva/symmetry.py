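"""Symmetry expansion of asymmetric-unit models and display filtering.

Deposited EM entries for viruses, helical assemblies and 2D crystals
usually hold one asymmetric unit plus a set of rigid transformations.  The
expansion rules implemented here mirror what an archive viewer displays:

* viruses — a *penton*: the five copies around one 5-fold axis;
* helical entries — five repeats generated from the rise/twist operator;
* 2D crystals — all plane-group copies within one unit cell.

Expanded instances are translated into the map's unit cell, and an
instance is only flagged for display when at least half of its trace atoms
lie inside the rendered surface (interpolated density at or above the
contour level).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .map_io import DensityMap
from .model_tools import SimplifiedModel

__all__ = [
    "SymmetryOperator",
    "Instance",
    "InstanceSet",
    "OperatorError",
    "apply_operator",
    "expand_virus",
    "expand_helical",
    "expand_2d_crystal",
    "translate_to_cell",
    "filter_instances",
    "helical_operator",
    "rotation_about_axis",
    "parse_biomt",
    "read_operators_json",
    "write_operators_json",
    "PLANE_GROUPS",
]

_ORTHO_TOL = 1e-6


class OperatorError(ValueError):
    """Raised for invalid symmetry operators or operator sets."""


@dataclass
class SymmetryOperator:
    """Rigid transform p ↦ R·p + t with a proper rotation R."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray = None  # (3,), Å

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        if self.translation is None:
            self.translation = np.zeros(3)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise OperatorError("operator needs a 3x3 rotation and 3-vector translation")
        self.validate()

    def validate(self) -> None:
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=_ORTHO_TOL):
            raise OperatorError("rotation matrix is not orthonormal")
        if not math.isclose(float(np.linalg.det(r)), 1.0, abs_tol=_ORTHO_TOL):
            raise OperatorError("rotation matrix determinant is not +1")

    @classmethod
    def identity(cls) -> "SymmetryOperator":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return positions @ self.rotation.T + self.translation

    def compose(self, other: "SymmetryOperator") -> "SymmetryOperator":
        """self ∘ other: apply ``other`` first."""
        return SymmetryOperator(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @property
    def angle_deg(self) -> float:
        """Rotation angle in degrees (0..180)."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, c))))

    @property
    def axis(self) -> np.ndarray | None:
        """Unit rotation axis, or None for the identity."""
        w, v = np.linalg.eig(self.rotation)
        idx = int(np.argmin(np.abs(w - 1.0)))
        axis = np.real(v[:, idx])
        n = np.linalg.norm(axis)
        if self.angle_deg < 1e-6 or n == 0:
            return None
        return axis / n


@dataclass
class Instance:
    operator: SymmetryOperator
    model: SimplifiedModel
    display: bool = True


@dataclass
class InstanceSet:
    instances: list[Instance] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)

    def displayed(self) -> list[Instance]:
        return [inst for inst in self.instances if inst.display]


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise OperatorError("rotation axis must be non-zero")
    x, y, z = axis / n
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + s * k + (1 - c) * np.outer([x, y, z], [x, y, z])


def apply_operator(model: SimplifiedModel, op: SymmetryOperator) -> SimplifiedModel:
    """Transform every trace position by the operator; annotations kept."""
    op.validate()
    return model.with_positions(op.apply(model.positions()))


def expand_virus(model: SimplifiedModel, ops) -> InstanceSet:
    """Generate a penton: the five copies around one 5-fold axis.

    ``ops`` must be the five operators of a C5 group about a common axis
    (identity included), e.g. extracted from the entry's BIOMT matrices.
    """
    ops = list(ops)
    if len(ops) != 5:
        raise OperatorError(f"a penton needs exactly 5 operators, got {len(ops)}")
    angles = sorted(round(op.angle_deg, 3) for op in ops)
    expected = [0.0, 72.0, 72.0, 144.0, 144.0]  # ±72°, ±144° fold onto 0..180
    if not np.allclose(angles, expected, atol=1e-3):
        raise OperatorError(
            f"operator rotation angles {angles} do not form a C5 group "
            "(expected multiples of 72 degrees)"
        )
    axes = [op.axis for op in ops if op.axis is not None]
    for a, b in zip(axes, axes[1:]):
        if abs(abs(float(a @ b)) - 1.0) > 1e-6:
            raise OperatorError("C5 operators do not share a common rotation axis")
    return InstanceSet([Instance(op, apply_operator(model, op)) for op in ops])


def helical_operator(rise: float, twist: float, axis=(0.0, 0.0, 1.0)) -> SymmetryOperator:
    """One helical repeat: rotate by ``twist`` about the axis, shift ``rise`` along it."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return SymmetryOperator(rotation_about_axis(axis, twist), rise * axis)


def expand_helical(
    model: SimplifiedModel,
    rise: float,
    twist: float,
    n_repeats: int = 5,
    axis=(0.0, 0.0, 1.0),
) -> InstanceSet:
    """Generate helical repeats (five by default, identity first).

    Instance k is transformed by k applications of the (twist, rise)
    screw operator; the deposited copy counts as instance 0.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if rise == 0 and twist == 0:
        raise ValueError("helical symmetry needs a non-zero rise or twist")
    gen = helical_operator(rise, twist, axis)
    instances = []
    op = SymmetryOperator.identity()
    for _ in range(n_repeats):
        instances.append(Instance(op, apply_operator(model, op)))
        op = gen.compose(op)
    return InstanceSet(instances)


# Plane groups as pure in-plane rotation sets (two-sided plane-group
# convention: p121 / p222 include the in-plane 2-fold about the b axis that
# flips the z direction).
PLANE_GROUPS: dict[str, list[tuple]] = {
    "p1": [((0, 0, 1), 0.0)],
    "p2": [((0, 0, 1), 0.0), ((0, 0, 1), 180.0)],
    "p121": [((0, 0, 1), 0.0), ((0, 1, 0), 180.0)],
    "p222": [((0, 0, 1), 0.0), ((0, 0, 1), 180.0), ((0, 1, 0), 180.0), ((1, 0, 0), 180.0)],
    "p4": [((0, 0, 1), a) for a in (0.0, 90.0, 180.0, 270.0)],
    "p6": [((0, 0, 1), a) for a in (0.0, 60.0, 120.0, 180.0, 240.0, 300.0)],
}


def expand_2d_crystal(model: SimplifiedModel, plane_group: str, cell) -> InstanceSet:
    """Generate all plane-group copies, translated into the reference cell.

    ``cell`` gives the two in-plane cell vectors (Å) as a (2, 3) array.
    Copies whose centroid falls outside the cell footprint are shifted back
    by whole cell vectors.
    """
    symbol = plane_group.strip().lower()
    if symbol not in PLANE_GROUPS:
        raise ValueError(
            f"unsupported plane group {plane_group!r}; supported: "
            f"{', '.join(sorted(PLANE_GROUPS))}"
        )
    cell = np.asarray(cell, dtype=float)
    if cell.shape != (2, 3):
        raise ValueError("cell must hold two in-plane 3-vectors")
    instances = []
    for axis, angle in PLANE_GROUPS[symbol]:
        op = SymmetryOperator(rotation_about_axis(axis, angle), np.zeros(3))
        transformed = apply_operator(model, op)
        # shift centroid into the unit-cell footprint spanned by the cell vectors
        pos = transformed.positions()
        if len(pos):
            centroid = pos.mean(axis=0)
            ab = cell[:, :2]  # in-plane components
            frac = np.linalg.solve(ab.T, centroid[:2])
            shift = -np.floor(frac) @ cell
            op = SymmetryOperator(op.rotation, op.translation + shift)
            transformed = transformed.with_positions(pos + shift)
        instances.append(Instance(op, transformed))
    return InstanceSet(instances)


def translate_to_cell(instances: InstanceSet, dmap: DensityMap) -> InstanceSet:
    """Shift each instance by whole box lengths so its centroid is inside the map.

    The EM volume's unit cell is its axis-aligned bounding box (origin to
    origin + extent); shifts are integer multiples of the box edge vectors.
    """
    origin = np.asarray(dmap.origin)
    extent = np.asarray(dmap.extent)
    out = []
    for inst in instances:
        pos = inst.model.positions()
        if len(pos) == 0:
            out.append(inst)
            continue
        centroid = pos.mean(axis=0)
        n_cells = np.floor((centroid - origin) / extent)
        shift = -n_cells * extent
        if np.any(shift != 0):
            op = SymmetryOperator(inst.operator.rotation, inst.operator.translation + shift)
            out.append(Instance(op, inst.model.with_positions(pos + shift), inst.display))
        else:
            out.append(inst)
    return InstanceSet(out)


def filter_instances(instances: InstanceSet, dmap: DensityMap, level: float) -> InstanceSet:
    """Flag instances for display when ≥ half their trace atoms are inside.

    "Inside" means interpolated map density at the trace position is at or
    above the contour level.
    """
    from .inclusion import density_at

    out = []
    for inst in instances:
        pos = inst.model.positions()
        if len(pos) == 0:
            out.append(Instance(inst.operator, inst.model, False))
            continue
        inside = int(np.count_nonzero(density_at(dmap, pos) >= level))
        out.append(Instance(inst.operator, inst.model, inside / len(pos) >= 0.5))
    return InstanceSet(out)


# ---------------------------------------------------------------------------
# Operator I/O


def parse_biomt(path) -> list[SymmetryOperator]:
    """Extract BIOMT operators from a PDB file's REMARK 350 records."""
    rows: dict[int, list[tuple[list[float], float]]] = {}
    with open(path, "r", errors="replace") as fh:
        for line in fh:
            if not line.startswith("REMARK 350   BIOMT"):
                continue
            parts = line.split()
            # REMARK 350   BIOMTn  serial  r1 r2 r3  t
            row = int(parts[2][5:])  # 1, 2 or 3
            serial = int(parts[3])
            vals = [float(v) for v in parts[4:8]]
            rows.setdefault(serial, [None, None, None])[row - 1] = (vals[:3], vals[3])
    ops = []
    for serial in sorted(rows):
        triple = rows[serial]
        if any(r is None for r in triple):
            raise OperatorError(f"incomplete BIOMT matrix {serial}")
        rot = np.array([r[0] for r in triple])
        trans = np.array([r[1] for r in triple])
        ops.append(SymmetryOperator(rot, trans))
    return ops


def read_operators_json(path) -> list[SymmetryOperator]:
    """Read operators from JSON: [{"rotation": [[...]x3], "translation": [...]}]."""
    with open(path) as fh:
        data = json.load(fh)
    return [
        SymmetryOperator(np.array(entry["rotation"]), np.array(entry.get("translation", [0, 0, 0])))
        for entry in data
    ]


def write_operators_json(ops, path) -> None:
    data = [
        {"rotation": op.rotation.tolist(), "translation": op.translation.tolist()}
        for op in ops
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
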