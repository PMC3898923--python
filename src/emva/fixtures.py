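"""Synthetic maps, models, masks and operator sets with known ground truth.

Everything here is seed-deterministic: identical parameters and seed
regenerate byte-identical fixtures.  The generators trade physical realism
for controllable ground truth — atom densities are unit-amplitude isotropic
Gaussians with no element weighting, noise is white, and there is no CTF or
missing wedge — which is exactly what exact tests of the analysis
operations need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .map_io import DensityMap
from .model_tools import Atom, Chain, Model, Residue, ResidueClass
from .symmetry import SymmetryOperator, helical_operator

__all__ = [
    "FixtureSpec",
    "build_fixture",
    "synth_map_from_model",
    "make_masked_map",
    "make_noise_map",
    "make_toy_helix",
    "make_toy_pentamer",
    "make_toy_protein",
    "make_inclusion_pair",
]


@dataclass
class FixtureSpec:
    """Declarative fixture request: a kind, its parameters, and a seed."""

    kind: str
    parameters: dict = dc_field(default_factory=dict)
    seed: int = 0

    KINDS = (
        "blob_map",
        "model_map",
        "noise_map",
        "masked_map",
        "toy_helix",
        "toy_pentamer",
        "toy_protein",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {self.KINDS}")


def build_fixture(spec: FixtureSpec):
    """Materialize a :class:`FixtureSpec`; dispatches on ``spec.kind``."""
    p = dict(spec.parameters)
    if spec.kind == "noise_map":
        return make_noise_map(seed=spec.seed, **p)
    if spec.kind == "masked_map":
        p.setdefault("dims", (24, 24, 24))
        p.setdefault("blob_center", (12.0, 12.0, 12.0))
        p.setdefault("blob_radius", 6.0)
        return make_masked_map(seed=spec.seed, **p)
    if spec.kind == "blob_map":
        p.setdefault("dims", (24, 24, 24))
        p.setdefault("blob_center", tuple(d / 2 for d in p["dims"]))
        p.setdefault("blob_radius", min(p["dims"]) / 4)
        return make_masked_map(seed=spec.seed, noise=0.0, **p)
    if spec.kind == "toy_protein":
        return make_toy_protein(seed=spec.seed, **p)
    if spec.kind == "toy_helix":
        return make_toy_helix(seed=spec.seed, **p)
    if spec.kind == "toy_pentamer":
        return make_toy_pentamer(seed=spec.seed, **p)
    if spec.kind == "model_map":
        model = make_toy_protein(seed=spec.seed, n_residues=p.pop("n_residues", 10))
        return synth_map_from_model(model, **p)
    raise AssertionError("unreachable")


def synth_map_from_model(
    model: Model,
    voxel_size: float = 1.0,
    padding: float = 5.0,
    sigma: float = 1.5,
) -> DensityMap:
    """Gaussian-atom density map covering the model's bounding box.

    Density is the sum over atoms of unit-amplitude isotropic Gaussians of
    width ``sigma`` (Å); the grid spans the model bounding box plus
    ``padding`` on every side.
    """
    if model.n_atoms == 0:
        raise ValueError("model has no atoms")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pos = model.atom_positions()
    lo = pos.min(axis=0) - padding
    hi = pos.max(axis=0) + padding
    dims = np.maximum(2, np.ceil((hi - lo) / voxel_size).astype(int) + 1)
    nx, ny, nz = int(dims[0]), int(dims[1]), int(dims[2])

    x = lo[0] + np.arange(nx) * voxel_size
    y = lo[1] + np.arange(ny) * voxel_size
    z = lo[2] + np.arange(nz) * voxel_size
    values = np.zeros((nz, ny, nx))
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for p in pos:
        gx = np.exp(-((x - p[0]) ** 2) * inv2s2)
        gy = np.exp(-((y - p[1]) ** 2) * inv2s2)
        gz = np.exp(-((z - p[2]) ** 2) * inv2s2)
        values += gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return DensityMap(values, voxel_size=(voxel_size,) * 3, origin=tuple(lo))


def make_noise_map(
    dims=(16, 16, 16), voxel_size: float = 1.0, sigma: float = 1.0, seed: int = 0
) -> DensityMap:
    """White Gaussian noise map (mean 0, sd ``sigma``)."""
    rng = np.random.default_rng(seed)
    nx, ny, nz = dims
    return DensityMap(
        rng.normal(0.0, sigma, size=(nz, ny, nx)),
        voxel_size=(voxel_size,) * 3,
    )


def make_masked_map(
    dims=(24, 24, 24),
    blob_center=(12.0, 12.0, 12.0),
    blob_radius: float = 6.0,
    seed: int = 0,
    voxel_size: float = 1.0,
    noise: float = 0.2,
) -> DensityMap:
    """Masked-volume mimic: exact zeros outside a noisy positive blob.

    Its histogram shows the sharp spike at zero that flags masking in
    deposited maps.
    """
    nx, ny, nz = dims
    cx, cy, cz = blob_center
    if not (0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz):
        raise ValueError("blob center must lie inside the grid")
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
    inside = r2 <= blob_radius**2
    values = np.zeros((nz, ny, nx))
    if np.any(inside):
        blob = 1.0 + np.clip(rng.normal(0.0, noise, size=int(inside.sum())), -0.9, None)
        values[inside] = blob
    return DensityMap(values, voxel_size=(voxel_size,) * 3)


def _poly_ala_chain(positions: np.ndarray, chain_id: str = "A") -> Model:
    """Poly-alanine trace model: one CA atom per residue at each position."""
    residues = [
        Residue(
            name="ALA",
            seq_id=i + 1,
            res_class=ResidueClass.AMINO,
            atoms=[Atom("CA", "C", p)],
        )
        for i, p in enumerate(positions)
    ]
    return Model([Chain(chain_id, residues)])


def make_toy_protein(
    n_residues: int = 10, seed: int = 0, full_backbone: bool = False, spacing: float = 3.8
) -> Model:
    """Random self-avoiding-ish poly-alanine walk; optionally with N/CA/C/O."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_residues, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    ca = np.cumsum(steps * spacing, axis=0)
    if not full_backbone:
        return _poly_ala_chain(ca)
    residues = []
    for i, p in enumerate(ca):
        atoms = [
            Atom("N", "N", p + [-1.4, 0.0, 0.0]),
            Atom("CA", "C", p),
            Atom("C", "C", p + [1.5, 0.0, 0.0]),
            Atom("O", "O", p + [1.5, 1.2, 0.0]),
            Atom("CB", "C", p + [0.0, -1.5, 0.0]),
        ]
        residues.append(Residue("ALA", i + 1, ResidueClass.AMINO, atoms))
    return Model([Chain("A", residues)])


def make_toy_helix(
    n_residues: int = 20,
    rise: float = 1.408,
    twist: float = 22.03,
    seed: int = 0,
    radius: float = 10.0,
) -> tuple[Model, list[SymmetryOperator]]:
    """Poly-alanine trace on a helix, with the matching repeat operators.

    Residue k sits at (r·cos kθ, r·sin kθ, k·rise); the returned operators
    are the identity plus powers of the one-repeat screw, so applying
    operator 1 maps residue k onto residue k+1.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    theta = math.radians(twist)
    ks = np.arange(n_residues)
    positions = np.column_stack(
        [radius * np.cos(ks * theta), radius * np.sin(ks * theta), ks * rise]
    )
    gen = helical_operator(rise, twist)
    ops = [SymmetryOperator.identity()]
    for _ in range(4):
        ops.append(gen.compose(ops[-1]))
    return _poly_ala_chain(positions), ops


def make_toy_pentamer(
    seed: int = 0, radius: float = 10.0, n_residues: int = 3
) -> tuple[Model, list[SymmetryOperator]]:
    """One subunit off a 5-fold z axis, plus the C5 operator set."""
    rng = np.random.default_rng(seed)
    base = np.array([radius, 0.0, 0.0]) + rng.normal(0, 1.0, size=(n_residues, 3))
    from .symmetry import rotation_about_axis

    ops = [
        SymmetryOperator(rotation_about_axis((0, 0, 1), 72.0 * k), np.zeros(3))
        for k in range(5)
    ]
    return _poly_ala_chain(base), ops


def make_inclusion_pair(
    n_atoms: int, fraction_inside: float, seed: int = 0
) -> tuple[DensityMap, Model, float]:
    """Map and model with an exactly known inside fraction.

    Atoms sit at voxel centers: the designated inside atoms on voxels of
    density 2, the rest on zero voxels, so at the returned reference level
    (1.0) exactly ``round(n_atoms · fraction_inside)`` atoms are inside and
    the rest strictly below the level.
    """
    if not 0.0 <= fraction_inside <= 1.0:
        raise ValueError("fraction_inside must be in [0, 1]")
    target = n_atoms * fraction_inside
    n_inside = round(target)
    if abs(target - n_inside) > 1e-9:
        raise ValueError("n_atoms * fraction_inside must be integral")

    rng = np.random.default_rng(seed)
    nx = 2 * n_atoms + 3
    values = np.zeros((5, 5, nx))
    level = 1.0

    xs = 1 + 2 * np.arange(n_atoms)  # voxel centers, two apart along x
    which_inside = rng.permutation(n_atoms) < n_inside
    values[2, 2, xs[which_inside]] = 2.0

    dmap = DensityMap(values, voxel_size=(1.0, 1.0, 1.0))
    # atom (x, y, z) in Å = voxel indices with unit voxels and zero origin
    positions = np.column_stack(
        [xs.astype(float), np.full(n_atoms, 2.0), np.full(n_atoms, 2.0)]
    )
    return dmap, _poly_ala_chain(positions), level
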