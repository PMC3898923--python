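"""Atomic model parsing, backbone classification, trace-atom simplification.

Models fitted into EM maps are reduced to one *trace atom* per residue for
lightweight display and coarse analysis: CA for amino acids, P for
nucleotides, and the first atom in file order for any other compound.
Backbone atoms are N, CA, C, O for amino acids and C3', C4', C5', O3',
O5', P for nucleotides (primed names are accepted in prime, Unicode-prime
and legacy asterisk spellings); for any other residue the backbone is its
first atom.

PDB files are parsed with gemmi; only the first model of multi-model files
is used.  Residues are classified as amino / nucleotide / other from
gemmi's tabulated chemical-component information.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "ResidueClass",
    "Atom",
    "Residue",
    "Chain",
    "Model",
    "SimplifiedEntry",
    "SimplifiedModel",
    "ModelParseError",
    "AMINO_BACKBONE",
    "NUCLEOTIDE_BACKBONE",
    "read_model",
    "write_model",
    "trace_atom",
    "is_backbone",
    "backbone_atoms",
    "simplify",
]


class ResidueClass(enum.Enum):
    AMINO = "amino"
    NUCLEOTIDE = "nucleotide"
    OTHER = "other"


class ModelParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


AMINO_BACKBONE = frozenset({"N", "CA", "C", "O", "CO"})
NUCLEOTIDE_BACKBONE = frozenset({"C3'", "C4'", "C5'", "O3'", "O5'", "P"})


def _normalize_atom_name(name: str) -> str:
    """Uppercase and map asterisk / Unicode-prime dialects to ASCII prime."""
    return name.strip().upper().replace("*", "'").replace("′", "'")


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # (3,) Å

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")


@dataclass
class Residue:
    name: str
    seq_id: int
    res_class: ResidueClass
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Model:
    chains: list[Chain] = field(default_factory=list)
    model_id: str = "1"

    def residues(self):
        for chain in self.chains:
            for residue in chain.residues:
                yield chain, residue

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def atom_positions(self) -> np.ndarray:
        """All atom positions in model order, shape (n_atoms, 3)."""
        pos = [a.position for c in self.chains for r in c.residues for a in r.atoms]
        if not pos:
            return np.empty((0, 3))
        return np.vstack(pos)


@dataclass
class SimplifiedEntry:
    """One trace atom with its provenance annotations and display colour."""

    model_id: str
    chain_id: str
    res_id: int
    res_name: str
    position: np.ndarray  # (3,) Å
    colour: tuple[int, int, int] = (128, 128, 128)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class SimplifiedModel:
    entries: list[SimplifiedEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def positions(self) -> np.ndarray:
        if not self.entries:
            return np.empty((0, 3))
        return np.vstack([e.position for e in self.entries])

    def with_positions(self, positions: np.ndarray) -> "SimplifiedModel":
        """Copy with new trace positions, annotations preserved."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.entries), 3):
            raise ValueError("position array shape must match entry count")
        return SimplifiedModel(
            [
                SimplifiedEntry(e.model_id, e.chain_id, e.res_id, e.res_name, p, e.colour)
                for e, p in zip(self.entries, positions)
            ]
        )


def _classify(residue_name: str) -> ResidueClass:
    info = gemmi.find_tabulated_residue(residue_name)
    if info is not None:
        if info.is_amino_acid():
            return ResidueClass.AMINO
        if info.is_nucleic_acid():
            return ResidueClass.NUCLEOTIDE
    return ResidueClass.OTHER


def _prescan_pdb(path) -> None:
    # gemmi is permissive; reject coordinate records with unparseable
    # coordinate fields up front so the error can carry a line number
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ModelParseError(f"line {lineno}: coordinate record too short")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise ModelParseError(
                    f"line {lineno}: unparseable coordinates in "
                    f"{line[:6].strip()} record"
                ) from None


def read_model(path) -> Model:
    """Read a PDB-format file into a :class:`Model`.

    Only the first model of a multi-model file is kept.  Residue classes
    are assigned from standard residue-name tables.
    """
    _prescan_pdb(path)
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ModelParseError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(structure) == 0:
        return Model(model_id="1")
    gmodel = structure[0]
    chains = []
    for gchain in gmodel:
        residues = []
        for gres in gchain:
            atoms = [
                Atom(
                    name=_normalize_atom_name(ga.name),
                    element=ga.element.name,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                )
                for ga in gres
            ]
            if not atoms:
                continue
            residues.append(
                Residue(
                    name=gres.name,
                    seq_id=gres.seqid.num,
                    res_class=_classify(gres.name),
                    atoms=atoms,
                )
            )
        chains.append(Chain(chain_id=gchain.name, residues=residues))
    model_id = getattr(gmodel, "name", None) or getattr(gmodel, "num", 1)
    return Model(chains=chains, model_id=str(model_id))


def write_model(model: Model, path) -> None:
    """Write a :class:`Model` as minimal PDB ATOM/HETATM records."""
    with open(path, "w") as fh:
        serial = 0
        for chain in model.chains:
            for residue in chain.residues:
                record = "ATOM" if residue.res_class != ResidueClass.OTHER else "HETATM"
                for atom in residue.atoms:
                    serial += 1
                    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                    fh.write(
                        f"{record:<6s}{serial:>5d} {name:<4s}"
                        f"{residue.name:>4s}{chain.chain_id[:1]:>2s}"
                        f"{residue.seq_id:>4d}    "
                        f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}"
                        f"{atom.position[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {atom.element:>2s}\n"
                    )
            fh.write("TER\n")
        fh.write("END\n")


def trace_atom(residue: Residue) -> Atom:
    """The residue's representative atom for coarse display.

    CA for amino acids, P for nucleotides, the first atom for any other
    compound; falls back to the first atom if the designated one is absent.
    """
    if not residue.atoms:
        raise ValueError("residue has no atoms")
    wanted = {
        ResidueClass.AMINO: "CA",
        ResidueClass.NUCLEOTIDE: "P",
    }.get(residue.res_class)
    if wanted is not None:
        for atom in residue.atoms:
            if _normalize_atom_name(atom.name) == wanted:
                return atom
    return residue.atoms[0]


def is_backbone(atom_name: str, residue_class: ResidueClass, is_first_atom: bool = False) -> bool:
    """Whether an atom belongs to the residue backbone.

    For residues that are neither amino acids nor nucleotides, only the
    first atom of the residue counts as backbone (``is_first_atom``).
    """
    name = _normalize_atom_name(atom_name)
    if residue_class == ResidueClass.AMINO:
        return name in AMINO_BACKBONE
    if residue_class == ResidueClass.NUCLEOTIDE:
        return name in NUCLEOTIDE_BACKBONE
    return is_first_atom


def backbone_atoms(residue: Residue) -> list[Atom]:
    return [
        atom
        for i, atom in enumerate(residue.atoms)
        if is_backbone(atom.name, residue.res_class, is_first_atom=(i == 0))
    ]


def has_full_backbone(residue: Residue) -> bool:
    """True when the residue contains its class's complete backbone set."""
    names = {_normalize_atom_name(a.name) for a in residue.atoms}
    if residue.res_class == ResidueClass.AMINO:
        return {"N", "CA", "C"}.issubset(names) and bool(names & {"O", "CO"})
    if residue.res_class == ResidueClass.NUCLEOTIDE:
        return NUCLEOTIDE_BACKBONE.issubset(names)
    return False


def simplify(model: Model, colour: tuple[int, int, int] = (0, 0, 255)) -> SimplifiedModel:
    """Reduce a model to one trace atom per residue, with annotations."""
    entries = [
        SimplifiedEntry(
            model_id=model.model_id,
            chain_id=chain.chain_id,
            res_id=residue.seq_id,
            res_name=residue.name,
            position=trace_atom(residue).position.copy(),
            colour=colour,
        )
        for chain, residue in model.residues()
    ]
    return SimplifiedModel(entries)
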