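"""PDB coordinate parsing and the typed structure model.

Parsing is delegated to gemmi; on top of it this module applies the policies
the density analysis needs: first MODEL only, one conformer per atom
(highest occupancy, ties broken toward altloc 'A'), heavy-atom typing into
the 13 classes, and hydrogen-folded electron counts.  Waters and other
hetero atoms are kept apart: they never enter the density-ratio statistics
but do count toward the F000 estimate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable

import gemmi
import numpy as np

from .atomtypes import (
    ELEMENT_ELECTRONS,
    STANDARD_RESIDUES,
    WATER_RESIDUES,
    UnclassifiableAtomError,
    classify_atom,
    electron_count,
)
from .cell import UnitCell


class EmptyStructureError(ValueError):
    """No ATOM/HETATM records found."""


@dataclass
class AtomRecord:
    """One coordinate record after altloc resolution."""

    serial: int
    name: str
    altloc: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    xyz: np.ndarray
    occupancy: float
    b_factor: float
    element: str
    hetero: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code, self.residue_name)


@dataclass
class TypedAtom(AtomRecord):
    """Atom with its type class and hydrogen-folded electron count."""

    atom_type: str = ""
    electrons: int = 0


@dataclass
class StructureModel:
    """Typed protein atoms plus waters/hetero atoms and crystal metadata."""

    atoms: list[TypedAtom]
    waters: list[AtomRecord] = field(default_factory=list)
    hetero: list[AtomRecord] = field(default_factory=list)
    cell: UnitCell | None = None
    space_group: str = "P 1"

    def chains(self) -> dict[str, list[TypedAtom]]:
        out: dict[str, list[TypedAtom]] = {}
        for a in self.atoms:
            out.setdefault(a.chain_id, []).append(a)
        return out

    def residues(self) -> dict[tuple, list[TypedAtom]]:
        out: dict[tuple, list[TypedAtom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms]).reshape(-1, 3)


def _iter_first_model(st: gemmi.Structure):
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                yield chain, residue, atom


def parse_structure(source: str | bytes | io.TextIOBase, lenient: bool = True) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only the first MODEL is used.  For alternate locations the
    highest-occupancy conformer is kept (ties resolved toward altloc 'A');
    its stated occupancy is retained for the occupancy adjustment downstream.
    """
    if hasattr(source, "read"):
        source = source.read()
    if isinstance(source, bytes):
        source = source.decode("ascii", errors="replace")
    try:
        st = gemmi.read_pdb_string(source)
    except (RuntimeError, ValueError) as exc:
        raise EmptyStructureError(f"unparsable PDB text: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError("no ATOM/HETATM records")
    st.setup_entities()

    # altloc resolution: best conformer per (chain, residue, atom name)
    best: dict[tuple, tuple] = {}
    serial = 0
    for chain, residue, atom in _iter_first_model(st):
        serial += 1
        if atom.element.name == "H" or atom.element.name == "D":
            continue
        altloc = atom.altloc if atom.altloc not in ("\x00", "") else ""
        key = (chain.name, residue.seqid.num, residue.seqid.icode.strip(),
               residue.name, atom.name)
        rank = (atom.occ, -ord(altloc) if altloc else 0)
        if key not in best or rank > best[key][0]:
            best[key] = (rank, serial, chain, residue, atom, altloc)
    if not best:
        raise EmptyStructureError("no heavy atoms in the first model")

    cell = None
    if st.cell and st.cell.is_crystal():
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
    space_group = st.spacegroup_hm or "P 1"

    atoms: list[TypedAtom] = []
    waters: list[AtomRecord] = []
    hetero: list[AtomRecord] = []
    for (_, serial, chain, residue, atom, altloc) in sorted(
        best.values(), key=lambda v: v[1]
    ):
        element = atom.element.name.upper() or _infer_element(atom.name)
        rec = AtomRecord(
            serial=serial,
            name=atom.name,
            altloc=altloc,
            residue_name=residue.name,
            chain_id=chain.name,
            residue_seq=residue.seqid.num,
            insertion_code=residue.seqid.icode.strip(),
            xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
            occupancy=float(atom.occ),
            b_factor=float(atom.b_iso),
            element=element,
            hetero=residue.het_flag == "H",
        )
        if rec.residue_name in WATER_RESIDUES:
            waters.append(rec)
            continue
        if rec.residue_name not in STANDARD_RESIDUES:
            hetero.append(rec)
            continue
        try:
            atom_type = classify_atom(rec.residue_name, rec.name)
            z = electron_count(rec.residue_name, rec.name, rec.element)
        except UnclassifiableAtomError:
            if not lenient:
                raise
            hetero.append(rec)
            continue
        atoms.append(TypedAtom(**rec.__dict__, atom_type=atom_type, electrons=z))

    return StructureModel(atoms=atoms, waters=waters, hetero=hetero,
                          cell=cell, space_group=space_group)


def _infer_element(atom_name: str) -> str:
    stripped = "".join(c for c in atom_name if c.isalpha())
    if stripped[:2].upper() in ELEMENT_ELECTRONS:
        return stripped[:2].upper()
    return stripped[:1].upper()


def element_electrons(rec: AtomRecord) -> int:
    """Element-only electron count; water oxygens fold their two hydrogens."""
    base = ELEMENT_ELECTRONS.get(rec.element.upper())
    if base is None:
        base = gemmi.Element(rec.element.capitalize()).atomic_number
    if rec.residue_name in WATER_RESIDUES and rec.element.upper() == "O":
        return base + 2
    return base


def write_pdb(model: StructureModel) -> str:
    """Serialize a model to fixed-width PDB v3.3 text."""
    lines = []
    if model.cell is not None:
        a, b, c, al, be, ga = model.cell.parameters
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} "
            f"{model.space_group:<11s}{1:4d}"
        )
    serial = 0
    records: Iterable[AtomRecord] = [*model.atoms, *model.waters, *model.hetero]
    last_chain = None
    for rec in records:
        serial += 1
        if last_chain is not None and rec.chain_id != last_chain and not rec.hetero:
            lines.append("TER")
        last_chain = rec.chain_id
        name = rec.name if len(rec.name) == 4 else f" {rec.name:<3s}"
        tag = "HETATM" if rec.hetero else "ATOM  "
        lines.append(
            f"{tag}{serial:5d} {name}{rec.altloc or ' '}{rec.residue_name:>3s} "
            f"{rec.chain_id:1s}{rec.residue_seq:4d}{rec.insertion_code or ' ':1s}   "
            f"{rec.xyz[0]:8.3f}{rec.xyz[1]:8.3f}{rec.xyz[2]:8.3f}"
            f"{rec.occupancy:6.2f}{rec.b_factor:6.2f}          {rec.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
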