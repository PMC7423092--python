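"""Heavy-atom typing and electron counting for the 20 standard amino acids.

Each heavy atom of a standard residue is assigned one of 13 atom types
reflecting its element and bonding character ("_bb" marks backbone atoms);
hydrogens, which are not resolvable in typical electron density maps, are
folded into the electron count of the heavy atom they bond to.  Protonation
follows conventional pH-7 states: Lys/Arg protonated, Asp/Glu carboxylates
deprotonated, His neutral with the ring proton on ND1.
"""

from __future__ import annotations

ATOM_TYPES: tuple[str, ...] = (
    "C_double",
    "C_double_bb",
    "C_intermediate",
    "C_single",
    "C_single_bb",
    "N_intermediate",
    "N_single",
    "N_single_bb",
    "O_double",
    "O_double_bb",
    "O_intermediate",
    "O_single",
    "S_single",
)

ELEMENT_ELECTRONS = {"C": 6, "N": 7, "O": 8, "S": 16, "H": 1, "P": 15}

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class UnclassifiableAtomError(KeyError):
    """Atom outside the 20-residue/13-type vocabulary."""


# (atom_type, bonded hydrogens) for backbone atoms; CA and N have
# residue-specific hydrogen counts handled in `_lookup`.
_BACKBONE = {
    "N": ("N_single_bb", 1),
    "CA": ("C_single_bb", 1),
    "C": ("C_double_bb", 0),
    "O": ("O_double_bb", 0),
    "OXT": ("O_intermediate", 0),
}

# side chains: atom -> (atom_type, bonded hydrogens)
_SIDE_CHAINS: dict[str, dict[str, tuple[str, int]]] = {
    "ALA": {"CB": ("C_single", 3)},
    "ARG": {
        "CB": ("C_single", 2), "CG": ("C_single", 2), "CD": ("C_single", 2),
        "NE": ("N_intermediate", 1), "CZ": ("C_intermediate", 0),
        "NH1": ("N_intermediate", 2), "NH2": ("N_intermediate", 2),
    },
    "ASN": {
        "CB": ("C_single", 2), "CG": ("C_double", 0),
        "OD1": ("O_double", 0), "ND2": ("N_intermediate", 2),
    },
    "ASP": {
        "CB": ("C_single", 2), "CG": ("C_intermediate", 0),
        "OD1": ("O_intermediate", 0), "OD2": ("O_intermediate", 0),
    },
    "CYS": {"CB": ("C_single", 2), "SG": ("S_single", 1)},
    "GLN": {
        "CB": ("C_single", 2), "CG": ("C_single", 2), "CD": ("C_double", 0),
        "OE1": ("O_double", 0), "NE2": ("N_intermediate", 2),
    },
    "GLU": {
        "CB": ("C_single", 2), "CG": ("C_single", 2), "CD": ("C_intermediate", 0),
        "OE1": ("O_intermediate", 0), "OE2": ("O_intermediate", 0),
    },
    "GLY": {},
    "HIS": {
        "CB": ("C_single", 2), "CG": ("C_intermediate", 0),
        "ND1": ("N_intermediate", 1), "CD2": ("C_intermediate", 1),
        "CE1": ("C_intermediate", 1), "NE2": ("N_intermediate", 0),
    },
    "ILE": {
        "CB": ("C_single", 1), "CG1": ("C_single", 2),
        "CG2": ("C_single", 3), "CD1": ("C_single", 3),
    },
    "LEU": {
        "CB": ("C_single", 2), "CG": ("C_single", 1),
        "CD1": ("C_single", 3), "CD2": ("C_single", 3),
    },
    "LYS": {
        "CB": ("C_single", 2), "CG": ("C_single", 2), "CD": ("C_single", 2),
        "CE": ("C_single", 2), "NZ": ("N_single", 3),
    },
    "MET": {
        "CB": ("C_single", 2), "CG": ("C_single", 2),
        "SD": ("S_single", 0), "CE": ("C_single", 3),
    },
    "PHE": {
        "CB": ("C_single", 2), "CG": ("C_intermediate", 0),
        "CD1": ("C_intermediate", 1), "CD2": ("C_intermediate", 1),
        "CE1": ("C_intermediate", 1), "CE2": ("C_intermediate", 1),
        "CZ": ("C_intermediate", 1),
    },
    "PRO": {"CB": ("C_single", 2), "CG": ("C_single", 2), "CD": ("C_single", 2)},
    "SER": {"CB": ("C_single", 2), "OG": ("O_single", 1)},
    "THR": {"CB": ("C_single", 1), "OG1": ("O_single", 1), "CG2": ("C_single", 3)},
    "TRP": {
        "CB": ("C_single", 2), "CG": ("C_intermediate", 0),
        "CD1": ("C_intermediate", 1), "CD2": ("C_intermediate", 0),
        "NE1": ("N_intermediate", 1), "CE2": ("C_intermediate", 0),
        "CE3": ("C_intermediate", 1), "CZ2": ("C_intermediate", 1),
        "CZ3": ("C_intermediate", 1), "CH2": ("C_intermediate", 1),
    },
    "TYR": {
        "CB": ("C_single", 2), "CG": ("C_intermediate", 0),
        "CD1": ("C_intermediate", 1), "CD2": ("C_intermediate", 1),
        "CE1": ("C_intermediate", 1), "CE2": ("C_intermediate", 1),
        "CZ": ("C_intermediate", 0), "OH": ("O_single", 1),
    },
    "VAL": {"CB": ("C_single", 1), "CG1": ("C_single", 3), "CG2": ("C_single", 3)},
}


def _lookup(residue_name: str, atom_name: str) -> tuple[str, int]:
    res = residue_name.upper().strip()
    name = atom_name.upper().strip()
    if res not in STANDARD_RESIDUES:
        raise UnclassifiableAtomError(f"non-standard residue {residue_name!r}")
    if name in _BACKBONE:
        atom_type, n_h = _BACKBONE[name]
        if name == "N" and res == "PRO":
            n_h = 0  # ring nitrogen carries no amide hydrogen
        elif name == "CA" and res == "GLY":
            n_h = 2
        return atom_type, n_h
    try:
        return _SIDE_CHAINS[res][name]
    except KeyError:
        raise UnclassifiableAtomError(f"unknown atom {atom_name!r} in {residue_name!r}") from None


def classify_atom(residue_name: str, atom_name: str) -> str:
    """Atom type (one of the 13 classes) of a standard-residue heavy atom."""
    return _lookup(residue_name, atom_name)[0]


def bonded_hydrogens(residue_name: str, atom_name: str) -> int:
    return _lookup(residue_name, atom_name)[1]


def electron_count(residue_name: str, atom_name: str, element: str) -> int:
    """Electrons of a heavy atom including its folded bonded hydrogens."""
    _, n_h = _lookup(residue_name, atom_name)
    el = element.upper().strip()
    if el not in ELEMENT_ELECTRONS:
        raise UnclassifiableAtomError(f"unknown element {element!r}")
    return ELEMENT_ELECTRONS[el] + n_h


def heavy_atoms(residue_name: str) -> list[str]:
    """Heavy-atom names (without OXT) of one standard residue."""
    res = residue_name.upper()
    if res not in STANDARD_RESIDUES:
        raise UnclassifiableAtomError(res)
    return ["N", "CA", "C", "O", *(_SIDE_CHAINS[res].keys())]
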