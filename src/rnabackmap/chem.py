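"""Atom-name conventions and per-base heavy-atom sets for standard RNA.

All names follow current PDB/CCD conventions (primed sugar atoms, OP1/OP2
phosphate oxygens).  The three coarse-grained bead positions are the P atom,
the C4' atom, and the glycosidic nitrogen (N9 in purines A/G, N1 in
pyrimidines U/C).
"""

from __future__ import annotations

STANDARD_BASES = ("A", "U", "G", "C")
PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"U", "C"})

#: Phosphate-group atoms moved as one rigid unit during bond repair.
PHOSPHATE_ATOMS = ("P", "OP1", "OP2", "O5'")

#: Ribose atoms (C5' counted with the sugar moiety).
SUGAR_ATOMS = ("C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'")

BACKBONE_ATOMS = PHOSPHATE_ATOMS + ("C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'")

#: Base heavy atoms per base type, glycosidic nitrogen first.
BASE_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
}

#: Complete expected heavy-atom set per base type (5'-phosphate included).
EXPECTED_HEAVY_ATOMS: dict[str, frozenset[str]] = {
    b: frozenset(BACKBONE_ATOMS) | frozenset(BASE_ATOMS[b]) for b in STANDARD_BASES
}

#: Default van der Waals radii (Angstrom), Bondi-type values.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80}


def glycosidic_nitrogen(base_type: str) -> str:
    """Name of the base nitrogen bonded to C1': N9 for A/G, N1 for U/C."""
    if base_type in PURINES:
        return "N9"
    if base_type in PYRIMIDINES:
        return "N1"
    raise ValueError(f"not a standard RNA base type: {base_type!r}")


def cg_atom_names(base_type: str) -> tuple[str, str, str]:
    """The three CG-bead source-atom names, in fixed (P, C4', N) order."""
    return ("P", "C4'", glycosidic_nitrogen(base_type))


def element_of(atom_name: str) -> str:
    """Element symbol inferred from a standard RNA heavy-atom name."""
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    if name == "P":
        return "P"
    head = name[0]
    if head in ("C", "N", "O"):
        return head
    raise ValueError(f"cannot infer element for atom name {atom_name!r}")


def is_base_atom(base_type: str, atom_name: str) -> bool:
    return atom_name in BASE_ATOMS.get(base_type, ())
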