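"""PDB-backed structure model and three-bead coarse-graining.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of chains, each an ordered list of :class:`Nucleotide` objects holding
heavy-atom records.  Reading and writing go through gemmi; only standard
ribonucleotides (A, U, G, C) are retained, hydrogens are always dropped, and
alternate locations other than blank/'A' are discarded.

Coarse-graining reduces each nucleotide to the three beads of the backmapping
model: the phosphate P atom, the sugar C4' atom, and the glycosidic nitrogen
(N9 for purines, N1 for pyrimidines).  Bead coordinates are copied verbatim
from the source atoms; nucleotides missing any of the three atoms are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .chem import STANDARD_BASES, cg_atom_names, element_of, glycosidic_nitrogen

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Nucleotide",
    "Chain",
    "Structure",
    "CGNucleotide",
    "CGChain",
    "CGModel",
    "EmptyStructureError",
    "EmptyModelError",
    "read_pdb",
    "write_pdb",
    "coarse_grain",
    "cg_to_structure",
    "structure_from_cg",
    "read_cg_pdb",
    "write_cg_pdb",
]

#: Largest coordinate magnitude representable in the fixed-width PDB field.
_PDB_COORD_MAX = 9999.999


class EmptyStructureError(ValueError):
    """Raised when a file or filter yields no RNA residues at all."""


class EmptyModelError(ValueError):
    """Raised when coarse-graining leaves no complete nucleotide."""


@dataclass
class AtomRecord:
    """One heavy atom: PDB-style name, element symbol, coordinates in Angstrom."""

    name: str
    element: str
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(3)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.name, self.element, self.xyz.copy())


@dataclass
class Nucleotide:
    base_type: str
    chain_id: str
    res_seq: int
    icode: str = " "
    atoms: list[AtomRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate atom names in residue {self.chain_id}/{self.res_seq}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity key (chain_id, res_seq, icode)."""
        return (self.chain_id, self.res_seq, self.icode)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray:
        a = self.atom(name)
        if a is None:
            raise KeyError(f"residue {self.key} has no atom {name!r}")
        return a.xyz

    def has_atoms(self, names) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, c in zip(self.atoms, coords):
            a.xyz = c.copy()

    def copy(self) -> "Nucleotide":
        return Nucleotide(
            self.base_type,
            self.chain_id,
            self.res_seq,
            self.icode,
            [a.copy() for a in self.atoms],
        )


@dataclass
class Chain:
    chain_id: str
    residues: list[Nucleotide] = field(default_factory=list)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)

    def residues(self):
        for chain in self.chains:
            yield from chain.residues

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def copy(self) -> "Structure":
        return Structure([c.copy() for c in self.chains])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Copy with every atom mapped through ``rotation @ x + translation``."""
        out = self.copy()
        rot = np.asarray(rotation, dtype=float)
        trans = np.asarray(translation, dtype=float)
        for res in out.residues():
            for a in res.atoms:
                a.xyz = rot @ a.xyz + trans
        return out


@dataclass
class CGNucleotide:
    """Three-bead reduction of one nucleotide (P, C4', glycosidic N)."""

    base_type: str
    bead_P: np.ndarray
    bead_C4p: np.ndarray
    bead_N: np.ndarray
    source_id: tuple[str, int, str]

    def __post_init__(self) -> None:
        self.bead_P = np.asarray(self.bead_P, dtype=float).reshape(3)
        self.bead_C4p = np.asarray(self.bead_C4p, dtype=float).reshape(3)
        self.bead_N = np.asarray(self.bead_N, dtype=float).reshape(3)
        for b in (self.bead_P, self.bead_C4p, self.bead_N):
            if not np.all(np.isfinite(b)):
                raise ValueError("non-finite bead coordinate")
        d = float(np.linalg.norm(self.bead_P - self.bead_C4p))
        if not (1.0 < d < 10.0):
            logger.warning(
                "implausible P-C4' bead distance %.2f A in %s", d, self.source_id
            )

    def beads(self) -> np.ndarray:
        """Bead coordinates in fixed (P, C4', N) order, shape (3, 3)."""
        return np.array([self.bead_P, self.bead_C4p, self.bead_N])

    def copy(self) -> "CGNucleotide":
        return CGNucleotide(
            self.base_type,
            self.bead_P.copy(),
            self.bead_C4p.copy(),
            self.bead_N.copy(),
            self.source_id,
        )


@dataclass
class CGChain:
    chain_id: str
    nucleotides: list[CGNucleotide] = field(default_factory=list)


@dataclass
class CGModel:
    chains: list[CGChain] = field(default_factory=list)

    def nucleotides(self):
        for chain in self.chains:
            yield from chain.nucleotides

    @property
    def n_nucleotides(self) -> int:
        return sum(len(c.nucleotides) for c in self.chains)

    def copy(self) -> "CGModel":
        return CGModel(
            [CGChain(c.chain_id, [nt.copy() for nt in c.nucleotides]) for c in self.chains]
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CGModel":
        rot = np.asarray(rotation, dtype=float)
        trans = np.asarray(translation, dtype=float)
        out = self.copy()
        for nt in out.nucleotides():
            nt.bead_P = rot @ nt.bead_P + trans
            nt.bead_C4p = rot @ nt.bead_C4p + trans
            nt.bead_N = rot @ nt.bead_N + trans
        return out


def read_pdb(path) -> Structure:
    """Read an RNA structure (first model, heavy atoms, standard bases only).

    Altloc policy: keep blank or 'A'.  Waters and hetero ligands are skipped
    silently; polymer residues with non-standard names (modified nucleotides,
    deoxyribonucleotides, amino acids) are excluded with a logged warning.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]

    structure = Structure()
    seen_keys: set[tuple[str, int, str]] = set()
    n_nonstandard = 0
    for gchain in model:
        chain = Chain(gchain.name)
        for gres in gchain:
            resname = gres.name.strip()
            if resname not in STANDARD_BASES:
                if not gres.is_water() and gres.het_flag != "H":
                    n_nonstandard += 1
                    logger.warning(
                        "skipping non-standard residue %s %s/%d", resname,
                        gchain.name, gres.seqid.num,
                    )
                continue
            icode = gres.seqid.icode or " "
            key = (gchain.name, gres.seqid.num, icode)
            if key in seen_keys:
                raise ValueError(f"{path}: duplicate residue identity {key}")
            seen_keys.add(key)
            nt = Nucleotide(resname, gchain.name, gres.seqid.num, icode)
            names_seen: set[str] = set()
            for atom in gres:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                if atom.element.name in ("H", "D"):
                    continue
                name = atom.name.strip()
                if name in names_seen:
                    continue
                names_seen.add(name)
                elem = atom.element.name if atom.element.name else element_of(name)
                nt.atoms.append(
                    AtomRecord(name, elem, [atom.pos.x, atom.pos.y, atom.pos.z])
                )
            if nt.atoms:
                chain.residues.append(nt)
        if chain.residues:
            structure.chains.append(chain)

    if structure.n_residues == 0:
        raise EmptyStructureError(f"{path}: no standard RNA residues parsed")
    if n_nonstandard:
        logger.info("%s: excluded %d non-standard residues", path, n_nonstandard)
    return structure


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.base_type
            gres.seqid = gemmi.SeqId(res.res_seq, res.icode if res.icode.strip() else " ")
            gres.het_flag = "A"
            gres.entity_type = gemmi.EntityType.Polymer
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.xyz)
                ga.occ = 1.0
                ga.b_iso = 0.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    return st


def write_pdb(structure: Structure, path) -> None:
    """Write standard fixed-width ATOM records with TER between chains."""
    if structure.n_atoms == 0:
        raise ValueError("refusing to write an empty structure")
    for res in structure.residues():
        for a in res.atoms:
            if np.any(np.abs(a.xyz) > _PDB_COORD_MAX):
                raise ValueError(
                    f"coordinate {a.xyz} of atom {a.name!r} in residue {res.key} "
                    f"exceeds the PDB fixed-width limit of +/-{_PDB_COORD_MAX}"
                )
    st = _to_gemmi(structure)
    text = st.make_pdb_string()
    # Strip gemmi's placeholder CRYST1/HET header lines; keep coordinates.
    kept = [
        line
        for line in text.splitlines()
        if line[:6] in ("ATOM  ", "HETATM", "TER   ", "END   ") or line.rstrip() == "END"
    ]
    Path(path).write_text("\n".join(kept) + "\n")


def coarse_grain(structure: Structure) -> CGModel:
    """Derive the three-bead CG model, copying source-atom coordinates exactly.

    Nucleotides lacking any of {P, C4', N1/N9} are dropped (count logged).
    """
    cg = CGModel()
    n_dropped = 0
    for chain in structure.chains:
        cg_chain = CGChain(chain.chain_id)
        for res in chain.residues:
            names = cg_atom_names(res.base_type)
            if not res.has_atoms(names):
                n_dropped += 1
                continue
            cg_chain.nucleotides.append(
                CGNucleotide(
                    base_type=res.base_type,
                    bead_P=res.coord(names[0]).copy(),
                    bead_C4p=res.coord(names[1]).copy(),
                    bead_N=res.coord(names[2]).copy(),
                    source_id=res.key,
                )
            )
        if cg_chain.nucleotides:
            cg.chains.append(cg_chain)
    if n_dropped:
        logger.info("coarse_grain: dropped %d incomplete nucleotides", n_dropped)
    if cg.n_nucleotides == 0:
        raise EmptyModelError("no nucleotide has a complete (P, C4', N) bead triplet")
    return cg


def cg_to_structure(cg: CGModel) -> Structure:
    """Represent a CG model as a Structure with one atom per bead, for PDB I/O."""
    structure = Structure()
    for cg_chain in cg.chains:
        chain = Chain(cg_chain.chain_id)
        for nt in cg_chain.nucleotides:
            n_name = glycosidic_nitrogen(nt.base_type)
            chain.residues.append(
                Nucleotide(
                    nt.base_type,
                    nt.source_id[0],
                    nt.source_id[1],
                    nt.source_id[2],
                    [
                        AtomRecord("P", "P", nt.bead_P),
                        AtomRecord("C4'", "C", nt.bead_C4p),
                        AtomRecord(n_name, "N", nt.bead_N),
                    ],
                )
            )
        structure.chains.append(chain)
    return structure


#: Alias used by callers that go the other way round.
structure_from_cg = cg_to_structure


def read_cg_pdb(path) -> CGModel:
    """Read a CG model stored as a PDB file with three bead atoms per residue."""
    return coarse_grain(read_pdb(path))


def write_cg_pdb(cg: CGModel, path) -> None:
    write_pdb(cg_to_structure(cg), path)
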