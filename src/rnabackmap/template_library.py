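"""Per-base-type template libraries of all-atom nucleotide fragments.

A fragment is one nucleotide's complete heavy-atom set, optionally carrying
the P position of its 3'-adjacent residue (``next_P``), which contributes to
the fragment-vs-standard RMSD but is never emplaced during reconstruction.
Each base type's template list starts with the standard A-form fragment
(rmsd_to_standard = 0); further templates are real or synthetic conformers
picked at evenly spaced percentiles of the rmsd-to-standard distribution so
the library spans conformational diversity with few members.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import (
    BASE_ATOMS,
    EXPECTED_HEAVY_ATOMS,
    STANDARD_BASES,
    cg_atom_names,
    element_of,
)
from .structure_io import AtomRecord, Chain, Nucleotide, Structure, read_pdb, write_pdb
from .superpose import kabsch_fit
from . import standards

logger = logging.getLogger(__name__)

__all__ = [
    "Fragment",
    "TemplateLibrary",
    "standard_fragment",
    "segment_nucleotides",
    "rmsd_to_standard",
    "select_templates",
    "build_library",
    "save_library",
    "load_library",
    "filter_redundant_sequences",
]

STANDARD_PROVENANCE = "standard"


@dataclass
class Fragment:
    """All-heavy-atom nucleotide template with provenance and diversity score."""

    base_type: str
    atoms: list[AtomRecord]
    next_P: np.ndarray | None = None
    provenance: tuple | str = STANDARD_PROVENANCE
    rmsd_to_standard: float = 0.0
    chain_terminal: bool = False

    def __post_init__(self) -> None:
        if self.base_type not in STANDARD_BASES:
            raise ValueError(f"unknown base type {self.base_type!r}")
        if self.next_P is not None:
            self.next_P = np.asarray(self.next_P, dtype=float).reshape(3)
        names = {a.name for a in self.atoms}
        missing = EXPECTED_HEAVY_ATOMS[self.base_type] - names
        if missing:
            raise ValueError(
                f"fragment {self.provenance} ({self.base_type}) misses atoms {sorted(missing)}"
            )

    def coord(self, name: str) -> np.ndarray:
        for a in self.atoms:
            if a.name == name:
                return a.xyz
        raise KeyError(name)

    def cg_coords(self) -> np.ndarray:
        """Template CG-atom coordinates in fixed (P, C4', N) order."""
        return np.array([self.coord(n) for n in cg_atom_names(self.base_type)])

    def copy(self) -> "Fragment":
        return Fragment(
            self.base_type,
            [a.copy() for a in self.atoms],
            None if self.next_P is None else self.next_P.copy(),
            self.provenance,
            self.rmsd_to_standard,
            self.chain_terminal,
        )


@dataclass
class TemplateLibrary:
    """Ordered template sets per base type; index 0 is always the standard."""

    fragments: dict[str, list[Fragment]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for base, frags in self.fragments.items():
            if not frags:
                raise ValueError(f"base type {base} has no templates")
            if frags[0].provenance != STANDARD_PROVENANCE:
                raise ValueError(f"template 0 for {base} must be the standard fragment")

    @property
    def k(self) -> int:
        """Number of templates per base type (the maximum across bases)."""
        return max(len(f) for f in self.fragments.values())

    def templates(self, base_type: str, k: int | None = None) -> list[Fragment]:
        if base_type not in self.fragments:
            raise KeyError(f"library has no templates for base type {base_type!r}")
        frags = self.fragments[base_type]
        return frags if k is None else frags[:k]

    @classmethod
    def standard_only(cls) -> "TemplateLibrary":
        """The k=1 library: just the packaged standard A-form fragments."""
        return cls({b: [standard_fragment(b)] for b in STANDARD_BASES})


def standard_fragment(base_type: str) -> Fragment:
    """The ideal A-form fragment for ``base_type`` (rmsd_to_standard = 0)."""
    coords, next_p = standards.standard_fragment_coords(base_type)
    atoms = [AtomRecord(n, element_of(n), c) for n, c in coords.items()]
    return Fragment(base_type, atoms, next_P=next_p, provenance=STANDARD_PROVENANCE,
                    rmsd_to_standard=0.0)


def segment_nucleotides(structure: Structure, source: str = "") -> list[Fragment]:
    """Cut an all-atom structure into per-nucleotide fragments.

    Each complete nucleotide yields one fragment; the 3'-neighbour's P atom is
    retained as ``next_P`` when that neighbour exists in the same chain and
    has a P atom, otherwise the fragment is flagged chain-terminal.
    Incomplete nucleotides are skipped (count logged).
    """
    fragments: list[Fragment] = []
    n_skipped = 0
    for chain in structure.chains:
        residues = chain.residues
        for i, res in enumerate(residues):
            expected = EXPECTED_HEAVY_ATOMS[res.base_type]
            present = {a.name for a in res.atoms}
            if not expected <= present:
                n_skipped += 1
                continue
            next_p = None
            terminal = True
            if i + 1 < len(residues):
                nxt = residues[i + 1].atom("P")
                if nxt is not None:
                    next_p = nxt.xyz.copy()
                    terminal = False
            atoms = [a.copy() for a in res.atoms if a.name in expected]
            fragments.append(
                Fragment(
                    res.base_type,
                    atoms,
                    next_P=next_p,
                    provenance=(source, res.chain_id, res.res_seq, res.icode),
                    chain_terminal=terminal,
                )
            )
    if n_skipped:
        logger.info("segment_nucleotides: skipped %d incomplete nucleotides", n_skipped)
    return fragments


def rmsd_to_standard(fragment: Fragment, standard: Fragment) -> float:
    """Post-superposition RMSD over all shared named heavy atoms.

    ``next_P`` enters the comparison when both fragments carry it.
    """
    if fragment.base_type != standard.base_type:
        raise ValueError(
            f"base-type mismatch: {fragment.base_type} vs {standard.base_type}"
        )
    names = sorted(
        {a.name for a in fragment.atoms} & {a.name for a in standard.atoms}
    )
    x = [fragment.coord(n) for n in names]
    y = [standard.coord(n) for n in names]
    if fragment.next_P is not None and standard.next_P is not None:
        x.append(fragment.next_P)
        y.append(standard.next_P)
    return kabsch_fit(np.array(x), np.array(y)).rmsd


def select_templates(fragments: list[Fragment], k: int) -> list[Fragment]:
    """Standard fragment plus k-1 conformers at evenly spaced RMSD percentiles.

    The non-standard pool is ranked by ``rmsd_to_standard``; stratum midpoints
    at percentiles (j - 1/2)/(k-1) pick the nearest unused fragment, ties
    broken by pool order.  Output is ordered by ascending rmsd_to_standard.
    If the pool cannot fill k-1 slots, all of it is returned (warning logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    base_types = {f.base_type for f in fragments}
    if len(base_types) > 1:
        raise ValueError(f"mixed base types in pool: {sorted(base_types)}")
    std = next((f for f in fragments if f.provenance == STANDARD_PROVENANCE), None)
    if std is None:
        std = standard_fragment(next(iter(base_types))) if base_types else None
    if std is None:
        raise ValueError("empty pool and no base type to build a standard for")
    pool = [f for f in fragments if f.provenance != STANDARD_PROVENANCE]

    if k - 1 >= len(pool):
        if k - 1 > len(pool):
            logger.warning(
                "requested %d non-standard templates but pool has %d; returning all",
                k - 1, len(pool),
            )
        chosen = list(pool)
    else:
        values = np.array([f.rmsd_to_standard for f in pool])
        order = np.argsort(values, kind="stable")
        sorted_vals = values[order]
        used: set[int] = set()
        chosen_idx: list[int] = []
        for j in range(1, k):
            q = (j - 0.5) / (k - 1)
            target = float(np.quantile(sorted_vals, q))
            best = None
            for rank in order:  # pool order breaks ties via stable argsort
                if int(rank) in used:
                    continue
                dist = abs(values[rank] - target)
                if best is None or dist < best[0] - 1e-12:
                    best = (dist, int(rank))
            used.add(best[1])
            chosen_idx.append(best[1])
        chosen = [pool[i] for i in chosen_idx]

    chosen.sort(key=lambda f: f.rmsd_to_standard)
    return [std] + chosen


def build_library(structures, k: int, sources=None) -> TemplateLibrary:
    """Segment structures, score fragments against the standards, select k.

    ``structures`` is an iterable of all-atom :class:`Structure`;
    ``sources`` optionally names them for provenance records.
    """
    pools: dict[str, list[Fragment]] = {b: [] for b in STANDARD_BASES}
    sources = list(sources) if sources is not None else None
    for idx, st in enumerate(structures):
        src = sources[idx] if sources else f"structure{idx}"
        for frag in segment_nucleotides(st, source=src):
            pools[frag.base_type].append(frag)
    lib: dict[str, list[Fragment]] = {}
    for base in STANDARD_BASES:
        std = standard_fragment(base)
        for frag in pools[base]:
            frag.rmsd_to_standard = rmsd_to_standard(frag, std)
        lib[base] = select_templates([std] + pools[base], k)
    return TemplateLibrary(lib)


# ---------------------------------------------------------------------------
# persistence: one PDB file per fragment plus a JSON manifest


def _fragment_to_structure(frag: Fragment) -> Structure:
    res = Nucleotide(frag.base_type, "A", 1, " ", [a.copy() for a in frag.atoms])
    chain = Chain("A", [res])
    if frag.next_P is not None:
        chain.residues.append(
            Nucleotide(frag.base_type, "A", 2, " ", [AtomRecord("P", "P", frag.next_P)])
        )
    return Structure([chain])


def _fragment_from_structure(st: Structure, meta: dict) -> Fragment:
    residues = list(st.residues())
    next_p = None
    if len(residues) > 1:
        p = residues[1].atom("P")
        next_p = None if p is None else p.xyz.copy()
    prov = meta["provenance"]
    if isinstance(prov, list):
        prov = tuple(prov)
    return Fragment(
        meta["base_type"],
        [a.copy() for a in residues[0].atoms],
        next_P=next_p,
        provenance=prov,
        rmsd_to_standard=float(meta["rmsd_to_standard"]),
        chain_terminal=bool(meta.get("chain_terminal", False)),
    )


def save_library(lib: TemplateLibrary, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"k": lib.k, "fragments": {}}
    for base, frags in lib.fragments.items():
        entries = []
        for i, frag in enumerate(frags):
            fname = f"{base}_{i:02d}.pdb"
            write_pdb(_fragment_to_structure(frag), directory / fname)
            entries.append(
                {
                    "file": fname,
                    "base_type": base,
                    "provenance": frag.provenance,
                    "rmsd_to_standard": frag.rmsd_to_standard,
                    "chain_terminal": frag.chain_terminal,
                }
            )
        manifest["fragments"][base] = entries
    (directory / "library.json").write_text(json.dumps(manifest, indent=1))


def load_library(directory) -> TemplateLibrary:
    directory = Path(directory)
    manifest_path = directory / "library.json"
    if not manifest_path.is_file():
        raise FileNotFoundError(f"library manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    fragments: dict[str, list[Fragment]] = {}
    for base, entries in manifest["fragments"].items():
        frags = []
        for meta in entries:
            fpath = directory / meta["file"]
            if not fpath.is_file():
                raise FileNotFoundError(f"fragment file missing from library: {fpath}")
            frags.append(_fragment_from_structure(read_pdb(fpath), meta))
        fragments[base] = frags
    return TemplateLibrary(fragments)


# ---------------------------------------------------------------------------
# optional convenience: naive greedy redundancy filter on chain sequences


def filter_redundant_sequences(sequences: list[str], identity: float = 0.8) -> list[int]:
    """Indices of a greedily selected subset with pairwise identity < cutoff.

    A deliberately naive stand-in for proper sequence clustering: identity is
    the length-normalized longest-common-subsequence ratio from difflib.
    """
    import difflib

    kept: list[int] = []
    for i, seq in enumerate(sequences):
        redundant = False
        for j in kept:
            ratio = difflib.SequenceMatcher(None, seq, sequences[j]).ratio()
            if ratio >= identity:
                redundant = True
                break
        if not redundant:
            kept.append(i)
    return kept
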