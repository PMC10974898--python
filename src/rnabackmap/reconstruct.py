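"""Per-nucleotide template fitting and all-atom assembly.

For each CG nucleotide, every same-base-type template in the library is
superposed onto the three beads by its own (P, C4', N) atoms; the template
with the smallest fit RMSD wins (ties go to the lowest template index) and
all of its atoms are carried through the fitted rigid map to replace the
beads.  Nucleotides are processed sequentially and independently; the
``next_P`` carried by library fragments is never emplaced (the 3'-neighbour's
own template provides that phosphate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure_io import CGModel, CGNucleotide, Chain, Nucleotide, Structure
from .superpose import SuperposeResult, kabsch_fit
from .template_library import Fragment, TemplateLibrary

logger = logging.getLogger(__name__)

__all__ = ["TemplateChoice", "best_template", "place_fragment", "assemble"]


@dataclass(frozen=True)
class TemplateChoice:
    """Winning template for one CG nucleotide."""

    template_index: int
    fit: SuperposeResult

    @property
    def rmsd(self) -> float:
        return self.fit.rmsd


def best_template(
    cg_nt: CGNucleotide, lib: TemplateLibrary, k: int | None = None
) -> TemplateChoice:
    """Minimum-RMSD template for the bead triplet, over templates[:k].

    Every candidate is Kabsch-fitted from its own CG atoms onto the beads;
    strict improvement is required to displace an earlier winner, so ties
    resolve to the lowest template index.
    """
    try:
        templates = lib.templates(cg_nt.base_type, k)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    beads = cg_nt.beads()
    best: TemplateChoice | None = None
    for index, template in enumerate(templates):
        fit = kabsch_fit(template.cg_coords(), beads)
        if fit.degenerate:
            logger.warning(
                "near-collinear bead triplet in %s: fit is defined only up to "
                "an axial spin", cg_nt.source_id,
            )
        if best is None or fit.rmsd < best.fit.rmsd:
            best = TemplateChoice(template_index=index, fit=fit)
    return best


def place_fragment(fragment: Fragment, fit: SuperposeResult) -> Nucleotide:
    """Carry all fragment atoms (``next_P`` excluded) through the fitted map.

    The returned nucleotide has placeholder identity (chain 'A', residue 1);
    callers re-key it to the CG nucleotide they are replacing.
    """
    atoms = [a.copy() for a in fragment.atoms]
    coords = fit.transform(np.array([a.xyz for a in atoms]))
    for atom, xyz in zip(atoms, coords):
        atom.xyz = xyz
    return Nucleotide(fragment.base_type, "A", 1, " ", atoms)


def assemble(
    cg: CGModel, lib: TemplateLibrary, k: int | None = None
) -> tuple[Structure, list[TemplateChoice]]:
    """Sequentially reconstruct every CG nucleotide into an all-atom structure.

    Returns the structure (one nucleotide per bead triplet, same order and
    identity keys) and the per-nucleotide template choices.
    """
    if cg.n_nucleotides == 0:
        raise ValueError("empty CG model")
    structure = Structure()
    choices: list[TemplateChoice] = []
    for cg_chain in cg.chains:
        chain = Chain(cg_chain.chain_id)
        for cg_nt in cg_chain.nucleotides:
            choice = best_template(cg_nt, lib, k)
            template = lib.templates(cg_nt.base_type, k)[choice.template_index]
            nt = place_fragment(template, choice.fit)
            nt.chain_id, nt.res_seq, nt.icode = cg_nt.source_id
            chain.residues.append(nt)
            choices.append(choice)
        structure.chains.append(chain)
    rmsds = np.array([c.rmsd for c in choices])
    logger.info(
        "assembled %d nucleotides: fit RMSD mean %.3f A, max %.3f A",
        len(choices), rmsds.mean(), rmsds.max(),
    )
    return structure, choices
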