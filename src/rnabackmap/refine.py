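"""Fast local refinement of assembled structures.

Two passes, in order:

1. **Bond check/repair** -- every inter-residue O3'(i)-P(i+1) bond is
   measured; bonds outside [1.4, 1.8] A are repaired by rigidly translating
   the 5'-phosphate group (P, OP1, OP2, O5') of residue i+1 along the
   O3'->P direction until the bond equals the 1.6 A standard value.  The
   group's internal geometry is untouched; if the translation overstretches
   the O5'-C5' bond beyond [1.2, 1.7] A, O5' alone is pulled back to the
   nearest bound.
2. **Clash elimination** -- only collisions involving a base are considered
   (phosphate-base, sugar-base, base-base); residue pairs whose C4'-C4'
   distance exceeds 20 A are prefiltered out.  A clash is two heavy atoms
   closer than the sum of their van der Waals radii.  For each clashing pair
   (i, j), j > i, the whole base of residue j is rotated rigidly about the
   C4'->N glycosidic axis (the glycosidic nitrogen stays fixed) in pi/20
   steps, at most 100 steps, choosing at each step the rotation sign that
   moves the base away from the colliding atom; residue i never moves.  If
   handling a pair would leave the structure with more clashes than before,
   the rotation is reverted, so the total clash count never increases.

There is no energy model and no stochastic move anywhere in this module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .chem import BASE_ATOMS, VDW_RADII, glycosidic_nitrogen
from .structure_io import Nucleotide, Structure
from .superpose import rotation_about_axis

logger = logging.getLogger(__name__)

__all__ = [
    "RefineParams",
    "BondViolation",
    "Clash",
    "RefineReport",
    "check_bonds",
    "repair_bond",
    "detect_clashes",
    "rotate_base",
    "eliminate_clashes",
    "refine",
]

#: atoms of residue i+1 moved as one rigid unit during bond repair
_PHOSPHATE_GROUP = ("P", "OP1", "OP2", "O5'")

#: 1-2 neighbour pairs across the O3'(i)-P(i+1) linkage, excluded from
#: clash detection between directly bonded residues
_LINKAGE_PAIRS = {("O3'", "P"), ("C3'", "P"), ("O3'", "OP1"), ("O3'", "OP2"), ("O3'", "O5'")}


@dataclass(frozen=True)
class RefineParams:
    """Refinement thresholds; defaults are the method's published values."""

    bond_target: float = 1.6  # A, repaired O3'-P length
    bond_min: float = 1.4
    bond_max: float = 1.8
    pair_cutoff: float = 20.0  # A, C4'-C4' clash prefilter
    rot_step: float = math.pi / 20.0  # rad per clash-elimination step
    max_steps: int = 100
    vdw_radii: dict = field(default_factory=lambda: dict(VDW_RADII))
    o5c5_min: float = 1.2  # A, post-repair O5'-C5' relaxation window
    o5c5_max: float = 1.7

    def __post_init__(self) -> None:
        if not (self.bond_min < self.bond_target < self.bond_max):
            raise ValueError("need bond_min < bond_target < bond_max")
        if self.rot_step <= 0 or self.max_steps < 1:
            raise ValueError("rot_step must be > 0 and max_steps >= 1")
        if any(r <= 0 for r in self.vdw_radii.values()):
            raise ValueError("van der Waals radii must be positive")


@dataclass(frozen=True)
class BondViolation:
    """An out-of-range O3'(i)-P(i+1) bond, located by flat residue index."""

    chain_index: int
    residue_index: int  # index of residue i within its chain
    i_key: tuple
    j_key: tuple
    length: float
    direction: str  # "too_long" | "too_short"


@dataclass(frozen=True)
class Clash:
    """Two non-bonded heavy atoms closer than their vdW-radius sum."""

    i: int  # flat residue indices, j > i
    j: int
    atom_i: str
    atom_j: str
    distance: float
    vdw_sum: float
    category: str  # "phosphate-base" | "sugar-base" | "base-base"


@dataclass
class RefineReport:
    bond_violations: list = field(default_factory=list)
    bonds_repaired: int = 0
    bonds_skipped: int = 0
    clashes_initial: list = field(default_factory=list)
    clashes_final: list = field(default_factory=list)
    pairs_resolved: int = 0
    pairs_unresolved: int = 0
    pairs_reverted: int = 0

    def summary(self) -> str:
        return (
            f"bonds: {len(self.bond_violations)} violations, "
            f"{self.bonds_repaired} repaired, {self.bonds_skipped} skipped; "
            f"clashes: {len(self.clashes_initial)} -> {len(self.clashes_final)} "
            f"({self.pairs_resolved} pairs resolved, "
            f"{self.pairs_unresolved} unresolved, {self.pairs_reverted} reverted)"
        )


def _flat_residues(s: Structure) -> list[Nucleotide]:
    return [res for chain in s.chains for res in chain.residues]


def check_bonds(s: Structure, params: RefineParams | None = None) -> list[BondViolation]:
    """All out-of-range inter-residue O3'-P bonds, chain breaks skipped.

    Consecutive residues within a chain are bonded candidates unless the
    author numbering jumps by more than one (a declared gap).
    """
    params = params or RefineParams()
    violations = []
    for ci, chain in enumerate(s.chains):
        for ri in range(len(chain.residues) - 1):
            res_i = chain.residues[ri]
            res_j = chain.residues[ri + 1]
            if res_j.res_seq - res_i.res_seq > 1:
                continue  # numbering gap: declared chain break
            o3 = res_i.atom("O3'")
            p = res_j.atom("P")
            if o3 is None or p is None:
                continue
            length = float(np.linalg.norm(p.xyz - o3.xyz))
            if length > params.bond_max or length < params.bond_min:
                violations.append(
                    BondViolation(
                        chain_index=ci,
                        residue_index=ri,
                        i_key=res_i.key,
                        j_key=res_j.key,
                        length=length,
                        direction="too_long" if length > params.bond_max else "too_short",
                    )
                )
    return violations


def repair_bond(
    s: Structure, violation: BondViolation, params: RefineParams | None = None
) -> Structure:
    """Repair one O3'-P bond in place by translating the 5'-phosphate group.

    Only the four phosphate-group atoms (P, OP1, OP2, O5') of residue i+1
    move; they translate rigidly along the O3'->P direction so the bond
    equals ``bond_target``.  If that stretches O5'-C5' outside its window,
    O5' alone is scaled back to the nearest bound along the C5'->O5' axis.
    """
    params = params or RefineParams()
    chain = s.chains[violation.chain_index]
    res_i = chain.residues[violation.residue_index]
    res_j = chain.residues[violation.residue_index + 1]
    o3 = res_i.atom("O3'")
    p = res_j.atom("P")
    if o3 is None or p is None:
        logger.warning("cannot repair bond %s-%s: O3' or P missing",
                       violation.i_key, violation.j_key)
        return s
    direction = p.xyz - o3.xyz
    norm = np.linalg.norm(direction)
    if norm == 0:
        logger.warning("degenerate zero-length bond %s-%s left as is",
                       violation.i_key, violation.j_key)
        return s
    unit = direction / norm
    delta = (params.bond_target - norm) * unit
    for name in _PHOSPHATE_GROUP:
        atom = res_j.atom(name)
        if atom is not None:
            atom.xyz = atom.xyz + delta

    o5 = res_j.atom("O5'")
    c5 = res_j.atom("C5'")
    if o5 is not None and c5 is not None:
        d = float(np.linalg.norm(o5.xyz - c5.xyz))
        if d > params.o5c5_max or d < params.o5c5_min:
            target = min(max(d, params.o5c5_min), params.o5c5_max)
            o5.xyz = c5.xyz + (o5.xyz - c5.xyz) * (target / d)
    return s


def _pair_clashes(
    res_a: Nucleotide, res_b: Nucleotide, ia: int, ib: int,
    params: RefineParams, bonded: bool,
) -> list[Clash]:
    """Base-involving clashes between one residue pair (ia < ib)."""
    radii = params.vdw_radii
    base_a = BASE_ATOMS[res_a.base_type]
    base_b = BASE_ATOMS[res_b.base_type]
    xa = np.array([a.xyz for a in res_a.atoms])
    xb = np.array([b.xyz for b in res_b.atoms])
    ra = np.array([radii[a.element] for a in res_a.atoms])
    rb = np.array([radii[b.element] for b in res_b.atoms])
    is_base_a = np.array([a.name in base_a for a in res_a.atoms])
    is_base_b = np.array([b.name in base_b for b in res_b.atoms])
    dist = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    limit = ra[:, None] + rb[None, :]
    mask = (dist < limit) & (is_base_a[:, None] | is_base_b[None, :])
    out = []
    for i, j in np.argwhere(mask):
        atom_a, atom_b = res_a.atoms[i], res_b.atoms[j]
        if bonded and (atom_a.name, atom_b.name) in _LINKAGE_PAIRS:
            continue
        if is_base_a[i] and is_base_b[j]:
            category = "base-base"
        else:
            other = atom_b.name if is_base_a[i] else atom_a.name
            category = "phosphate-base" if other in _PHOSPHATE_GROUP else "sugar-base"
        out.append(
            Clash(ia, ib, atom_a.name, atom_b.name, float(dist[i, j]),
                  float(limit[i, j]), category)
        )
    return out


def _residue_pair_candidates(s: Structure, params: RefineParams):
    """(ia, ib, res_a, res_b, bonded) for pairs inside the C4' prefilter."""
    flat = []
    for ci, chain in enumerate(s.chains):
        for ri, res in enumerate(chain.residues):
            flat.append((ci, ri, res))
    c4 = np.full((len(flat), 3), np.nan)
    for idx, (_, _, res) in enumerate(flat):
        atom = res.atom("C4'")
        if atom is not None:
            c4[idx] = atom.xyz
    for ia in range(len(flat)):
        for ib in range(ia + 1, len(flat)):
            if np.any(np.isnan(c4[ia])) or np.any(np.isnan(c4[ib])):
                continue
            if np.linalg.norm(c4[ia] - c4[ib]) > params.pair_cutoff:
                continue
            ci_a, ri_a, res_a = flat[ia]
            ci_b, ri_b, res_b = flat[ib]
            bonded = (
                ci_a == ci_b
                and ri_b == ri_a + 1
                and res_b.res_seq - res_a.res_seq <= 1
            )
            yield ia, ib, res_a, res_b, bonded


def detect_clashes(s: Structure, params: RefineParams | None = None) -> list[Clash]:
    """All base-involving inter-residue clashes, ordered by (i, j)."""
    params = params or RefineParams()
    clashes: list[Clash] = []
    for ia, ib, res_a, res_b, bonded in _residue_pair_candidates(s, params):
        clashes.extend(_pair_clashes(res_a, res_b, ia, ib, params, bonded))
    return clashes


def rotate_base(
    residue: Nucleotide, angle: float, direction_hint=None
) -> Nucleotide:
    """Copy of ``residue`` with its base rotated about the glycosidic axis.

    The axis runs through the glycosidic nitrogen along C4'->N, so the
    nitrogen itself is exactly fixed; sugar and phosphate atoms never move
    and the base's internal geometry is preserved.  With a
    ``direction_hint``, both +-angle are evaluated and the variant whose
    base centroid moves farther along the hint is kept (the hint is the
    escape direction away from a colliding atom).
    """
    n_name = glycosidic_nitrogen(residue.base_type)
    c4 = residue.atom("C4'")
    n = residue.atom(n_name)
    if c4 is None or n is None:
        logger.warning("residue %s lacks C4'/%s: base rotation skipped",
                       residue.key, n_name)
        return residue.copy()
    if angle == 0.0:
        return residue.copy()
    axis = n.xyz - c4.xyz
    base_names = BASE_ATOMS[residue.base_type]

    def rotated(signed_angle: float) -> Nucleotide:
        rot = rotation_about_axis(axis, signed_angle)
        out = residue.copy()
        for atom in out.atoms:
            if atom.name in base_names:
                atom.xyz = rot @ (atom.xyz - n.xyz) + n.xyz
        return out

    if direction_hint is None:
        return rotated(angle)
    hint = np.asarray(direction_hint, dtype=float)

    def centroid(nt: Nucleotide) -> np.ndarray:
        return np.mean([a.xyz for a in nt.atoms if a.name in base_names], axis=0)

    plus, minus = rotated(abs(angle)), rotated(-abs(angle))
    ref = centroid(residue)
    if np.dot(centroid(plus) - ref, hint) >= np.dot(centroid(minus) - ref, hint):
        return plus
    return minus


def _eliminate_in_place(s: Structure, params: RefineParams) -> RefineReport:
    report = RefineReport()
    flat = _flat_residues(s)
    initial = detect_clashes(s, params)
    report.clashes_initial = initial
    pairs = sorted({(c.i, c.j) for c in initial})

    def pair_state(ia: int, ib: int) -> list[Clash]:
        ci, cj = flat[ia], flat[ib]
        bonded = _bonded(s, ia, ib)
        return _pair_clashes(ci, cj, ia, ib, params, bonded)

    def _bonded(struct: Structure, ia: int, ib: int) -> bool:
        # flat indices are contiguous per chain, in order
        count = 0
        for chain in struct.chains:
            if count <= ia < count + len(chain.residues) and ib == ia + 1 \
                    and ib < count + len(chain.residues):
                ra = chain.residues[ia - count]
                rb = chain.residues[ib - count]
                return rb.res_seq - ra.res_seq <= 1
            count += len(chain.residues)
        return False

    for ia, ib in pairs:
        count_before = len(detect_clashes(s, params))
        res_j = flat[ib]
        saved = [(a.name, a.xyz.copy()) for a in res_j.atoms]
        steps = 0
        current = pair_state(ia, ib)
        while current and steps < params.max_steps:
            deepest = min(current, key=lambda c: c.distance - c.vdw_sum)
            atom_i = flat[ia].atom(deepest.atom_i)
            atom_j = flat[ib].atom(deepest.atom_j)
            hint = atom_j.xyz - atom_i.xyz
            rotated = rotate_base(res_j, params.rot_step, direction_hint=hint)
            for atom, (name, _) in zip(res_j.atoms, saved):
                atom.xyz = rotated.atom(atom.name).xyz
            steps += 1
            current = pair_state(ia, ib)
        resolved = not current
        if len(detect_clashes(s, params)) > count_before:
            # rotating this base made things globally worse: revert
            for atom, (name, xyz) in zip(res_j.atoms, saved):
                atom.xyz = xyz.copy()
            report.pairs_reverted += 1
            resolved = False
        if resolved:
            report.pairs_resolved += 1
        else:
            report.pairs_unresolved += 1

    report.clashes_final = detect_clashes(s, params)
    return report


def eliminate_clashes(
    s: Structure, params: RefineParams | None = None
) -> tuple[Structure, RefineReport]:
    """Resolve base-involving clashes by rigid base rotations.

    Clashing pairs are processed in ascending (i, j); only the base of the
    higher-numbered residue rotates.  Deterministic; the final clash count
    never exceeds the initial one.
    """
    params = params or RefineParams()
    out = s.copy()
    report = _eliminate_in_place(out, params)
    return out, report


def refine(
    s: Structure, params: RefineParams | None = None
) -> tuple[Structure, RefineReport]:
    """Bond check/repair followed by clash elimination.

    Idempotent on a structure that is already bond-clean and clash-free.
    """
    params = params or RefineParams()
    out = s.copy()
    violations = check_bonds(out, params)
    repaired = 0
    skipped = 0
    for violation in violations:
        before = len(check_bonds(out, params))
        repair_bond(out, violation, params)
        after = len(check_bonds(out, params))
        if after < before:
            repaired += 1
        else:
            skipped += 1
    report = _eliminate_in_place(out, params)
    report.bond_violations = violations
    report.bonds_repaired = repaired
    report.bonds_skipped = skipped
    if report.bond_violations or report.clashes_initial:
        logger.info("refine: %s", report.summary())
    return out, report
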