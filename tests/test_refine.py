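"""Bond check/repair and clash elimination contracts."""

import numpy as np
import pytest

import rnabackmap as rb
from rnabackmap.chem import BASE_ATOMS
from rnabackmap.refine import (
    RefineParams,
    _PHOSPHATE_GROUP,
    check_bonds,
    detect_clashes,
    eliminate_clashes,
    refine,
    repair_bond,
    rotate_base,
)
from rnabackmap.structure_io import AtomRecord, Chain, Nucleotide, Structure

from .conftest import all_coords

PARAMS = RefineParams()


def _two_nt(strand, bond_length=None):
    """Two-residue slice of the ideal strand, optionally with the O3'-P
    bond set to a given length by translating the whole second residue."""
    pair = Structure([Chain("A", [strand.chains[0].residues[0].copy(),
                                  strand.chains[0].residues[1].copy()])])
    if bond_length is not None:
        r1, r2 = pair.chains[0].residues
        direction = r2.coord("P") - r1.coord("O3'")
        d = np.linalg.norm(direction)
        delta = (bond_length - d) * direction / d
        for a in r2.atoms:
            a.xyz = a.xyz + delta
    return pair


def _minimal_residue(base, chain_id, seq, coords):
    return Nucleotide(
        base, chain_id, seq, " ",
        [AtomRecord(name, name[0] if name != "P" else "P", xyz)
         for name, xyz in coords.items()],
    )


class TestCheckBonds:
    @pytest.mark.parametrize(
        "length, flagged, direction",
        [
            (1.60, False, None),  # the standard value
            (1.70, False, None),  # inside the tolerated window
            (1.90, True, "too_long"),
            (1.39, True, "too_short"),
        ],
    )
    def test_threshold_rules(self, strand, length, flagged, direction):
        pair = _two_nt(strand, bond_length=length)
        violations = check_bonds(pair, PARAMS)
        assert bool(violations) is flagged
        if flagged:
            assert violations[0].direction == direction
            assert violations[0].length == pytest.approx(length, abs=1e-9)

    def test_numbering_gap_is_a_chain_break(self, strand):
        pair = _two_nt(strand, bond_length=5.0)
        pair.chains[0].residues[1].res_seq = 10
        assert check_bonds(pair, PARAMS) == []

    def test_clean_strand_has_no_violations(self, strand):
        assert check_bonds(strand, PARAMS) == []


class TestRepairBond:
    def test_overlong_bond_repaired_exactly(self, strand):
        pair = _two_nt(strand, bond_length=2.4)
        before = {a.name: a.xyz.copy() for a in pair.chains[0].residues[1].atoms}
        violation = check_bonds(pair, PARAMS)[0]
        repair_bond(pair, violation, PARAMS)
        r1, r2 = pair.chains[0].residues
        assert np.linalg.norm(r2.coord("P") - r1.coord("O3'")) == pytest.approx(1.6, abs=1e-9)
        # phosphate-group internal geometry untouched (rigid translation)
        group = [n for n in _PHOSPHATE_GROUP]
        for a in group:
            for b in group:
                d_now = np.linalg.norm(r2.coord(a) - r2.coord(b))
                d_was = np.linalg.norm(before[a] - before[b])
                assert d_now == pytest.approx(d_was, abs=1e-9)

    def test_short_bond_direction_preserved(self, strand):
        pair = _two_nt(strand, bond_length=1.0)
        r1, r2 = pair.chains[0].residues
        unit_before = (r2.coord("P") - r1.coord("O3'")) / 1.0
        repair_bond(pair, check_bonds(pair, PARAMS)[0], PARAMS)
        after = r2.coord("P") - r1.coord("O3'")
        assert np.linalg.norm(after) == pytest.approx(1.6, abs=1e-9)
        assert np.allclose(after / np.linalg.norm(after), unit_before, atol=1e-9)

    def test_locality_only_phosphate_group_moves(self, strand):
        pair = _two_nt(strand, bond_length=2.2)
        frozen_r1 = all_coords(Structure([Chain("A", [pair.chains[0].residues[0]])]))
        r2 = pair.chains[0].residues[1]
        untouched = {a.name: a.xyz.copy() for a in r2.atoms
                     if a.name not in _PHOSPHATE_GROUP}
        repair_bond(pair, check_bonds(pair, PARAMS)[0], PARAMS)
        assert np.array_equal(
            frozen_r1, all_coords(Structure([Chain("A", [pair.chains[0].residues[0]])]))
        )
        for name, xyz in untouched.items():
            assert np.array_equal(r2.coord(name), xyz)


class TestDetectClashes:
    def test_base_base_nitrogen_pair(self):
        """Two base nitrogens of different residues at 2.0 A: one clash
        against the 1.55 + 1.55 = 3.10 A radius sum."""
        res_a = _minimal_residue("A", "A", 1, {"C4'": (0, 0, 0), "N9": (1.5, 0, 0)})
        res_b = _minimal_residue("A", "A", 2, {"C4'": (5, 0, 0), "N9": (3.5, 0, 0)})
        clashes = detect_clashes(Structure([Chain("A", [res_a, res_b])]), PARAMS)
        assert len(clashes) == 1
        clash = clashes[0]
        assert (clash.atom_i, clash.atom_j) == ("N9", "N9")
        assert clash.distance == pytest.approx(2.0)
        assert clash.vdw_sum == pytest.approx(3.10)
        assert clash.category == "base-base"

    def test_c4_prefilter_suppresses_distant_pairs(self):
        # base atoms overlap but the C4' anchors are 25 A apart
        res_a = _minimal_residue("A", "A", 1, {"C4'": (0, 0, 0), "N9": (12, 0, 0)})
        res_b = _minimal_residue("A", "A", 2, {"C4'": (25, 0, 0), "N9": (12.5, 0, 0)})
        assert detect_clashes(Structure([Chain("A", [res_a, res_b])]), PARAMS) == []

    def test_backbone_only_contacts_ignored(self):
        res_a = _minimal_residue("G", "A", 1, {"C4'": (0, 0, 0), "P": (2, 0, 0)})
        res_b = _minimal_residue("G", "A", 2, {"C4'": (5, 0, 0), "O2'": (3, 1, 0)})
        assert detect_clashes(Structure([Chain("A", [res_a, res_b])]), PARAMS) == []

    def test_ideal_strand_is_clash_free(self, strand):
        assert detect_clashes(strand, PARAMS) == []


class TestRotateBase:
    def test_zero_angle_is_identity(self, strand):
        res = strand.chains[0].residues[3]
        out = rotate_base(res, 0.0)
        assert np.array_equal(out.coords(), res.coords())

    def test_full_turn_returns_home(self, strand):
        res = strand.chains[0].residues[3]
        out = res
        for _ in range(40):
            out = rotate_base(out, np.pi / 20)
        assert np.allclose(out.coords(), res.coords(), atol=1e-6)

    def test_glycosidic_nitrogen_exactly_fixed(self, strand):
        for res in strand.residues():
            n_name = "N9" if res.base_type in "AG" else "N1"
            out = rotate_base(res, 0.7)
            assert np.array_equal(out.coord(n_name), res.coord(n_name))

    def test_sugar_and_phosphate_untouched(self, strand):
        res = strand.chains[0].residues[2]
        out = rotate_base(res, 1.0)
        for atom in res.atoms:
            if atom.name not in BASE_ATOMS[res.base_type]:
                assert np.array_equal(out.coord(atom.name), atom.xyz)

    def test_base_internal_distances_preserved(self, strand):
        res = strand.chains[0].residues[7]
        out = rotate_base(res, 0.9)
        names = [n for n in BASE_ATOMS[res.base_type]]
        before = np.array([res.coord(n) for n in names])
        after = np.array([out.coord(n) for n in names])
        d0 = np.linalg.norm(before[:, None] - before[None, :], axis=-1)
        d1 = np.linalg.norm(after[:, None] - after[None, :], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)


class TestEliminateClashes:
    def test_clash_free_structure_unchanged(self, strand):
        out, report = eliminate_clashes(strand, PARAMS)
        assert np.array_equal(all_coords(out), all_coords(strand))
        assert report.clashes_initial == [] and report.clashes_final == []

    def test_swung_base_clash_is_resolved(self, strand):
        """A base swung 30 degrees off its helical orientation collides with
        its stacked neighbours; rigid rotation alone must clear it."""
        res = strand.chains[0].residues[5]
        swung = rotate_base(res, np.deg2rad(30))
        for a, b in zip(res.atoms, swung.atoms):
            a.xyz = b.xyz
        assert len(detect_clashes(strand, PARAMS)) > 0
        out, report = eliminate_clashes(strand, PARAMS)
        assert report.clashes_final == []
        assert report.pairs_resolved >= 1

    def test_interlocked_base_hits_step_cap(self):
        """A clashing base atom sitting on its own rotation axis can never
        escape; the loop must stop at max_steps and keep the clash in the
        report without making things worse."""
        res_a = _minimal_residue(
            "U", "A", 1, {"C4'": (0, 0, 0), "N1": (1.4, 0, 0), "C2": (2.8, 0, 0)}
        )
        res_b = _minimal_residue(
            "U", "A", 2, {"C4'": (6.0, 0, 0), "N1": (4.6, 0, 0), "C2": (3.3, 0, 0)}
        )
        s = Structure([Chain("A", [res_a, res_b])])
        n_initial = len(detect_clashes(s, PARAMS))
        assert n_initial > 0
        out, report = eliminate_clashes(s, PARAMS)
        assert report.pairs_unresolved >= 1
        assert len(report.clashes_final) <= n_initial
        assert len(report.clashes_final) > 0

    def test_clash_count_never_increases(self):
        for seed in range(50):
            strand = rb.make_ideal_strand(
                rb.FixtureSpec(sequence="GACGUAUGCA", jitter_sigma=0.35, seed=seed)
            )
            before = len(detect_clashes(strand, PARAMS))
            _, report = eliminate_clashes(strand, PARAMS)
            assert len(report.clashes_final) <= before


class TestRefine:
    def test_idempotent_on_clean_strand(self, strand):
        out, report = refine(strand, PARAMS)
        assert np.array_equal(all_coords(out), all_coords(strand))
        assert report.bond_violations == [] and report.clashes_initial == []

    def test_stretched_bond_and_clash_both_fixed(self, strand):
        # stretch one inter-residue bond by translating a phosphate group
        r3 = strand.chains[0].residues[3]
        o3 = strand.chains[0].residues[2].coord("O3'")
        direction = r3.coord("P") - o3
        unit = direction / np.linalg.norm(direction)
        for name in _PHOSPHATE_GROUP:
            atom = r3.atom(name)
            atom.xyz = atom.xyz + 0.9 * unit
        # swing one base into its neighbours
        res6 = strand.chains[0].residues[5]
        swung = rotate_base(res6, np.deg2rad(30))
        for a, b in zip(res6.atoms, swung.atoms):
            a.xyz = b.xyz
        assert len(check_bonds(strand, PARAMS)) == 1
        assert len(detect_clashes(strand, PARAMS)) > 0
        out, report = refine(strand, PARAMS)
        assert report.bonds_repaired == 1
        assert check_bonds(out, PARAMS) == []
        assert report.clashes_final == []

    def test_second_pass_reports_nothing(self, strand):
        strand_mod = strand
        r5 = strand_mod.chains[0].residues[5]
        for name in _PHOSPHATE_GROUP:
            atom = r5.atom(name)
            atom.xyz = atom.xyz + np.array([0.0, 0.0, 0.6])
        once, report1 = refine(strand_mod, PARAMS)
        assert report1.bonds_repaired >= 1
        twice, report2 = refine(once, PARAMS)
        assert report2.bond_violations == [] and report2.bonds_repaired == 0
        assert np.array_equal(all_coords(once), all_coords(twice))

    def test_base_geometry_preserved_through_refinement(self):
        strand = rb.make_ideal_strand(
            rb.FixtureSpec(sequence="GGCAUACGUC", jitter_sigma=0.3, seed=77)
        )
        names_before = {}
        for idx, res in enumerate(strand.residues()):
            pts = np.array([res.coord(n) for n in BASE_ATOMS[res.base_type]])
            names_before[idx] = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        out, _ = refine(strand, PARAMS)
        for idx, res in enumerate(out.residues()):
            pts = np.array([res.coord(n) for n in BASE_ATOMS[res.base_type]])
            dists = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            assert np.allclose(dists, names_before[idx], atol=1e-6)
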