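"""Fragment segmentation, diversity scoring, selection, and persistence."""

import numpy as np
import pytest

import rnabackmap as rb
from rnabackmap.chem import BASE_ATOMS, EXPECTED_HEAVY_ATOMS
from rnabackmap.superpose import rotation_about_axis
from rnabackmap.template_library import STANDARD_PROVENANCE

from .conftest import random_rotation
from .oracles import horn_fit


class TestStandardFragments:
    def test_complete_and_self_consistent(self):
        for base in "AUGC":
            frag = rb.standard_fragment(base)
            assert {a.name for a in frag.atoms} == EXPECTED_HEAVY_ATOMS[base]
            assert frag.provenance == STANDARD_PROVENANCE
            assert frag.rmsd_to_standard == 0.0
            assert frag.next_P is not None
            assert rb.rmsd_to_standard(frag, rb.standard_fragment(base)) < 1e-9


class TestSegmentNucleotides:
    def test_three_nt_chain(self, strand):
        three = rb.Structure([rb.Chain("A", strand.chains[0].residues[:3])])
        frags = rb.segment_nucleotides(three, source="fix")
        assert len(frags) == 3
        assert frags[0].next_P is not None and frags[1].next_P is not None
        assert frags[2].next_P is None and frags[2].chain_terminal
        # next_P is literally the neighbour's P atom
        assert np.array_equal(frags[0].next_P, three.chains[0].residues[1].coord("P"))

    def test_incomplete_nucleotide_skipped(self, strand):
        res = strand.chains[0].residues[1]
        res.atoms = [a for a in res.atoms if a.name != "O2'"]
        frags = rb.segment_nucleotides(strand)
        assert len(frags) == strand.n_residues - 1

    def test_no_next_p_across_chain_break(self, strand):
        c1 = rb.Chain("A", [r.copy() for r in strand.chains[0].residues[:2]])
        c2 = rb.Chain("B", [r.copy() for r in strand.chains[0].residues[2:4]])
        for r in c2.residues:
            r.chain_id = "B"
        frags = rb.segment_nucleotides(rb.Structure([c1, c2]))
        assert len(frags) == 4
        assert [f.chain_terminal for f in frags] == [False, True, False, True]


class TestRmsdToStandard:
    def test_zero_against_itself_and_rigid_copies(self):
        std = rb.standard_fragment("G")
        assert rb.rmsd_to_standard(std, std) == pytest.approx(0.0, abs=1e-9)
        rng = np.random.default_rng(5)
        moved = std.copy()
        rot = random_rotation(rng)
        shift = rng.normal(size=3) * 10
        for a in moved.atoms:
            a.xyz = rot @ a.xyz + shift
        moved.next_P = rot @ moved.next_P + shift
        moved.provenance = ("moved", "A", 1, " ")
        assert rb.rmsd_to_standard(moved, std) == pytest.approx(0.0, abs=1e-6)

    def test_base_rotation_matches_quaternion_oracle(self):
        """A 30-degree base swing about the glycosidic axis: the operation
        must agree with an independent quaternion-fit oracle to 1e-6."""
        std = rb.standard_fragment("A")
        frag = std.copy()
        axis = frag.coord("N9") - frag.coord("C4'")
        rot = rotation_about_axis(axis, np.deg2rad(30))
        pivot = frag.coord("N9").copy()
        for a in frag.atoms:
            if a.name in BASE_ATOMS["A"]:
                a.xyz = rot @ (a.xyz - pivot) + pivot
        frag.provenance = ("synthetic", "A", 1, " ")
        value = rb.rmsd_to_standard(frag, std)
        names = sorted({a.name for a in frag.atoms})
        x = np.array([frag.coord(n) for n in names] + [frag.next_P])
        y = np.array([std.coord(n) for n in names] + [std.next_P])
        _, _, oracle = horn_fit(x, y)
        assert value == pytest.approx(oracle, abs=1e-6)
        assert 0.2 < value < 0.8  # frozen scale: ~0.39 A for a 30 deg swing

    def test_base_type_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rb.rmsd_to_standard(rb.standard_fragment("A"), rb.standard_fragment("G"))


class TestSelectTemplates:
    def test_k1_returns_only_standard(self):
        pool = rb.make_fragment_pool("U", 10, seed=1)
        out = rb.select_templates([rb.standard_fragment("U")] + pool, 1)
        assert len(out) == 1 and out[0].provenance == STANDARD_PROVENANCE

    def test_k3_picks_distinct_strata(self):
        pool = rb.make_fragment_pool("C", 30, seed=2)
        out = rb.select_templates([rb.standard_fragment("C")] + pool, 3)
        assert len(out) == 3
        assert out[0].provenance == STANDARD_PROVENANCE
        values = [f.rmsd_to_standard for f in out]
        assert values == sorted(values)
        assert values[2] > values[1] > 0

    def test_pool_exhaustion_returns_all(self, caplog):
        pool = rb.make_fragment_pool("G", 2, seed=3)
        with caplog.at_level("WARNING"):
            out = rb.select_templates([rb.standard_fragment("G")] + pool, 5)
        assert len(out) == 3
        assert any("pool has" in rec.message for rec in caplog.records)

    def test_selection_is_deterministic(self):
        pool = rb.make_fragment_pool("A", 25, seed=4)
        first = rb.select_templates([rb.standard_fragment("A")] + pool, 6)
        second = rb.select_templates([rb.standard_fragment("A")] + pool, 6)
        assert [f.provenance for f in first] == [f.provenance for f in second]


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, synthetic_library):
        rb.save_library(synthetic_library, tmp_path / "lib")
        back = rb.load_library(tmp_path / "lib")
        for base in "AUGC":
            orig = synthetic_library.templates(base)
            loaded = back.templates(base)
            assert len(loaded) == len(orig) == 6
            assert loaded[0].provenance == STANDARD_PROVENANCE
            for a, b in zip(orig, loaded):
                assert a.provenance == b.provenance or tuple(a.provenance) == tuple(b.provenance)
                assert b.rmsd_to_standard == pytest.approx(a.rmsd_to_standard, abs=1e-6)
                for atom_a, atom_b in zip(a.atoms, b.atoms):
                    assert np.allclose(atom_a.xyz, atom_b.xyz, atol=1e-3)

    def test_missing_fragment_file_raises(self, tmp_path, synthetic_library):
        rb.save_library(synthetic_library, tmp_path / "lib")
        (tmp_path / "lib" / "G_02.pdb").unlink()
        with pytest.raises(FileNotFoundError, match="G_02"):
            rb.load_library(tmp_path / "lib")

    def test_missing_manifest_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="manifest"):
            rb.load_library(tmp_path)


class TestBuildLibrary:
    def test_from_structures(self, strand):
        lib = rb.build_library([strand], k=3, sources=["fixture"])
        for base in "AUGC":
            frags = lib.templates(base)
            assert frags[0].provenance == STANDARD_PROVENANCE
            assert len(frags) >= 1

    def test_pool_rmsd_histogram_mode_tracks_jitter_scale(self):
        """On a pool of jittered conformers, most fragments sit near the
        jitter-induced RMSD scale rather than at zero or far away."""
        pool = rb.make_fragment_pool("A", 120, seed=9, base_sigma_deg=10,
                                     jitter_sigma=0.15)
        values = np.array([f.rmsd_to_standard for f in pool])
        # per-atom jitter of 0.15 A in both copies -> paired RMSD near
        # 0.15*sqrt(3)-ish after fitting; the bulk must sit in that decade
        assert 0.05 < np.median(values) < 1.0
        assert (values > 0).all()
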