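"""Binding-geometry derivation/transfer, scaffold assembly, B-DNA and
splicing."""

import numpy as np
import pytest

from mbg import fixtures as fx
from mbg.assembly import (BDnaParams, build_bdna, derive_binding_geometry,
                          dna_segment, duplex_sequence, splice_dna, transfer,
                          assemble_on_scaffold)
from mbg.geometry import RigidTransform, apply_transform, rmsd
from mbg.structures import Structure

from conftest import random_rigid_transform


@pytest.fixture
def planted_complex():
    """Chains A and B where B is a rigidly moved copy of A (planted)."""
    a, b, truth = fx.domain_structures(seed=0, with_sidechains=True)
    cx = Structure(id="complex", chains=a.chains + b.chains)
    return cx, a, b, truth


class TestDeriveBindingGeometry:
    def test_planted_transform_recovered(self, planted_complex):
        cx, _, _, truth = planted_complex
        bg = derive_binding_geometry(cx, "A", "B")
        world = bg.world_transform()
        np.testing.assert_allclose(world.rotation,
                                   truth.planted_transform.rotation, atol=1e-9)
        np.testing.assert_allclose(world.translation,
                                   truth.planted_transform.translation, atol=1e-8)

    def test_same_selection_gives_identity(self, planted_complex):
        cx = planted_complex[0]
        bg = derive_binding_geometry(cx, "A", "A")
        assert bg.transform_a_to_b_frame.is_identity(tol=1e-9)

    def test_invariant_under_global_motion(self, planted_complex, rng):
        cx = planted_complex[0]
        bg1 = derive_binding_geometry(cx, "A", "B")
        g = random_rigid_transform(rng)
        moved = cx.with_coords(apply_transform(g, cx.coords()))
        bg2 = derive_binding_geometry(moved, "A", "B")
        np.testing.assert_allclose(bg1.transform_a_to_b_frame.rotation,
                                   bg2.transform_a_to_b_frame.rotation, atol=1e-9)
        np.testing.assert_allclose(bg1.transform_a_to_b_frame.translation,
                                   bg2.transform_a_to_b_frame.translation,
                                   atol=1e-8)

    def test_degenerate_selection(self, planted_complex):
        cx = planted_complex[0]
        with pytest.raises(ValueError):
            derive_binding_geometry(cx, "A:1-1", "B")


class TestTransfer:
    def test_identity_on_template_components(self, planted_complex):
        cx, a, b, _ = planted_complex
        bg = derive_binding_geometry(cx, "A", "B")
        cand = transfer(bg, a, b)
        merged = cand.to_structure()
        assert rmsd(merged.coords(), cx.coords()) <= 1e-9
        assert all(c.superposition_rmsd == pytest.approx(0.0, abs=1e-9)
                   for c in cand.components)

    def test_prerotated_targets_cancel(self, planted_complex, rng):
        cx, a, b, _ = planted_complex
        bg = derive_binding_geometry(cx, "A", "B")
        ga, gb = random_rigid_transform(rng), random_rigid_transform(rng)
        ta = a.with_coords(apply_transform(ga, a.coords()))
        tb = b.with_coords(apply_transform(gb, b.coords()))
        cand = transfer(bg, ta, tb)
        assert rmsd(cand.to_structure().coords(), cx.coords()) <= 1e-6

    def test_noisy_homolog_frame_within_tolerance(self, planted_complex):
        cx, a, b, _ = planted_complex
        bg = derive_binding_geometry(cx, "A", "B")
        noise = np.random.default_rng(5)
        ta = a.with_coords(a.coords() + noise.normal(scale=0.5 / np.sqrt(3),
                                                     size=(a.n_atoms, 3)))
        tb = b.with_coords(b.coords() + noise.normal(scale=0.5 / np.sqrt(3),
                                                     size=(b.n_atoms, 3)))
        cand = transfer(bg, ta, tb)
        assembled = cand.to_structure()
        bg2 = derive_binding_geometry(assembled, "A", "B")
        rel = bg.transform_a_to_b_frame
        rel2 = bg2.transform_a_to_b_frame
        drot = rel.rotation.T @ rel2.rotation
        angle = np.degrees(np.arccos(np.clip((np.trace(drot) - 1) / 2, -1, 1)))
        assert angle <= 5.0
        assert np.linalg.norm(rel.translation - rel2.translation) <= 1.0

    def test_mapping_too_small(self, planted_complex):
        cx, a, b, _ = planted_complex
        bg = derive_binding_geometry(cx, "A", "B")
        with pytest.raises(ValueError):
            transfer(bg, a, b, mapping_a=np.array([[0, 0], [1, 1]]))


class TestAssembleOnScaffold:
    def test_identity_placement(self):
        duplex = build_bdna("ACGTACGTACGTACG")
        comp = fx.make_ideal_helix(6, chain_id="C")
        cand = assemble_on_scaffold(duplex, [("helix", comp,
                                              RigidTransform.identity())])
        np.testing.assert_array_equal(
            cand.component("helix").placed_structure().coords(), comp.coords())

    def test_two_components_clash_free(self):
        from mbg.filters import count_clashes
        duplex = build_bdna("ACGTACGTACGTACGTACGTACGTACGTAC")  # 30 bp
        c1 = fx.make_ideal_helix(5, chain_id="C")
        c2 = fx.make_ideal_helix(5, chain_id="D")
        # explicit transforms placing the helices well off the duplex ends
        t1 = RigidTransform(np.eye(3), np.array([25.0, 0.0, 0.0]))
        t2 = RigidTransform(np.eye(3), np.array([-25.0, 0.0, 95.0]))
        cand = assemble_on_scaffold(duplex, [("c1", c1, t1), ("c2", c2, t2)])
        merged = cand.to_structure()
        assert merged.n_atoms == duplex.n_atoms + c1.n_atoms + c2.n_atoms
        assert count_clashes(cand).n_clash_pairs == 0

    def test_binding_geometry_placement(self, planted_complex):
        cx, a, b, truth = planted_complex
        bg = derive_binding_geometry(cx, "A", "B")
        # scaffold = component A itself; anchor = all of chain A
        cand = assemble_on_scaffold(a, [("b", b, (bg, "A"))])
        merged = cand.to_structure()
        assert rmsd(merged.coords(), cx.coords()) <= 1e-6

    def test_duplicate_placement_clashes(self):
        from mbg.filters import count_clashes
        duplex = build_bdna("ACGTACGTACG")
        comp = fx.make_ideal_helix(5, chain_id="C")
        cand = assemble_on_scaffold(
            duplex, [("c1", comp, RigidTransform(np.eye(3), np.array([30.0, 0, 0]))),
                     ("c2", comp, RigidTransform(np.eye(3), np.array([30.0, 0, 0])))])
        report = count_clashes(cand, exclude_component_pairs=[
            ("scaffold", "c1"), ("scaffold", "c2")])
        assert report.n_clash_pairs >= comp.n_atoms

    def test_chain_collision_renamed(self):
        duplex = build_bdna("ACGTACGTACG")  # chains A, B
        comp = fx.make_ideal_helix(5, chain_id="A")
        cand = assemble_on_scaffold(
            duplex, [("c", comp, RigidTransform(np.eye(3), np.array([30.0, 0, 0])))])
        merged = cand.to_structure()
        assert len(set(merged.chain_ids)) == 3
        assert any("renamed" in n for n in cand.notes)


class TestBuildBdna:
    def test_axis_length_11bp(self):
        duplex = build_bdna("ACGTACGTACG")
        z = [r.atom("P").coords[2] for r in duplex.chains[0].residues]
        assert max(z) - min(z) == pytest.approx(10 * 3.38)

    def test_full_turn_every_10bp(self):
        duplex = build_bdna("ACGTACGTACG")
        p = [r.atom("P").coords for r in duplex.chains[0].residues]
        a0 = np.arctan2(p[0][1], p[0][0])
        a10 = np.arctan2(p[10][1], p[10][0])
        wrapped = ((a10 - a0 + np.pi) % (2 * np.pi)) - np.pi
        assert wrapped == pytest.approx(0.0, abs=1e-9)

    def test_backbone_radius(self):
        params = BDnaParams(backbone_radius=9.4)
        duplex = build_bdna("GATTACA", params)
        for res in duplex.residues():
            r = np.linalg.norm(res.atom("P").coords[:2])
            assert r == pytest.approx(9.4, abs=1e-9)

    def test_strands_are_reverse_complement(self):
        duplex = build_bdna("GATTACA")
        s1 = duplex_sequence(duplex, duplex.chains[0].chain_id)
        s2 = duplex_sequence(duplex, duplex.chains[1].chain_id)
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        assert s2 == "".join(comp[c] for c in reversed(s1))

    def test_glycosidic_atom_naming(self):
        duplex = build_bdna("AG")
        names = {r.res_name: r.atoms[-1].name for r in duplex.chains[0].residues}
        assert names == {"DA": "N9", "DG": "N9"}
        names2 = {r.res_name: r.atoms[-1].name for r in duplex.chains[1].residues}
        assert names2 == {"DC": "N1", "DT": "N1"}

    def test_invalid_sequence(self):
        with pytest.raises(ValueError):
            build_bdna("ACGU")
        with pytest.raises(ValueError):
            build_bdna("A")


class TestSpliceDna:
    def test_self_splice_full_overlap(self):
        duplex = build_bdna("ACGTACGTACGT")
        out = splice_dna(duplex, duplex, (1, 12), (1, 12))
        assert rmsd(out.coords(), duplex.coords()) <= 1e-9

    def test_split_reconstruction(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30 bp
        duplex = build_bdna(seq)
        up = dna_segment(duplex, 1, 18)
        down = dna_segment(duplex, 13, 30)
        out = splice_dna(up, down, (13, 18), (1, 6))
        assert len(out.chains[0]) == 30
        assert rmsd(out.coords(), duplex.coords()) < 1e-6
        assert duplex_sequence(out) == seq

    def test_three_way_split_associative(self):
        duplex = build_bdna("ACGTACGTACGTACGTACGTACGTACGTAC")
        s1 = dna_segment(duplex, 1, 14)
        s2 = dna_segment(duplex, 9, 24)
        s3 = dna_segment(duplex, 19, 30)
        left_first = splice_dna(splice_dna(s1, s2, (9, 14), (1, 6)),
                                s3, (19, 24), (1, 6))
        right_first = splice_dna(s1, splice_dna(s2, s3, (11, 16), (1, 6)),
                                 (9, 14), (1, 6))
        assert rmsd(left_first.coords(), duplex.coords()) < 1e-6
        assert rmsd(right_first.coords(), duplex.coords()) < 1e-6

    def test_bad_overlap_rejected(self):
        duplex = build_bdna("ACGTACGTACGT")
        up = dna_segment(duplex, 1, 8)
        down = dna_segment(duplex, 5, 12)
        # corrupt the downstream overlap beyond the splice-quality limit
        bad = down.copy()
        for res in bad.chains[0].residues[:4]:
            for a in res.atoms:
                a.coords = a.coords + np.array([0.0, 3.0, 0.0]) * (a.serial % 2)
        with pytest.raises(ValueError, match="RMSD"):
            splice_dna(up, bad, (5, 8), (1, 4))

    def test_too_small_overlap(self):
        duplex = build_bdna("ACGTACGTACGT")
        up = dna_segment(duplex, 1, 8)
        down = dna_segment(duplex, 8, 12)
        with pytest.raises(ValueError):
            splice_dna(up, down, (8, 8), (1, 1))
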