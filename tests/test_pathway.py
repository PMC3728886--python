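"""Pathway builder: endpoint derivation, constraints, interpolation frames."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import barrierscreen as bs
from barrierscreen.errors import (
    ConfigurationError,
    CorrespondenceError,
    DerivationError,
)
from barrierscreen.pathway import GLYCOSIDIC_BOND, plan_pathway


class TestDeriveEsFromGe:
    def test_bond_bookkeeping(self, toy):
        es = bs.derive_es_from_ge(toy.ge, toy.rc, toy.phenolic)
        oe1 = toy.rc.atom_a.resolve(es)
        c1 = toy.rc.atom_b.resolve(es)
        o1 = toy.phenolic.resolve(es)
        assert not es.are_linked(oe1, c1)
        assert es.are_linked(c1, o1)

    def test_new_glycosidic_bond_length(self, toy):
        es = bs.derive_es_from_ge(toy.ge, toy.rc, toy.phenolic)
        c1 = toy.rc.atom_b.resolve(es)
        o1 = toy.phenolic.resolve(es)
        assert np.linalg.norm(c1.coords - o1.coords) == pytest.approx(GLYCOSIDIC_BOND)

    def test_leaving_group_moves_rigidly(self, toy):
        es = bs.derive_es_from_ge(toy.ge, toy.rc, toy.phenolic)
        old = next(r for r in toy.ge.residues if r.res_name == "ONP")
        new = next(r for r in es.residues if r.res_name == "ONP")
        shifts = np.array([b.coords - a.coords for a, b in zip(old.atoms, new.atoms)])
        # every atom of the fragment translated by the same vector
        assert np.ptp(shifts, axis=0).max() < 1e-9

    def test_protein_and_sugar_untouched(self, toy):
        es = bs.derive_es_from_ge(toy.ge, toy.rc, toy.phenolic)
        for r_old, r_new in zip(toy.ge.residues, es.residues):
            if r_old.res_name == "ONP":
                continue
            for a, b in zip(r_old.atoms, r_new.atoms):
                assert np.array_equal(a.coords, b.coords)

    def test_non_ge_input_rejected(self, toy):
        es = bs.derive_es_from_ge(toy.ge, toy.rc, toy.phenolic)
        with pytest.raises(DerivationError):
            bs.derive_es_from_ge(es, toy.rc, toy.phenolic)  # already derived

    def test_input_not_mutated(self, toy):
        before = toy.ge.coords_matrix().copy()
        links_before = set(toy.ge.links)
        bs.derive_es_from_ge(toy.ge, toy.rc, toy.phenolic)
        np.testing.assert_array_equal(toy.ge.coords_matrix(), before)
        assert toy.ge.links == links_before


class TestExtractAndModifySubstrate:
    def test_protein_from_ge_substrate_from_es(self, toy):
        mut_es = bs.extract_and_modify_substrate(toy.ge, toy.es)
        for r_ge, r_out in zip(toy.ge.residues, mut_es.residues):
            for a_ge, a_out in zip(r_ge.atoms, r_out.atoms):
                if not a_ge.is_substrate:
                    assert np.array_equal(a_out.coords, a_ge.coords)
        es_sub = {toy.es.atom_key(a): a.coords for a in toy.es.substrate_atoms()}
        for a in mut_es.substrate_atoms():
            np.testing.assert_array_equal(a.coords, es_sub[mut_es.atom_key(a)])

    def test_link_registry_becomes_es_state(self, toy):
        mut_es = bs.extract_and_modify_substrate(toy.ge, toy.es)
        c1 = toy.rc.atom_b.resolve(mut_es)
        o1 = toy.phenolic.resolve(mut_es)
        oe1 = toy.rc.atom_a.resolve(mut_es)
        assert mut_es.are_linked(c1, o1)
        assert not mut_es.are_linked(oe1, c1)

    def test_substrate_mismatch_rejected(self, toy):
        broken = toy.es.copy()
        sub = broken.substrate_atoms()[0]
        sub.name = "ZZ"
        with pytest.raises(CorrespondenceError):
            bs.extract_and_modify_substrate(toy.ge, broken)


class TestBuildConstraints:
    def test_infinite_radius_unconstrained(self, toy):
        k = bs.build_constraints(toy.ge, toy.ge.substrate_atoms(), math.inf)
        assert len(k) == 0

    def test_small_radius_freezes_outer_shell(self, toy):
        k = bs.build_constraints(toy.ge, toy.ge.substrate_atoms(), 6.0, toy.rc)
        assert len(k) > 0
        # fixed serials must belong to residues entirely farther than 6 A
        fixed_res = set()
        for res in toy.ge.residues:
            if any(a.serial in k.fixed_serials for a in res.atoms):
                fixed_res.add(res.key)
                dmin = min(
                    np.linalg.norm(a.coords - sa.coords)
                    for a in res.atoms for sa in toy.ge.substrate_atoms()
                )
                assert dmin > 6.0

    def test_rc_atoms_never_fixed(self, toy):
        for radius in (0.5, 2.0, 6.0, 10.0):
            k = bs.build_constraints(toy.ge, toy.ge.substrate_atoms(), radius, toy.rc)
            for serial in toy.rc.serials(toy.ge):
                assert serial not in k.fixed_serials

    def test_substrate_never_fixed(self, toy):
        k = bs.build_constraints(toy.ge, toy.ge.substrate_atoms(), 2.0, toy.rc)
        for a in toy.ge.substrate_atoms():
            assert a.serial not in k.fixed_serials

    def test_nonpositive_radius_rejected(self, toy):
        with pytest.raises(ValueError):
            bs.build_constraints(toy.ge, toy.ge.substrate_atoms(), 0.0)


class TestMakeFrames:
    def test_frame_count(self, toy):
        frames = bs.make_frames(toy.es, toy.ge, toy.rc, 10)
        assert len(frames) == 12

    def test_endpoints_are_inputs(self, toy):
        frames = bs.make_frames(toy.es, toy.ge, toy.rc, 10)
        np.testing.assert_array_equal(frames[0].structure.coords_matrix(),
                                      toy.es.coords_matrix())
        np.testing.assert_array_equal(frames[-1].structure.coords_matrix(),
                                      toy.ge.coords_matrix())

    def test_x1_targets_arithmetic_progression(self, toy):
        frames = bs.make_frames(toy.es, toy.ge, toy.rc, 10)
        targets = [f.x1_target for f in frames]
        diffs = np.diff(targets)
        np.testing.assert_allclose(diffs, diffs[0], rtol=1e-12)
        assert targets[0] == pytest.approx(toy.rc.measure(toy.es))
        assert targets[-1] == pytest.approx(toy.rc.measure(toy.ge))

    def test_x1_enforced_exactly(self, toy):
        frames = bs.make_frames(toy.es, toy.ge, toy.rc, 10)
        for f in frames:
            assert abs(toy.rc.measure(f.structure) - f.x1_target) < 1e-6

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=30))
    def test_frame_count_property(self, toy, n):
        frames = bs.make_frames(toy.es, toy.ge, toy.rc, n)
        assert len(frames) == n + 2
        targets = [f.x1_target for f in frames]
        assert sorted(targets, reverse=targets[0] > targets[-1]) == targets

    def test_intermediate_coords_are_linear_blend(self, toy):
        frames = bs.make_frames(toy.es, toy.ge, toy.rc, 10)
        ces, cge = toy.es.coords_matrix(), toy.ge.coords_matrix()
        c1_serial = toy.rc.atom_b.resolve(toy.es).serial
        serials = [a.serial for a in toy.es.atoms()]
        for k, f in enumerate(frames[1:-1], start=1):
            t = k / 11
            blend = (1 - t) * ces + t * cge
            got = f.structure.coords_matrix()
            for i, ser in enumerate(serials):
                if ser == c1_serial:
                    continue  # C1 is rescaled to pin x1
                np.testing.assert_allclose(got[i], blend[i], atol=1e-9)

    def test_constrained_atoms_bit_identical_to_origin(self, toy):
        k = bs.build_constraints(toy.ge, toy.ge.substrate_atoms(), 6.0, toy.rc)
        assert len(k) > 0
        frames = bs.make_frames(toy.es, toy.ge, toy.rc, 10, k)
        idx = {a.serial: i for i, a in enumerate(toy.ge.atoms())}
        cge = toy.ge.coords_matrix()
        for f in frames[1:-1]:
            got = f.structure.coords_matrix()
            for ser in k.fixed_serials:
                assert np.array_equal(got[idx[ser]], cge[idx[ser]])

    def test_correspondence_mismatch_rejected(self, toy):
        broken = toy.es.copy()
        broken.residues[0].atoms[0].name = "QQ"
        with pytest.raises(CorrespondenceError):
            bs.make_frames(broken, toy.ge, toy.rc, 10)

    def test_degenerate_endpoints_rejected(self, toy):
        with pytest.raises(DerivationError):
            bs.make_frames(toy.ge, toy.ge, toy.rc, 10)


class TestCloseContactCheck:
    def test_clean_structure_passes(self, toy):
        ok, pairs = bs.close_contact_check(toy.ge, 0.7)
        assert ok and pairs == []

    def test_planted_overlap_detected(self, toy):
        bad = toy.ge.copy()
        # move a shell-residue atom onto a substrate atom
        sub = bad.substrate_atoms()[0]
        shell = next(r for r in bad.residues if r.seq_number == 12)
        shell.atoms[0].coords = sub.coords + np.array([0.3, 0.0, 0.0])
        ok, pairs = bs.close_contact_check(bad, 0.7)
        assert not ok
        assert any(abs(d - 0.3) < 1e-9 for _, _, d in pairs)

    def test_linked_pair_exempt(self, toy):
        # OE1 and C1 are covalently linked in GE at 1.5 A; a dmin just above
        # that distance would flag them were the link not exempt
        ok, pairs = bs.close_contact_check(toy.ge, 1.6)
        flagged = {frozenset(p[:2]) for p in pairs}
        oe1, c1 = toy.rc.serials(toy.ge)
        assert frozenset((oe1, c1)) not in flagged

    def test_same_residue_exempt(self, toy):
        # intra-residue bond distances are ~1.2-1.5 A; none may appear
        ok, pairs = bs.close_contact_check(toy.ge, 1.4)
        res_of = {}
        for res in toy.ge.residues:
            for a in res.atoms:
                res_of[a.serial] = res.key
        for si, sj, _ in pairs:
            assert res_of[si] != res_of[sj]

    def test_nonpositive_dmin_rejected(self, toy):
        with pytest.raises(ValueError):
            bs.close_contact_check(toy.ge, 0.0)


class TestPlanPathway:
    WT = {"wt_ge": None, "wt_ge_opt": None, "wt_es_opt": None, "wt_es_prime_opt": None}

    def test_five_pathways_have_steps(self):
        m = bs.MutationSpec("A", 10, "A", "W")
        for pid in (1, 2, 3, 4, 5):
            plan = plan_pathway(pid, dict(self.WT), None if pid in (1, 2) else m)
            assert plan.pathway_id == pid
            assert len(plan.steps) >= 3

    def test_wild_type_pathways_reject_mutation(self):
        m = bs.MutationSpec("A", 10, "A", "W")
        with pytest.raises(ConfigurationError):
            plan_pathway(2, dict(self.WT), m)

    def test_mutant_pathways_require_mutation(self):
        with pytest.raises(ConfigurationError):
            plan_pathway(5, dict(self.WT), None)

    def test_pathway_3_disallows_constraints(self):
        m = bs.MutationSpec("A", 10, "A", "W")
        with pytest.raises(ConfigurationError):
            plan_pathway(3, dict(self.WT), m, use_constraints=True)
        plan = plan_pathway(5, dict(self.WT), m, use_constraints=True)
        assert plan.uses_constraints

    def test_missing_precursor_rejected(self):
        m = bs.MutationSpec("A", 10, "A", "W")
        with pytest.raises(ConfigurationError):
            plan_pathway(5, {"wt_ge_opt": None}, m)

    def test_unknown_pathway_rejected(self):
        with pytest.raises(ConfigurationError):
            plan_pathway(9, dict(self.WT))


class TestWriteFrames:
    def test_multimodel_pdb_and_sidecar(self, toy, tmp_path):
        frames = bs.make_frames(toy.es, toy.ge, toy.rc, 3)
        pdb = tmp_path / "frames.pdb"
        sidecar = tmp_path / "frames.json"
        bs.write_frames(frames, pdb, sidecar)
        text = pdb.read_text()
        assert text.count("MODEL") == text.count("ENDMDL") == 5
        import json
        meta = json.loads(sidecar.read_text())
        assert [m["index"] for m in meta] == list(range(5))
        assert meta[0]["x1_target"] == pytest.approx(toy.rc.measure(toy.es))
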