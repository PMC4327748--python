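"""Hydrogen-bond energies, turns, helices, bridges, sheets, summaries."""

import warnings

import numpy as np
import pytest

from ssassign.assign import (
    HBondTable,
    assign_bends,
    assign_secondary_structure,
    assign_summary,
    assign_turns,
    build_hbond_table,
    build_ladders_sheets,
    find_bridges,
    hbond_energy,
    map_from_header_records,
    simplify,
)
from ssassign.fixtures import (
    BackboneSpec,
    build_backbone,
    make_alpha_helix,
    make_antiparallel_hairpin,
    make_extended_strand,
    write_pdb,
)
from ssassign.geometry import GeometryRow
from ssassign.pdbio import Atom, Residue, SSRecordSet, layout, place_amide_hydrogens

from conftest import synthetic_chain


def residue_with(res_name="ALA", **atoms):
    res = Residue(chain_id="A", res_seq=1, i_code=" ", res_name=res_name)
    for k, (name, pos) in enumerate(atoms.items()):
        res.atoms[name] = Atom(k + 1, name, " ", name[0], np.asarray(pos, float))
    return res


class TestHBondEnergy:
    def test_symmetric_geometry_cancels_exactly(self):
        # O on the x-axis, N and H mirror images across it: r_ON = r_OH and
        # r_CN = r_CH, so all four terms cancel
        acc = residue_with(C=(0, 0, 0), O=(1.231, 0, 0))
        don = residue_with(N=(3, 1, 0), H=(3, -1, 0))
        assert hbond_energy(acc, don) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # distances r_ON = 2.9, r_CH = 3.9, r_OH = 1.9, r_CN = 3.9
        acc = residue_with(C=(0, 0, 0), O=(2.0, 2.1908902300207, 0))
        don = residue_with(N=(3.9, 0, 0), H=(3.67746, 1.29860, 0))
        assert np.linalg.norm(acc.coord("O") - don.coord("N")) == pytest.approx(2.9, abs=1e-4)
        assert np.linalg.norm(acc.coord("C") - don.coord("H")) == pytest.approx(3.9, abs=1e-4)
        assert np.linalg.norm(acc.coord("O") - don.coord("H")) == pytest.approx(1.9, abs=1e-4)
        expected = 27.888 * (1 / 2.9 + 1 / 3.9 - 1 / 1.9 - 1 / 3.9)
        assert hbond_energy(acc, don) == pytest.approx(expected, abs=2e-3)

    def test_proline_and_missing_h_are_no_donors(self):
        acc = residue_with(C=(0, 0, 0), O=(1.2, 0, 0))
        pro = residue_with(res_name="PRO", N=(3, 0, 0), H=(3.5, 0.8, 0))
        assert hbond_energy(acc, pro) is None
        no_h = residue_with(N=(3, 0, 0))
        assert hbond_energy(acc, no_h) is None

    def test_clash_guard_and_floor(self):
        acc = residue_with(C=(0, 0, 0), O=(1.2, 0, 0))
        clash = residue_with(N=(1.3, 0, 0), H=(1.5, 0.3, 0))  # r_OH = 0.1 < 0.5
        assert hbond_energy(acc, clash) is None
        close = residue_with(N=(2.3, 0, 0), H=(1.85, 0, 0))   # r_OH = 0.65
        assert hbond_energy(acc, close) == -9.9


class TestHBondTable:
    def test_helix_has_i_to_i_plus_4_bonds(self, helix12):
        place_amide_hydrogens(helix12)
        lay = layout(helix12)
        table = build_hbond_table(lay)
        for i in range(1, 7):
            assert table.hb(i, i + 4)

    def test_extended_strand_has_no_bonds(self, strand6):
        place_amide_hydrogens(strand6)
        table = build_hbond_table(layout(strand6))
        assert table.n_bonds() == 0

    def test_hairpin_reciprocal_bonds(self, hairpin5):
        place_amide_hydrogens(hairpin5)
        table = build_hbond_table(layout(hairpin5))
        pairs = [(i, j) for i in range(12) for j in range(12) if table.hb(i, j)]
        reciprocal = [(i, j) for i, j in pairs if (j, i) in pairs and i < j]
        assert len(reciprocal) >= 2
        for i, j in reciprocal:
            assert abs(i - j) >= 3

    def test_predicate_rejects_near_neighbours_and_weak_bonds(self):
        t = HBondTable(6)
        t.add(0, 1, -3.0)
        t.add(0, 4, -0.4)
        t.add(0, 5, -0.6)
        assert not t.hb(0, 1)   # separation < 2
        assert not t.hb(0, 4)   # above the -0.5 cutoff
        assert t.hb(0, 5)

    def test_keeps_two_lowest_energy_partners_with_tie_break(self):
        t = HBondTable(8)
        t.add(0, 3, -1.0)
        t.add(0, 5, -2.0)
        t.add(0, 7, -1.5)
        assert t.donors[0] == [(5, -2.0), (7, -1.5)]
        t2 = HBondTable(8)
        t2.add(0, 6, -1.0)
        t2.add(0, 4, -1.0)
        assert t2.donors[0][0] == (4, -1.0)  # earlier partner wins the tie


class TestTurns:
    def lay12(self):
        return layout(synthetic_chain([(1.5 * i, 0, 0) for i in range(12)]))

    def test_single_bond_makes_one_4_turn(self):
        t = HBondTable(12)
        t.add(4, 8, -1.0)
        starts, marks, t_flag = assign_turns(t, self.lay12())
        assert starts[4][4] is True and sum(starts[4]) == 1
        assert marks[4][4] == ">" and marks[4][8] == "<"
        assert [marks[4][k] for k in (5, 6, 7)] == ["4", "4", "4"]
        assert [k for k, f in enumerate(t_flag) if f] == [5, 6, 7]

    def test_no_bonds_no_turns(self):
        starts, marks, t_flag = assign_turns(HBondTable(12), self.lay12())
        assert not any(any(s) for s in starts.values())
        assert not any(t_flag)

    def test_start_and_end_is_X(self):
        t = HBondTable(12)
        t.add(2, 5, -1.0)
        t.add(5, 8, -1.0)
        _, marks, _ = assign_turns(t, self.lay12())
        assert marks[3][5] == "X"

    def test_turns_refuse_spans_crossing_breaks(self):
        s = synthetic_chain([(1.5 * i, 0, 0) for i in range(12)])
        for atom in s.chains[0].residues[6].atoms.values():
            atom.coord += np.array([30.0, 0, 0])
        lay = layout(s)
        t = HBondTable(12)
        t.add(4, 8, -1.0)
        starts, _, _ = assign_turns(t, lay)
        assert not any(starts[4])


class TestHelices:
    def test_ideal_helix_interior_is_H(self, helix12):
        a = assign_secondary_structure(helix12, with_acc=False)
        assert "".join(a.summary[1:11]) == "H" * 10
        assert a.summary[0] == " " and a.summary[11] == " "

    def test_lone_310_turn_demoted_to_T(self):
        s = build_backbone(BackboneSpec(5, phi=[-49.0] * 5, psi=[-26.0] * 5))
        a = assign_secondary_structure(s, with_acc=False)
        assert "G" not in a.summary
        assert "T" in a.summary

    def test_long_310_run_is_G(self):
        s = build_backbone(BackboneSpec(8, phi=[-49.0] * 8, psi=[-26.0] * 8))
        a = assign_secondary_structure(s, with_acc=False)
        runs = "".join(a.summary).strip()
        assert set(runs) == {"G"} and len(runs) >= 4

    @pytest.mark.parametrize("builder,n", [
        (make_alpha_helix, 4), (make_alpha_helix, 6), (make_alpha_helix, 12),
        (make_antiparallel_hairpin, 5), (make_extended_strand, 8),
    ])
    def test_no_helical_run_shorter_than_four(self, builder, n):
        import re

        a = assign_secondary_structure(builder(n), with_acc=False)
        text = "".join(a.summary)
        for code in "HGI":
            for match in re.finditer(f"{code}+", text):
                assert len(match.group()) >= 4

    def test_short_helix_has_no_assignment(self):
        a = assign_secondary_structure(make_alpha_helix(4), with_acc=False)
        assert "E" not in a.summary and "H" not in a.summary


class TestBridgesLaddersSheets:
    def test_hairpin_bridges_are_antiparallel(self, hairpin5):
        place_amide_hydrogens(hairpin5)
        lay = layout(hairpin5)
        bridges = find_bridges(build_hbond_table(lay), lay)
        assert len(bridges) >= 2
        assert all(kind == "antiparallel" for _, _, kind in bridges)

    def test_helix_has_no_bridges(self, helix12):
        place_amide_hydrogens(helix12)
        lay = layout(helix12)
        assert find_bridges(build_hbond_table(lay), lay) == []

    def test_minimum_separation_enforced(self):
        lay = layout(synthetic_chain([(1.5 * i, 0, 0) for i in range(8)]))
        t = HBondTable(8)
        t.add(2, 4, -2.0)
        t.add(4, 2, -2.0)
        assert find_bridges(t, lay) == []

    def test_hairpin_single_sheet_and_ladder(self, hairpin5):
        a = assign_secondary_structure(hairpin5, with_acc=False)
        sheets = {s for s in a.sheet if s != " "}
        ladders = {l for l in a.ladder1 if l != " "}
        assert len(sheets) == 1 and len(ladders) == 1
        assert next(iter(ladders)).isupper()  # antiparallel

    def test_hairpin_strand_interiors_E_with_mutual_partners(self, hairpin5):
        a = assign_secondary_structure(hairpin5, with_acc=False)
        e_positions = [k for k, s in enumerate(a.summary) if s == "E"]
        assert len(e_positions) >= 4
        for k in e_positions:
            partner = a.bp1[k] - 1
            assert a.bp1[partner] - 1 == k or a.bp2[partner] - 1 == k

    def test_isolated_bridge_is_B(self):
        hp = make_antiparallel_hairpin(3)
        a = assign_secondary_structure(hp, with_acc=False)
        assert a.summary.count("B") == 2
        assert "E" not in a.summary

    def test_two_ladders_sharing_a_strand_share_a_sheet(self):
        bridges = [(2, 10, "antiparallel"), (3, 9, "antiparallel"),
                   (3, 20, "parallel"), (4, 21, "parallel")]
        state, bp1, bp2, lad1, lad2, sheet = build_ladders_sheets(bridges, 24)
        assert state[2] == state[3] == state[9] == state[10] == "E"
        labels = {sheet[k] for k in (2, 3, 9, 10, 20, 21)}
        assert len(labels) == 1
        assert lad1[2].isupper() and lad1[20].islower()
        assert bp1[3] == 10 and bp2[3] == 21


class TestBendsAndSummary:
    @staticmethod
    def rows(kappas):
        return [GeometryRow(kappa=k) for k in kappas]

    def test_bend_thresholds(self):
        assert assign_bends(self.rows([None, 0.0, 69.9, 70.0, 70.1, 120.0])) == [
            False, False, False, False, True, True,
        ]

    def test_elbow_structure_gets_S(self):
        cas = [(-4.5, 0, 0), (-3, 0, 0), (-1.5, 0, 0), (0, 0, 0), (0, 1.5, 0), (0, 3, 0), (0, 4.5, 0)]
        # carbonyls out of the bend plane so no spurious H-bonds form
        a = assign_secondary_structure(
            synthetic_chain(cas, o_directions=[(0, 0, 1)] * 7), with_acc=False
        )
        assert a.summary[3] == "S"

    def test_summary_priority(self):
        assert assign_summary(["H"], [" "], [True], [True]) == ["H"]
        assert assign_summary([" "], ["E"], [False], [True]) == ["E"]
        assert assign_summary([" "], ["B"], [True], [False]) == ["B"]
        assert assign_summary(["G"], [" "], [True], [True]) == ["G"]
        assert assign_summary(["I"], [" "], [True], [True]) == ["I"]
        assert assign_summary([" "], [" "], [True], [True]) == ["T"]
        assert assign_summary([" "], [" "], [False], [True]) == ["S"]
        assert assign_summary([" "], [" "], [False], [False]) == [" "]


class TestSimplify:
    def test_paper_mapping_examples(self):
        assert simplify(list("HHHHGGG")) == ["H"] * 7
        assert simplify(["B"]) == ["-"]
        assert simplify(list("ETS ")) == ["E", "-", "-", "-"]

    def test_total_surjection_preserving_length(self):
        out = simplify(list(" BEGHIST"))
        assert len(out) == 8
        assert set(out) == {"H", "E", "-"}


class TestHeaderMapping:
    def chain10(self):
        return make_alpha_helix(10).chains[0]

    def test_helix_range(self):
        records = SSRecordSet(helices=[("A", (2, " "), (6, " "))])
        labels = map_from_header_records(records, self.chain10())
        assert "".join(labels) == "-HHHHH----"

    def test_empty_records_all_unstructured(self):
        labels = map_from_header_records(SSRecordSet(), self.chain10())
        assert set(labels) == {"-"}

    def test_overlap_resolved_helical_first(self):
        records = SSRecordSet(
            helices=[("A", (4, " "), (6, " "))],
            strands=[("A", (3, " "), (5, " "))],
        )
        labels = map_from_header_records(records, self.chain10())
        assert "".join(labels) == "--EHHH----"

    def test_absent_residue_clips_with_warning(self):
        records = SSRecordSet(helices=[("A", (8, " "), (20, " "))])
        with pytest.warns(UserWarning, match="clipped"):
            labels = map_from_header_records(records, self.chain10())
        assert labels[7] == "H"


class TestWholePipelineProperties:
    def test_assignment_invariant_under_rigid_motion(self, hairpin5, rng):
        ref = assign_secondary_structure(make_antiparallel_hairpin(5), with_acc=False)
        a = rng.normal(size=3)
        a /= np.linalg.norm(a)
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + np.sin(1.1) * K + (1 - np.cos(1.1)) * K @ K
        t = np.array([13.0, -7.0, 4.0])
        for res in hairpin5.residues():
            for atom in res.atoms.values():
                atom.coord = R @ atom.coord + t
        moved = assign_secondary_structure(hairpin5, with_acc=False)
        assert moved.summary == ref.summary
        assert moved.bp1 == ref.bp1

    def test_mirrored_hairpin_keeps_strand_summaries(self):
        plain = assign_secondary_structure(make_antiparallel_hairpin(5), with_acc=False)
        mirrored_structure = make_antiparallel_hairpin(5)
        for res in mirrored_structure.residues():
            for atom in res.atoms.values():
                atom.coord[2] *= -1
        mirrored = assign_secondary_structure(mirrored_structure, with_acc=False)
        assert mirrored.summary == plain.summary

    def test_stretched_structure_loses_all_bonded_states(self, helix12):
        for res in helix12.residues():
            for atom in res.atoms.values():
                atom.coord *= 3.0
        a = assign_secondary_structure(helix12, with_acc=False)
        assert set(a.summary) <= {"S", " "}
        assert a.hbonds.n_bonds() == 0

    def test_agrees_with_independent_dssp_implementation(self, tmp_path):
        mdtraj = pytest.importorskip("mdtraj")
        for builder, n in ((make_alpha_helix, 12), (make_antiparallel_hairpin, 5)):
            structure = builder(n)
            ours = assign_secondary_structure(structure, with_acc=False)
            path = tmp_path / "fixture.pdb"
            path.write_text(write_pdb(structure))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                theirs = mdtraj.compute_dssp(mdtraj.load(str(path)), simplified=False)[0]
            assert list(theirs) == ours.summary
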