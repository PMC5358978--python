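"""Pocket assignment, displacements, filter-lysine H-bonds and clashes."""

import numpy as np
import pytest

from nescan.groove_interactions import (
    PocketFrame,
    anchor_displacements,
    assign_anchors,
    build_pocket_frame,
    clash_filter,
    detect_filter_hbonds,
    nes_criteria_report,
)
from nescan.structure_core import (
    PeptideStructure,
    Residue,
    StructureError,
    compute_dihedrals,
)
from nescan.conformation_classifier import find_conserved_turn
from nescan.synthetic_builder import (
    MockComplexSpec,
    build_backbone,
    build_class_template,
    build_clash_pair,
    build_mock_complex,
)
from conftest import random_rigid_transform


@pytest.fixture(scope="module")
def mock_1c():
    spec = build_class_template("1c")
    return build_mock_complex(MockComplexSpec(backbone=spec)), spec


class TestPocketFrame:
    def test_mock_frame_has_planted_centers(self, mock_1c):
        (pep, frame), spec = mock_1c
        assert set(frame.pocket_centers) == {"P1", "P2", "P3", "P4"}
        for chain_idx, label in enumerate(("P1", "P2", "P3", "P4")):
            res = pep.residues[spec.anchor_positions[chain_idx]]
            assert np.allclose(frame.pocket_centers[label], res.atoms["CB"])

    def test_frame_requires_nz(self):
        with pytest.raises(StructureError, match="NZ"):
            PocketFrame({}, {}, 568, {"CE": np.zeros(3)})

    def test_json_round_trip(self, tmp_path, mock_1c):
        (pep, frame), _ = mock_1c
        path = tmp_path / "frame.json"
        frame.to_json(path)
        back = PocketFrame.from_json(path)
        for k, v in frame.pocket_centers.items():
            assert np.allclose(back.pocket_centers[k], v)
        assert np.allclose(back.nz, frame.nz)
        assert back.filter_lysine_number == frame.filter_lysine_number

    def test_build_from_reference_complex(self, mock_1c, tmp_path):
        """A written mock complex round-trips through build_pocket_frame."""
        from nescan.structure_core import load_complex, write_pdb

        (pep, frame), spec = mock_1c
        # fabricate a CRM1 stand-in chain carrying the filter lysine NZ
        lys = Residue(579, "", "LYS", {
            "N": frame.nz + (3.0, 0, 0), "CA": frame.nz + (2.0, 0, 0),
            "C": frame.nz + (2.0, 1.0, 0), "O": frame.nz + (2.0, 2.0, 0),
            "NZ": frame.nz,
        })
        crm1 = PeptideStructure("B", [lys])
        path = tmp_path / "complex.pdb"
        write_pdb({"A": pep, "B": crm1}, path)
        chains = load_complex(path)
        anchors_authors = [pep.residues[i].author_number for i in spec.anchor_positions]
        built = build_pocket_frame(
            chains, "B", "A", anchors_authors,
            filter_lysine_number=579,
            pocket_labels=("P1", "P2", "P3", "P4"),
        )
        for label in ("P1", "P2", "P3", "P4"):
            assert np.allclose(
                built.pocket_centers[label], frame.pocket_centers[label], atol=5e-4
            )
        assert np.allclose(built.nz, frame.nz, atol=5e-4)

    def test_missing_anchor_listed(self, mock_1c, tmp_path):
        (pep, frame), spec = mock_1c
        lys = Residue(579, "", "LYS", {"CA": frame.nz, "NZ": frame.nz})
        chains = {"A": pep, "B": PeptideStructure("B", [lys])}
        with pytest.raises(StructureError, match="999"):
            build_pocket_frame(chains, "B", "A", [999, 998, 997, 996])


class TestAnchorAssignment:
    def test_planted_anchors_recovered_in_order(self, mock_1c):
        (pep, frame), spec = mock_1c
        amap = assign_anchors(pep, frame)
        assert not amap.insufficient
        assert amap.orientation == "plus"
        expected = {
            pep.residues[i].author_number: f"P{k+1}"
            for k, i in enumerate(spec.anchor_positions)
        }
        assert amap.assignments == expected

    def test_minus_template_reads_minus(self):
        spec = build_class_template("1a-R")
        pep, frame = build_mock_complex(MockComplexSpec(backbone=spec))
        amap = assign_anchors(pep, frame)
        assert amap.orientation == "minus"

    def test_class3_leaves_p4_empty(self):
        spec = build_class_template("3")
        pep, frame = build_mock_complex(MockComplexSpec(backbone=spec))
        amap = assign_anchors(pep, frame)
        assert sorted(amap.assignments.values()) == ["P0", "P1", "P2", "P3"]
        assert not amap.occupancy.get("P4", False)

    def test_displaced_peptide_unassigned(self, mock_1c):
        (pep, frame), _ = mock_1c
        far = pep.transformed(np.eye(3), np.array([20.0, 0.0, 0.0]))
        amap = assign_anchors(far, frame)
        assert amap.n_assigned == 0
        assert amap.insufficient

    def test_assignment_stable_under_residue_order(self, mock_1c):
        (pep, frame), _ = mock_1c
        shuffled = PeptideStructure(pep.chain_id, list(reversed(pep.residues)))
        a1 = assign_anchors(pep, frame)
        a2 = assign_anchors(shuffled, frame)
        assert a1.assignments == a2.assignments


class TestDisplacements:
    def test_identical_peptide_zero_displacement(self, mock_1c):
        (pep, frame), _ = mock_1c
        amap = assign_anchors(pep, frame)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in amap.displacement.values())

    def test_planted_translation_recovered_exactly(self):
        spec = build_class_template("1c")
        pep, frame = build_mock_complex(
            MockComplexSpec(backbone=spec, displace_anchors=1.0)
        )
        amap = assign_anchors(pep, frame)
        for v in amap.displacement.values():
            assert v == pytest.approx(1.0, abs=1e-6)
        table = anchor_displacements([amap])
        for label in amap.displacement:
            assert table[label]["mean"] == pytest.approx(1.0, abs=1e-6)

    def test_cohort_mean_and_sd(self):
        maps = []
        for d in (0.5, 1.0, 1.5):
            spec = build_class_template("1c")
            pep, frame = build_mock_complex(
                MockComplexSpec(backbone=spec, displace_anchors=d)
            )
            maps.append(assign_anchors(pep, frame))
        table = anchor_displacements(maps)
        assert table["P2"]["mean"] == pytest.approx(1.0, abs=1e-6)
        assert table["P2"]["sd"] == pytest.approx(0.5, abs=1e-6)


class TestFilterLysine:
    def test_turn_carbonyls_bond_as_niche_motif(self, mock_1c):
        (pep, frame), spec = mock_1c
        records, motifs, _ = detect_filter_hbonds(pep, frame, expected_direction="plus")
        a = spec.anchor_positions
        bonded = {r.residue_number for r in records}
        # Phi2+1 and Phi3 carbonyls (author numbering = index + 1)
        assert {a[1] + 2, a[2] + 1} <= bonded
        assert any(m.motif_type == "niche4" for m in motifs)

    def test_niche3_for_two_residue_spacing(self):
        spec = build_class_template("1b")
        pep, frame = build_mock_complex(MockComplexSpec(backbone=spec))
        _, motifs, _ = detect_filter_hbonds(pep, frame)
        assert any(m.motif_type == "niche3" for m in motifs)

    def test_nz_moved_out_of_range_loses_bonds(self, mock_1c):
        (pep, frame), _ = mock_1c
        direction = frame.nz - pep.residues[7].atoms["O"]
        direction /= np.linalg.norm(direction)
        far = PocketFrame(
            frame.pocket_centers,
            frame.reference_anchor_cas,
            frame.filter_lysine_number,
            {"NZ": frame.nz + 1.3 * direction},  # now ~4.2 A or more from both
        )
        records, motifs, _ = detect_filter_hbonds(pep, far)
        assert records == [] and motifs == []

    def test_hbond_geometry_invariant_under_joint_transform(self, rng, mock_1c):
        (pep, frame), _ = mock_1c
        base = detect_filter_hbonds(pep, frame)[0]
        R, t = random_rigid_transform(rng)
        moved_pep = pep.transformed(R, t)
        from nescan.structure_core import SuperpositionResult

        moved_frame = frame.transformed(
            SuperpositionResult(rotation=R, translation=t, rmsd=0.0, n_atoms=0)
        )
        moved = detect_filter_hbonds(moved_pep, moved_frame)[0]
        assert [r.residue_number for r in moved] == [r.residue_number for r in base]
        for a, b in zip(moved, base):
            assert a.distance == pytest.approx(b.distance, abs=1e-9)
            assert a.angle == pytest.approx(b.angle, abs=1e-6)


class TestClashFilter:
    def test_true_nes_passes_blocked_helix_clashes(self):
        true_pep, false_pep, frame = build_clash_pair()
        assert not clash_filter(true_pep, frame).clashing
        report = clash_filter(false_pep, frame)
        assert report.clashing
        assert report.worst_overlap > 0.4
        # the clash involves the extension past the true chain's end
        clash_residues = {c[0].split("/")[0] for c in report.contacts}
        assert any(int(r[3:]) > len(true_pep) for r in clash_residues)

    def test_reference_peptide_never_clashes_its_own_frame(self, mock_1c):
        (pep, frame), _ = mock_1c
        assert not clash_filter(pep, frame).clashing

    def test_clash_invariant_under_joint_transform(self, rng):
        _, false_pep, frame = build_clash_pair()
        base = clash_filter(false_pep, frame)
        R, t = random_rigid_transform(rng)
        from nescan.structure_core import SuperpositionResult

        res = SuperpositionResult(rotation=R, translation=t, rmsd=0.0, n_atoms=0)
        moved = clash_filter(false_pep.transformed(R, t), frame.transformed(res))
        assert moved.worst_overlap == pytest.approx(base.worst_overlap, abs=1e-9)
        assert len(moved.contacts) == len(base.contacts)


class TestCriteriaReport:
    @pytest.mark.parametrize("label", ["1a", "1b", "1c", "1d", "2", "3", "4",
                                       "1a-R", "1b-R", "1c-R", "1d-R"])
    def test_every_class_template_is_an_active_nes(self, label):
        spec = build_class_template(label)
        pep, frame = build_mock_complex(MockComplexSpec(backbone=spec))
        amap = assign_anchors(pep, frame)
        hbonds, _, _ = detect_filter_hbonds(pep, frame)
        clash = clash_filter(pep, frame)
        turn = find_conserved_turn(compute_dihedrals(pep))
        report = nes_criteria_report(amap, turn, hbonds, clash)
        assert report["active_nes"], (label, report["failed_criteria"])

    def test_all_strand_peptide_fails_turn_criterion(self):
        import numpy as np
        from nescan.synthetic_builder import STRAND, BackboneSpec

        pep = build_backbone(
            BackboneSpec("LALALALALA", np.full(10, STRAND[0]), np.full(10, STRAND[1]))
        )
        spec = build_class_template("1c")
        _, frame = build_mock_complex(MockComplexSpec(backbone=spec))
        amap = assign_anchors(pep, frame)
        hbonds, _, _ = detect_filter_hbonds(pep, frame)
        clash = clash_filter(pep, frame)
        turn = find_conserved_turn(compute_dihedrals(pep))
        report = nes_criteria_report(amap, turn, hbonds, clash)
        assert not report["active_nes"]
        assert "conserved-one-turn-helix" in report["failed_criteria"]

    def test_blocked_helix_fails_lysine_criterion(self):
        _, false_pep, frame = build_clash_pair()
        amap = assign_anchors(false_pep, frame)
        hbonds, _, _ = detect_filter_hbonds(false_pep, frame)
        clash = clash_filter(false_pep, frame)
        turn = find_conserved_turn(compute_dihedrals(false_pep))
        report = nes_criteria_report(amap, turn, hbonds, clash)
        assert not report["active_nes"]
        assert "filter-lysine-hydrogen-bonding" in report["failed_criteria"]
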