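"""Secondary structure, the conserved one-turn helix, and class calling."""

import numpy as np
import pytest

from nescan.conformation_classifier import (
    assign_sse,
    classify_peptide,
    evaluate_turn_psis,
    find_conserved_turn,
    psi_progression,
)
from nescan.sequence_patterns import scan_sequence
from nescan.structure_core import compute_dihedrals
from nescan.synthetic_builder import (
    ALPHA,
    STRAND,
    THREE10,
    BackboneSpec,
    build_backbone,
    build_class_template,
)
from conftest import random_rigid_transform

# Printed conserved-turn psi series (degrees, chain order).
HDAC5_TURN_PSIS = (-43.5, -21.7, -1.3, 133.8)
CPEB4_TURN_PSIS = (111.5, 16.5, -31.0, -40.2)


def _uniform(seq_len, pair, letter="A"):
    return BackboneSpec(letter * seq_len, np.full(seq_len, pair[0]), np.full(seq_len, pair[1]))


class TestAssignSSE:
    def test_alpha_helix_labelled_H(self):
        p = build_backbone(_uniform(12, ALPHA))
        sse = assign_sse(compute_dihedrals(p), p)
        assert set(sse) == {"H"}

    def test_310_helix_labelled_G_via_i3_hbonds(self):
        p = build_backbone(_uniform(8, THREE10))
        # confirm the hydrogen-bond geometry directly: O(i)..N(i+3) bonded,
        # O(i)..N(i+4) broken
        d3 = np.linalg.norm(p.residues[0].atoms["O"] - p.residues[3].atoms["N"])
        d4 = np.linalg.norm(p.residues[0].atoms["O"] - p.residues[4].atoms["N"])
        assert d3 < 3.5 < d4
        sse = assign_sse(compute_dihedrals(p), p)
        assert set(sse) == {"G"}

    def test_strand_labelled_E(self):
        p = build_backbone(_uniform(6, STRAND))
        sse = assign_sse(compute_dihedrals(p), p)
        assert set(sse) == {"E"}

    def test_short_helical_run_demoted(self):
        n = 8
        phi = np.full(n, STRAND[0])
        psi = np.full(n, STRAND[1])
        phi[3:5] = ALPHA[0]
        psi[3:5] = ALPHA[1]
        p = build_backbone(BackboneSpec("A" * n, phi, psi))
        sse = assign_sse(compute_dihedrals(p), p)
        assert "H" not in sse and "G" not in sse

    def test_class4_template_shows_helix_then_beta_turn(self):
        spec = build_class_template("4")
        p = build_backbone(spec)
        sse = assign_sse(compute_dihedrals(p), p)
        t = spec.anchor_positions[3] + 1
        assert "H" * 8 in sse
        assert sse[t + 1 : t + 3] == "TT"

    def test_invariant_under_rigid_transform(self, rng):
        spec = build_class_template("1a")
        p = build_backbone(spec)
        base = assign_sse(compute_dihedrals(p), p)
        for _ in range(3):
            R, t = random_rigid_transform(rng)
            moved = p.transformed(R, t)
            assert assign_sse(compute_dihedrals(moved), moved) == base


class TestConservedTurn:
    def test_accepts_printed_plus_series(self):
        ok, direction = evaluate_turn_psis(HDAC5_TURN_PSIS)
        assert ok and direction == "plus"

    def test_accepts_printed_minus_series(self):
        ok, direction = evaluate_turn_psis(CPEB4_TURN_PSIS)
        assert ok and direction == "minus"

    def test_rejects_pure_helix_series_without_terminus(self):
        ok, _ = evaluate_turn_psis((-47.0, -47.0, -47.0, -47.0))
        assert not ok

    def test_all_strand_peptide_has_no_turn(self):
        p = build_backbone(_uniform(10, STRAND))
        assert find_conserved_turn(compute_dihedrals(p)) is None

    def test_all_loop_peptide_has_no_turn(self):
        p = build_backbone(_uniform(10, (-80.0, 55.0)))
        assert find_conserved_turn(compute_dihedrals(p)) is None

    def test_located_at_phi2_phi3_span(self):
        spec = build_class_template("1a")
        p = build_backbone(spec)
        a = spec.anchor_positions
        turn = find_conserved_turn(compute_dihedrals(p), phi2_index=a[1], phi3_index=a[2])
        assert turn is not None and turn.span == (a[1], a[2])

    def test_five_residue_span_tolerated(self):
        # Phi2-X3-Phi3 spacing: the 4-residue window floats inside the span
        spec = build_class_template("1d")
        p = build_backbone(spec)
        a = spec.anchor_positions
        turn = find_conserved_turn(compute_dihedrals(p), phi2_index=a[1], phi3_index=a[2])
        assert turn is not None
        assert a[1] <= turn.start and turn.start + 3 <= a[2]

    def test_missing_anchors_error(self):
        p = build_backbone(_uniform(10, ALPHA))
        with pytest.raises(ValueError, match="turn undefined"):
            find_conserved_turn(compute_dihedrals(p), phi2_index=8, phi3_index=2)

    def test_accepts_all_class_templates(self, class_templates):
        for label, (spec, p) in class_templates.items():
            assert find_conserved_turn(compute_dihedrals(p)) is not None, label


class TestPsiProgression:
    def test_hdac5_series_increases(self):
        from nescan.conformation_classifier import ConservedTurn

        rep = psi_progression(ConservedTurn(0, HDAC5_TURN_PSIS, "plus"))
        assert rep["monotone"] and rep["direction"] == "plus"
        assert rep["series"] == HDAC5_TURN_PSIS

    def test_cpeb4_series_decreases(self):
        from nescan.conformation_classifier import ConservedTurn

        rep = psi_progression(ConservedTurn(0, CPEB4_TURN_PSIS, "minus"))
        assert rep["monotone"] and rep["direction"] == "minus"

    def test_single_small_backtrack_tolerated(self):
        from nescan.conformation_classifier import ConservedTurn

        rep = psi_progression(ConservedTurn(0, (-43.0, -21.0, -25.0, 130.0), "plus"))
        assert rep["monotone"]
        rep = psi_progression(ConservedTurn(0, (-43.0, -21.0, -40.0, 130.0), "plus"))
        assert not rep["monotone"]


class TestClassCalling:
    @pytest.mark.parametrize(
        "label,shape,orientation",
        [
            ("1a", "helix-strand", "plus"),
            ("1b", "310-strand", "plus"),
            ("1c", "helix-strand", "plus"),
            ("1d", "helix-strand", "plus"),
            ("2", "loop", "plus"),
            ("3", "all-helix", "plus"),
            ("4", "helix-beta-turn", "plus"),
            ("1a-R", "strand-helix", "minus"),
            ("1b-R", "strand-helix", "minus"),
            ("1c-R", "strand-helix", "minus"),
            ("1d-R", "strand-helix", "minus"),
        ],
    )
    def test_noise_free_templates_recover_generating_class(
        self, class_templates, label, shape, orientation
    ):
        spec, p = class_templates[label]
        call = classify_peptide(p, matches=scan_sequence(spec.sequence))
        assert call.class_label == label
        assert call.shape == shape
        assert call.orientation == orientation
        assert call.is_nes_like

    @pytest.mark.parametrize(
        "label,shape",
        [
            ("1a", "helix-strand"),
            ("1b", "310-strand"),
            ("2", "loop"),
            ("3", "all-helix"),
            ("4", "helix-beta-turn"),
            ("1a-R", "strand-helix"),
        ],
    )
    def test_class_recovery_under_dihedral_noise(self, label, shape):
        """>= 95% of 100 noisy builds (sigma = 8 deg) recover their class."""
        ok = 0
        for seed in range(100):
            spec = build_class_template(label, noise_sigma=8.0, seed=seed)
            p = build_backbone(spec)
            call = classify_peptide(p, matches=scan_sequence(spec.sequence))
            ok += call.class_label == label and call.shape == shape
        assert ok >= 95

    def test_not_nes_like_without_turn(self):
        p = build_backbone(_uniform(10, STRAND))
        call = classify_peptide(p)
        assert not call.is_nes_like
        assert call.class_label is None
        assert any("turn" in n for n in call.notes)

    def test_reversing_plus_template_reads_minus(self):
        """Building the reversed residue order of a (+) NES yields a (-) call."""
        spec = build_class_template("1a")
        rev = BackboneSpec(
            sequence=spec.sequence[::-1],
            # keep each residue's conformation but reverse the segment
            # order along the chain: strand first, then helix
            phi=spec.phi[::-1].copy(),
            psi=spec.psi[::-1].copy(),
        )
        p = build_backbone(rev)
        call = classify_peptide(p, matches=scan_sequence(rev.sequence))
        assert call.orientation == "minus"
        assert call.shape == "strand-helix"
        assert call.class_label == "1a-R"

    def test_groove_orientation_hint_dominates(self, class_templates):
        spec, p = class_templates["3"]
        call = classify_peptide(p, matches=scan_sequence(spec.sequence),
                                orientation_hint="plus")
        assert call.orientation == "plus"
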