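"""Backbone-conformation classification of CRM1-bound NES peptides.

NESs reach the CRM1 groove in five to six distinct backbone shapes —
helix-strand (classes 1a/1c/1d), 3-10-helix-strand (1b), mostly-loop (2),
all-helix (3), helix-beta-turn (4) and strand-helix (the reversed class-1
family) — yet all of them share a single structural element: one turn of
helix spanning Phi2-X(2-3)-Phi3, whose psi angles walk from helical values
up into the beta range as the chain leaves the constriction of the groove.

This module assigns per-residue secondary structure from backbone
dihedrals, locates the conserved one-turn helix, checks the psi-angle
progression along it, and calls the conformational class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_patterns import PATTERN_LIBRARY, PatternMatch
from .structure_core import DihedralSeries, PeptideStructure

__all__ = [
    "SSE_H", "SSE_G", "SSE_E", "SSE_T", "SSE_L",
    "ConservedTurn",
    "ClassCall",
    "assign_sse",
    "find_conserved_turn",
    "evaluate_turn_psis",
    "psi_progression",
    "call_class",
    "classify_peptide",
]

SSE_H, SSE_G, SSE_E, SSE_T, SSE_L = "H", "G", "E", "T", "L"

# --- dihedral windows (degrees) --------------------------------------------
# Helical gate: wide enough to hold both alpha (-57,-47) and 3-10 (-49,-26)
# conformers under crystallographic/thermal scatter; alpha vs 3-10 is then
# separated by carbonyl hydrogen bonding, not by dihedrals.
HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-77.0, 10.0)
# Extended/strand gate.
STRAND_PSI = (85.0, 180.0)
STRAND_PHI_MAX = -45.0
# Type I beta-turn central residues i+1, i+2: canonical (phi, psi) pairs,
# matched within +/- 30 degrees.
TURN_I_C1 = (-60.0, -30.0)
TURN_I_C2 = (-90.0, 0.0)
TURN_TOL = 30.0
TURN_CA_DIST = 7.0
# Conserved one-turn-helix psi windows.  The helical face is wider than the
# SSE helical gate because the final helical psi of the turn has already
# started its climb toward the beta range.
TURN_HELICAL_PSI = (-90.0, 45.0)
TURN_STRAND_PSI = (85.0, 180.0)
#: Allowed single backtrack (degrees) in the "gradually increasing" psi check.
PROGRESSION_SLACK = 5.0

HBOND_NO_CUTOFF = 3.5  # O(i)..N(i+k) carbonyl H-bond distance, angstrom
MIN_HELIX_RUN = 3


def _in(x: float, window: tuple[float, float]) -> bool:
    return window[0] < x < window[1]


def assign_sse(d: DihedralSeries, p: PeptideStructure) -> str:
    """Per-residue secondary-structure string (H/G/E/T/L).

    Helical-dihedral runs of >= 3 become H (alpha) or G (3-10) depending on
    whether i->i+4 or i->i+3 carbonyl O..N hydrogen bonds dominate inside
    the run; shorter helical runs are demoted.  E requires strand psi with
    phi < -45; T marks type I beta-turns (canonical central dihedrals within
    +/-30 degrees and CA(i)-CA(i+3) < 7 angstrom); everything else is L.

    Missing O atoms disable the helix-type split; such runs are labelled H
    and the condition is recorded on the returned string's ``warning``
    attribute (a plain string is returned; callers needing the flag use
    :func:`classify_peptide`).
    """
    n = len(p)
    phi, psi = d.phi, d.psi
    helical = np.zeros(n, dtype=bool)
    for i in range(n):
        # Termini: judge on whichever torsions exist.
        ok_phi = np.isnan(phi[i]) or _in(phi[i], HELIX_PHI)
        ok_psi = np.isnan(psi[i]) or _in(psi[i], HELIX_PSI)
        defined = not (np.isnan(phi[i]) and np.isnan(psi[i]))
        helical[i] = defined and ok_phi and ok_psi

    labels = [SSE_L] * n
    have_o = all("O" in r.atoms for r in p.residues)
    if not have_o:
        import warnings

        warnings.warn(
            "missing O atoms: helical runs labelled H without 3-10 check",
            stacklevel=2,
        )

    # helix runs
    i = 0
    while i < n:
        if not helical[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and helical[j + 1]:
            j += 1
        if j - i + 1 >= MIN_HELIX_RUN:
            kind = _helix_kind(p, i, j) if have_o else SSE_H
            for k in range(i, j + 1):
                labels[k] = kind
        i = j + 1

    # beta-turns (only where not already helix)
    ca = p.coords("CA")
    for i in range(n - 3):
        c1, c2 = i + 1, i + 2
        if labels[c1] in (SSE_H, SSE_G) or labels[c2] in (SSE_H, SSE_G):
            continue
        if np.isnan(phi[c1]) or np.isnan(psi[c1]) or np.isnan(phi[c2]) or np.isnan(psi[c2]):
            continue
        if (
            abs(phi[c1] - TURN_I_C1[0]) <= TURN_TOL
            and abs(psi[c1] - TURN_I_C1[1]) <= TURN_TOL
            and abs(phi[c2] - TURN_I_C2[0]) <= TURN_TOL
            and abs(psi[c2] - TURN_I_C2[1]) <= TURN_TOL
            and np.linalg.norm(ca[i] - ca[i + 3]) < TURN_CA_DIST
        ):
            labels[c1] = SSE_T
            labels[c2] = SSE_T

    # strand; a terminal residue with only phi defined counts when that phi
    # is clearly outside the helical gate
    for i in range(n):
        if labels[i] != SSE_L:
            continue
        if not np.isnan(psi[i]):
            if STRAND_PSI[0] <= psi[i] <= STRAND_PSI[1] and (
                np.isnan(phi[i]) or phi[i] < STRAND_PHI_MAX
            ):
                labels[i] = SSE_E
        elif not np.isnan(phi[i]) and phi[i] <= HELIX_PHI[0]:
            labels[i] = SSE_E
    return "".join(labels)


def _helix_kind(p: PeptideStructure, i: int, j: int) -> str:
    """Alpha vs 3-10 for a helical run, by carbonyl O..N bonding pattern.

    In an alpha-helix both O(i)..N(i+3) and O(i)..N(i+4) sit near 3.1-3.2
    angstrom, while a 3-10 helix bonds i->i+3 tightly (~2.8) and leaves
    i->i+4 far beyond bonding range (~4.9).  A residue therefore votes 3-10
    only when its i+3 contact is bonded and its i+4 contact is clearly
    broken; an intact i+4 contact votes alpha.
    """
    d3s, d4s = [], []
    for k in range(i, j + 1):
        o = p.residues[k].atoms.get("O")
        if o is None:
            continue
        # only acceptor partners inside the run: junction residues would
        # pollute the averages
        if k + 3 <= j:
            d3s.append(float(np.linalg.norm(o - p.residues[k + 3].atoms["N"])))
        if k + 4 <= j:
            d4s.append(float(np.linalg.norm(o - p.residues[k + 4].atoms["N"])))
    # Run-averaged ladder comparison: in an alpha-helix the i->i+4 contacts
    # are as short as the i->i+3 ones (~3.1 A both), while a 3-10 helix
    # keeps i->i+3 bonded (~2.8) and i->i+4 far out of range (~4.9).  The
    # gap between the two averages separates the geometries with a wide
    # margin on either side.
    if d3s and d4s:
        return SSE_G if np.mean(d4s) - np.mean(d3s) > 0.8 else SSE_H
    if d3s:
        return SSE_G if np.mean(d3s) <= 3.0 else SSE_H
    return SSE_H


# ---------------------------------------------------------------------------
# Conserved one-turn helix

@dataclass
class ConservedTurn:
    """The single turn of helix shared by all NES conformations."""

    start: int          # chain index of the first residue of the 4-residue window
    psi_series: tuple[float, ...]
    direction: str      # "plus" | "minus"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.start + 3)


def evaluate_turn_psis(psis, allow_terminal: bool = False):
    """Judge a 4-residue psi series (chain order) as a conserved turn.

    (+) turns read helical, helical, helical then strand; (-) turns read
    strand then three helical values (the mirror along the chain).  With
    ``allow_terminal`` the strand slot may instead be a chain terminus
    (undefined psi): class 3 helices simply end as the chain exits the
    groove.

    Returns (accepted, direction) with direction in {"plus", "minus", None}.
    """
    psis = [float("nan") if v is None else float(v) for v in psis]
    if len(psis) != 4:
        raise ValueError("a turn window has exactly 4 residues")

    def helical(v):
        return not np.isnan(v) and _in(v, TURN_HELICAL_PSI)

    def strand(v):
        return not np.isnan(v) and TURN_STRAND_PSI[0] <= v <= TURN_STRAND_PSI[1]

    def exiting(v):
        return bool(np.isnan(v))

    if all(helical(v) for v in psis[:3]):
        if strand(psis[3]) or (allow_terminal and exiting(psis[3])):
            return True, "plus"
    if all(helical(v) for v in psis[1:]):
        if strand(psis[0]) or (allow_terminal and exiting(psis[0])):
            return True, "minus"
    return False, None


def find_conserved_turn(
    d: DihedralSeries,
    phi2_index: int | None = None,
    phi3_index: int | None = None,
    direction_hint: str | None = None,
    allow_terminal: bool = True,
) -> ConservedTurn | None:
    """Locate the conserved one-turn helix.

    When the Phi2/Phi3 anchor indices are known, only 4-residue windows
    inside Phi2..Phi3 are considered (the spacing may be X2 or X3, i.e. a
    4- or 5-residue span); otherwise every window is scanned.  Returns None
    when no window qualifies.
    """
    psi = d.psi
    n = len(psi)
    if phi2_index is not None and phi3_index is not None:
        if not 0 <= phi2_index < phi3_index < n:
            raise ValueError("turn undefined: bad Phi2/Phi3 indices")
        span = phi3_index - phi2_index
        if span not in (3, 4):
            raise ValueError("turn undefined: Phi2..Phi3 must span 4-5 residues")
        # Phi2-X2-Phi3 hosts one 4-residue window, Phi2-X3-Phi3 two.
        starts = [s for s in range(phi2_index, phi3_index - 2) if s + 3 < n]
    else:
        starts = list(range(n - 3))

    best = None
    for s in starts:
        window = [psi[s + k] for k in range(4)]
        ok, direction = evaluate_turn_psis(window, allow_terminal=allow_terminal)
        if not ok:
            continue
        turn = ConservedTurn(start=s, psi_series=tuple(window), direction=direction)
        if direction_hint is not None and direction == direction_hint:
            return turn
        if best is None:
            best = turn
    return best


def psi_progression(turn: ConservedTurn) -> dict:
    """Monotonicity of the psi walk along the conserved turn.

    (+) turns should be non-decreasing along the chain and (-) turns
    non-increasing (psi climbs from helical toward beta values in the
    pocket direction).  One backtrack of at most 5 degrees is tolerated.
    """
    series = np.array(turn.psi_series, dtype=float)
    diffs = np.diff(series)
    if turn.direction == "minus":
        diffs = -diffs
    violations = diffs[diffs < 0]
    monotone = len(violations) == 0 or (
        len(violations) == 1 and abs(float(violations[0])) <= PROGRESSION_SLACK
    )
    return {
        "series": tuple(float(v) for v in series),
        "direction": turn.direction,
        "monotone": bool(monotone),
    }


# ---------------------------------------------------------------------------
# Class calling

SHAPE_HELIX_STRAND = "helix-strand"
SHAPE_310_STRAND = "310-strand"
SHAPE_LOOP = "loop"
SHAPE_ALL_HELIX = "all-helix"
SHAPE_HELIX_BETA_TURN = "helix-beta-turn"
SHAPE_STRAND_HELIX = "strand-helix"


@dataclass
class ClassCall:
    class_label: str | None
    shape: str | None
    orientation: str | None
    is_nes_like: bool
    turn: ConservedTurn | None
    notes: list[str]


def _runs(labels: str, kinds: str) -> list[tuple[int, int]]:
    runs = []
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] in kinds:
            j = i
            while j + 1 < n and labels[j + 1] in kinds:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _pick_class(matches: list[PatternMatch], candidates: tuple[str, ...]) -> str | None:
    order = {c: k for k, c in enumerate(candidates)}
    hits = sorted(
        (m for m in matches if m.class_label in order),
        key=lambda m: order[m.class_label],
    )
    return hits[0].class_label if hits else None


def call_class(
    sse: str,
    turn: ConservedTurn | None,
    matches: list[PatternMatch] | None = None,
    orientation_hint: str | None = None,
) -> ClassCall:
    """Call the conformational class from SSE labels and the conserved turn.

    The decision table mirrors the observed shape families: a long helix
    followed by a type I beta-turn is class 4; an uninterrupted helix that
    simply ends is class 3; 3-10-helix-then-strand is 1b; strand-then-helix
    binds in the minus direction (class 1-R family); alpha-helix-then-strand
    is 1a/1c/1d, separated by anchor spacing; a loop-dominated chain with
    the conserved turn is class 2.  A groove-derived orientation hint, when
    present, dominates the geometric reading.
    """
    matches = matches or []
    notes: list[str] = []
    n = len(sse)
    h_runs = _runs(sse, SSE_H)
    g_runs = _runs(sse, SSE_G)
    helix_runs = sorted(h_runs + g_runs)
    e_positions = [i for i, c in enumerate(sse) if c == SSE_E]
    t_positions = [i for i, c in enumerate(sse) if c == SSE_T]
    frac_loop = sse.count(SSE_L) / n if n else 0.0

    if turn is None:
        return ClassCall(None, None, None, False, None,
                         ["no conserved one-turn helix found"])

    longest_helix = max(helix_runs, key=lambda r: r[1] - r[0], default=None)

    shape = None
    label = None
    orientation = "plus"

    # Loop-dominated chains (class 2) are recognized first: their only
    # helical content is the conserved turn itself.
    if frac_loop >= 0.5:
        shape, label = SHAPE_LOOP, "2"

    if shape is None and longest_helix is not None:
        h0, h1 = longest_helix
        hlen = h1 - h0 + 1
        strand_after = [i for i in e_positions if i > h1]
        strand_before = [i for i in e_positions if i < h0]
        turn_after = [i for i in t_positions if i > h1]
        is_310 = all(sse[k] == SSE_G for k in range(h0, h1 + 1))

        if hlen >= 8 and turn_after and not is_310:
            shape, label = SHAPE_HELIX_BETA_TURN, "4"
        elif len(strand_before) >= 2 and hlen >= 4 and not strand_after:
            shape = SHAPE_STRAND_HELIX
            orientation = "minus"
            label = _pick_class(matches, ("1a-R", "1b-R", "1c-R", "1d-R")) or "1a-R"
        elif hlen >= 7 and not strand_after and not turn_after and h1 >= n - 3:
            shape, label = SHAPE_ALL_HELIX, "3"
            notes.append("structural anchor labels Phi0..Phi3; P4 unused")
        elif is_310 and hlen >= 3 and strand_after:
            shape, label = SHAPE_310_STRAND, "1b"
        elif hlen >= 6 and strand_after:
            shape = SHAPE_HELIX_STRAND
            label = _pick_class(matches, ("1a", "1c", "1d")) or "1a"

    if shape is None and frac_loop >= 0.35:
        shape, label = SHAPE_LOOP, "2"

    if shape is None:
        return ClassCall(None, None, None, False, turn,
                         ["conformation matches no known NES shape family"])

    if orientation_hint is not None and orientation_hint != orientation:
        notes.append(
            f"groove pocket order ({orientation_hint}) overrides geometric "
            f"reading ({orientation})"
        )
        orientation = orientation_hint
    elif orientation_hint is None and shape not in (SHAPE_STRAND_HELIX,):
        # geometric reading only; flag residual ambiguity for symmetric shapes
        if turn.direction == "minus" and orientation == "plus":
            notes.append("orientation ambiguous without groove evidence")

    seq_labels = sorted({m.class_label for m in matches})
    if seq_labels and label not in seq_labels:
        notes.append(
            f"sequence pattern ({','.join(seq_labels)}) and structural call "
            f"({label}) disagree; both reported"
        )

    return ClassCall(label, shape, orientation, True, turn, notes)


def classify_peptide(
    p: PeptideStructure,
    matches: list[PatternMatch] | None = None,
    orientation_hint: str | None = None,
) -> ClassCall:
    """Dihedrals -> SSE -> conserved turn -> class call, in one step."""
    from .structure_core import compute_dihedrals

    d = compute_dihedrals(p)
    sse = assign_sse(d, p)
    turn = find_conserved_turn(d, direction_hint=orientation_hint)
    return call_class(sse, turn, matches=matches, orientation_hint=orientation_hint)
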