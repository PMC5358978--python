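"""Pocket assignment, filter-lysine hydrogen bonds and the steric filter.

The CRM1 groove presents five hydrophobic pockets, P0 at the wide end
through P4 at the constriction, which is capped by the filter lysine
(ScCRM1 Lys579 / Hs-MmCRM1 Lys568).  A bound NES places 3-5 hydrophobic
anchors into the pockets; its backbone donates two carbonyls (Phi2+1 and
Phi3 in plus NESs, the N-terminal strand carbonyls in minus NESs) to the
lysine ammonium in a niche3/niche4-type arrangement; and any chain that
fails to transition to strand or terminate before the constriction runs
into the lysine side chain sterically.  The three checks together form the
active-NES criteria: (1) 3-5 anchors in pockets, (2) the conserved one-turn
helix, (3) backbone hydrogen bonding with (and no clash against) the filter
lysine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_core import (
    PeptideStructure,
    StructureError,
    SuperpositionResult,
)

__all__ = [
    "PocketFrame",
    "AnchorMap",
    "HBondRecord",
    "NicheMotif",
    "ClashReport",
    "build_pocket_frame",
    "assign_anchors",
    "anchor_displacements",
    "detect_filter_hbonds",
    "clash_filter",
    "nes_criteria_report",
    "VDW_RADII",
    "POCKET_CUTOFF",
    "HBOND_CUTOFF",
    "HBOND_MIN_ANGLE",
    "CLASH_OVERLAP",
]

PHI_RESIDUE_NAMES = {"LEU", "VAL", "ILE", "PHE", "MET"}
BACKBONE_SET = {"N", "CA", "C", "O", "OXT"}

#: Side-chain-centroid to pocket-center assignment cutoff (angstrom); must
#: exceed the largest observed mean anchor displacement (1.8 A at Phi0)
#: plus its spread.
POCKET_CUTOFF = 4.0
#: NZ...O=C hydrogen-bond criteria (no hydrogens in 2.1-2.4 A structures).
HBOND_CUTOFF = 3.5
HBOND_MIN_ANGLE = 90.0
#: van der Waals radii (angstrom) and the serious-clash overlap threshold.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
CLASH_OVERLAP = 0.4

POCKET_LABELS = ("P0", "P1", "P2", "P3", "P4")


@dataclass
class PocketFrame:
    """Reference frame: pocket centers, reference anchor CAs, filter lysine.

    Pocket centers are centroids of the reference NES's Phi side-chain
    heavy atoms after superposition; serializable to JSON so tests and
    reruns need no structure download.
    """

    pocket_centers: dict[str, np.ndarray]
    reference_anchor_cas: dict[str, np.ndarray]
    filter_lysine_number: int
    filter_lysine_atoms: dict[str, np.ndarray]
    groove_residues: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pocket_centers = {k: np.asarray(v, float) for k, v in self.pocket_centers.items()}
        self.reference_anchor_cas = {
            k: np.asarray(v, float) for k, v in self.reference_anchor_cas.items()
        }
        self.filter_lysine_atoms = {
            k: np.asarray(v, float) for k, v in self.filter_lysine_atoms.items()
        }
        if "NZ" not in self.filter_lysine_atoms:
            raise StructureError("filter lysine lacks its NZ atom")

    @property
    def nz(self) -> np.ndarray:
        return self.filter_lysine_atoms["NZ"]

    def transformed(self, result: SuperpositionResult) -> "PocketFrame":
        f = lambda v: result.rotation @ v + result.translation
        return PocketFrame(
            {k: f(v) for k, v in self.pocket_centers.items()},
            {k: f(v) for k, v in self.reference_anchor_cas.items()},
            self.filter_lysine_number,
            {k: f(v) for k, v in self.filter_lysine_atoms.items()},
            list(self.groove_residues),
        )

    def to_json(self, path) -> None:
        payload = {
            "pocket_centers": {k: list(v) for k, v in self.pocket_centers.items()},
            "reference_anchor_cas": {
                k: list(v) for k, v in self.reference_anchor_cas.items()
            },
            "filter_lysine_number": self.filter_lysine_number,
            "filter_lysine_atoms": {
                k: list(v) for k, v in self.filter_lysine_atoms.items()
            },
            "groove_residues": self.groove_residues,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "PocketFrame":
        payload = json.loads(Path(path).read_text())
        return cls(
            payload["pocket_centers"],
            payload["reference_anchor_cas"],
            payload["filter_lysine_number"],
            payload["filter_lysine_atoms"],
            payload.get("groove_residues", []),
        )


def _sidechain_centroid(residue) -> np.ndarray | None:
    side = [v for k, v in residue.atoms.items() if k not in BACKBONE_SET and not k.startswith("H")]
    if side:
        return np.mean(side, axis=0)
    if "CB" in residue.atoms:
        return residue.atoms["CB"]
    return None


def build_pocket_frame(
    chains: dict[str, PeptideStructure],
    crm1_chain: str,
    nes_chain: str,
    anchor_numbers: list[int],
    filter_lysine_number: int = 579,
    pocket_labels: tuple[str, ...] | None = None,
) -> PocketFrame:
    """Derive a pocket frame from a reference CRM1-NES complex.

    ``anchor_numbers`` are the author numbers of the reference NES's Phi
    residues, N- to C-terminal; they define P0.. (or P1.. for four-anchor
    references starting at Phi1) via ``pocket_labels``.
    """
    crm1 = chains[crm1_chain]
    nes = chains[nes_chain]
    if pocket_labels is None:
        pocket_labels = POCKET_LABELS[: len(anchor_numbers)]
    if len(pocket_labels) != len(anchor_numbers):
        raise ValueError("one pocket label per anchor number required")

    centers: dict[str, np.ndarray] = {}
    anchor_cas: dict[str, np.ndarray] = {}
    missing = []
    for num, label in zip(anchor_numbers, pocket_labels):
        try:
            res = nes.residue_by_number(num)
        except StructureError:
            missing.append(num)
            continue
        centroid = _sidechain_centroid(res)
        if centroid is None:
            missing.append(num)
            continue
        centers[label] = centroid
        anchor_cas[label] = res.coord("CA")
    if missing:
        raise StructureError(f"reference NES anchors missing: {missing}")

    lys = crm1.residue_by_number(filter_lysine_number)
    if "NZ" not in lys.atoms:
        raise StructureError(
            f"filter lysine {filter_lysine_number} lacks NZ in chain {crm1_chain}"
        )
    from .structure_core import select_groove_residues

    groove = select_groove_residues(crm1, nes)
    return PocketFrame(
        pocket_centers=centers,
        reference_anchor_cas=anchor_cas,
        filter_lysine_number=filter_lysine_number,
        filter_lysine_atoms=dict(lys.atoms),
        groove_residues=groove,
    )


# ---------------------------------------------------------------------------
# Anchor assignment

@dataclass
class AnchorMap:
    """Phi residues mapped to groove pockets with displacement distances."""

    assignments: dict[int, str]          # residue author number -> pocket label
    occupancy: dict[str, bool]           # pocket label -> occupied
    displacement: dict[str, float]       # pocket label -> CA-CA distance (A)
    orientation: str | None              # "plus" | "minus" | None
    insufficient: bool

    @property
    def n_assigned(self) -> int:
        return len(self.assignments)


def assign_anchors(
    peptide: PeptideStructure,
    frame: PocketFrame,
    transform: SuperpositionResult | None = None,
    cutoff: float = POCKET_CUTOFF,
) -> AnchorMap:
    """Greedy one-to-one matching of Phi side chains to pocket centers.

    The peptide must be in the reference frame (pass ``transform`` to move
    it there first).  Candidate pairs beyond ``cutoff`` angstrom are never
    assigned.  Ties break to the lower residue number, then the lower
    pocket index — the result is independent of residue input order.
    Orientation is plus when assigned pocket indices increase with residue
    number, minus when they decrease.
    """
    if transform is not None:
        peptide = peptide.transformed(transform.rotation, transform.translation)

    candidates = []
    for res in peptide.residues:
        if res.name.upper() not in PHI_RESIDUE_NAMES:
            continue
        centroid = _sidechain_centroid(res)
        if centroid is None:
            centroid = res.atoms.get("CA")
        for label, center in frame.pocket_centers.items():
            dist = float(np.linalg.norm(centroid - center))
            if dist <= cutoff:
                candidates.append((dist, res.author_number, label, res))

    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    assignments: dict[int, str] = {}
    displacement: dict[str, float] = {}
    used_pockets: set[str] = set()
    for dist, resnum, label, res in candidates:
        if resnum in assignments or label in used_pockets:
            continue
        assignments[resnum] = label
        used_pockets.add(label)
        ref_ca = frame.reference_anchor_cas.get(label)
        if ref_ca is not None and "CA" in res.atoms:
            displacement[label] = float(np.linalg.norm(res.atoms["CA"] - ref_ca))

    occupancy = {label: label in used_pockets for label in frame.pocket_centers}
    ordered = sorted(assignments.items())
    pocket_idx = [int(lbl[1]) for _, lbl in ordered]
    orientation: str | None = None
    if len(pocket_idx) >= 2:
        if all(b > a for a, b in zip(pocket_idx, pocket_idx[1:])):
            orientation = "plus"
        elif all(b < a for a, b in zip(pocket_idx, pocket_idx[1:])):
            orientation = "minus"
    return AnchorMap(
        assignments=assignments,
        occupancy=occupancy,
        displacement=displacement,
        orientation=orientation,
        insufficient=len(assignments) < 3,
    )


def anchor_displacements(maps: list[AnchorMap]) -> dict:
    """Per-pocket displacement table with cohort mean and sd.

    Returns ``{pocket: {"values": [...], "mean": m, "sd": s}}`` over all
    maps that assigned that pocket (sd is NaN for singletons).
    """
    table: dict[str, dict] = {}
    for label in POCKET_LABELS:
        values = [m.displacement[label] for m in maps if label in m.displacement]
        if not values:
            continue
        arr = np.asarray(values)
        table[label] = {
            "values": [float(v) for v in values],
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(values) > 1 else float("nan"),
        }
    return table


# ---------------------------------------------------------------------------
# Filter-lysine hydrogen bonds / niche motifs

@dataclass
class HBondRecord:
    residue_number: int
    acceptor_atom: str
    distance: float
    angle: float


@dataclass
class NicheMotif:
    residue_pair: tuple[int, int]
    motif_type: str  # "niche3" (i, i+2) | "niche4" (i, i+3)


def detect_filter_hbonds(
    peptide: PeptideStructure,
    frame: PocketFrame,
    cutoff: float = HBOND_CUTOFF,
    min_angle: float = HBOND_MIN_ANGLE,
    expected_direction: str | None = None,
):
    """Hydrogen bonds from the filter-lysine NZ to backbone carbonyls.

    A contact qualifies when NZ...O <= cutoff and the C-O...NZ angle is at
    least ``min_angle`` degrees.  Two qualifying carbonyls spaced 2 or 3
    residues apart coordinate the same ammonium as a niche3/niche4 motif.

    Returns ``(records, motifs, expectation)`` where expectation describes
    which donors the orientation predicts (turn carbonyls for plus,
    N-terminal strand carbonyls for minus) — observation is reported either
    way.
    """
    nz = frame.nz
    records: list[HBondRecord] = []
    for res in peptide.residues:
        o = res.atoms.get("O")
        c = res.atoms.get("C")
        if o is None or c is None:
            continue
        dist = float(np.linalg.norm(nz - o))
        if dist > cutoff:
            continue
        v1 = c - o
        v2 = nz - o
        cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if angle >= min_angle:
            records.append(HBondRecord(res.author_number, "O", dist, angle))

    motifs: list[NicheMotif] = []
    numbers = sorted(r.residue_number for r in records)
    for i, a in enumerate(numbers):
        for b in numbers[i + 1 :]:
            if b - a == 2:
                motifs.append(NicheMotif((a, b), "niche3"))
            elif b - a == 3:
                motifs.append(NicheMotif((a, b), "niche4"))

    expectation = None
    if expected_direction == "plus":
        expectation = "carbonyls of Phi2+1 and Phi3 in the conserved turn"
    elif expected_direction == "minus":
        expectation = "carbonyls of the N-terminal strand"
    return records, motifs, expectation


# ---------------------------------------------------------------------------
# Steric clash filter

@dataclass
class ClashReport:
    contacts: list[tuple[str, str, float, float]]  # (peptide atom, lys atom, dist, overlap)
    worst_overlap: float
    clashing: bool


def clash_filter(
    peptide: PeptideStructure,
    frame: PocketFrame,
    overlap_threshold: float = CLASH_OVERLAP,
) -> ClashReport:
    """Van der Waals overlap of the peptide with the filter-lysine side chain.

    Lysine side-chain atoms (CB..NZ) are screened against every peptide
    heavy atom; a pair with overlap (sum of vdW radii minus distance)
    above ``overlap_threshold`` angstrom is a serious clash.  Hydrogen-bond
    distances (~2.9 A for N...O) stay below the threshold by design.
    """
    lys_atoms = {
        k: v
        for k, v in frame.filter_lysine_atoms.items()
        if k not in BACKBONE_SET and not k.startswith("H")
    }
    contacts = []
    worst = 0.0
    for res in peptide.residues:
        for aname, apos in res.atoms.items():
            if aname.startswith("H"):
                continue
            r1 = VDW_RADII.get(aname[0])
            if r1 is None:
                continue
            for lname, lpos in lys_atoms.items():
                r2 = VDW_RADII.get(lname[0])
                if r2 is None:
                    continue
                dist = float(np.linalg.norm(apos - lpos))
                overlap = r1 + r2 - dist
                if overlap > overlap_threshold:
                    contacts.append(
                        (f"{res.label}/{aname}", lname, round(dist, 3), round(overlap, 3))
                    )
                    worst = max(worst, overlap)
    return ClashReport(contacts=contacts, worst_overlap=round(worst, 3), clashing=bool(contacts))


# ---------------------------------------------------------------------------
# Three-criterion verdict

def nes_criteria_report(
    anchor_map: AnchorMap,
    turn,
    hbonds: list[HBondRecord],
    clash: ClashReport,
) -> dict:
    """Active-NES verdict: anchors in pockets, conserved turn, lysine H-bonding.

    Criterion 3 requires at least one backbone-to-lysine hydrogen bond and
    no steric clash with the lysine side chain (the selectivity-filter
    reading: a clashing chain cannot realize the bonding geometry against
    the wild-type groove).
    """
    c1 = not anchor_map.insufficient
    c2 = turn is not None
    c3 = bool(hbonds) and not clash.clashing
    failed = [
        name
        for ok, name in (
            (c1, "anchors-in-pockets"),
            (c2, "conserved-one-turn-helix"),
            (c3, "filter-lysine-hydrogen-bonding"),
        )
        if not ok
    ]
    return {
        "criterion_1_anchors": {
            "passed": c1,
            "n_assigned": anchor_map.n_assigned,
            "occupancy": dict(anchor_map.occupancy),
            "orientation": anchor_map.orientation,
        },
        "criterion_2_turn": {
            "passed": c2,
            "span": list(turn.span) if turn is not None else None,
            "psi_series": list(turn.psi_series) if turn is not None else None,
        },
        "criterion_3_lysine": {
            "passed": c3,
            "n_hbonds": len(hbonds),
            "hbond_residues": [h.residue_number for h in hbonds],
            "clashing": clash.clashing,
            "worst_overlap": clash.worst_overlap,
        },
        "active_nes": c1 and c2 and c3,
        "failed_criteria": failed,
    }
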