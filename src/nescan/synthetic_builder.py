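"""Synthetic test-input generation.

Two generators live here:

* a peptide-backbone builder that turns per-residue (phi, psi, omega)
  specifications into 3D coordinates with ideal bond geometry (NeRF-style
  internal-coordinate chain extension), used to emulate the backbone shapes
  NESs adopt in the CRM1 groove (alpha-helix, 3-10 helix, beta-strand,
  type I beta-turn, loop), optionally with a mock groove (pocket markers
  plus a pseudo filter-lysine ammonium nitrogen) so the full
  anchor/H-bond/clash analysis can run without crystallographic input;

* a random-sequence generator that embeds NES consensus motifs at known
  positions into background sequence of controlled hydrophobic content,
  with a truth table for matcher precision/recall evaluation.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .sequence_patterns import (
    CLASS_ORDER,
    PATTERN_LIBRARY,
    PHI_RESIDUES,
    PatternMatch,
)
from .structure_core import PeptideStructure, Residue, one_to_three

__all__ = [
    "BackboneSpec",
    "build_backbone",
    "build_class_template",
    "MockComplexSpec",
    "build_mock_complex",
    "generate_sequences",
    "evaluate_matcher",
    "ALPHA", "THREE10", "STRAND", "LOOP_A", "LOOP_B", "TURN_I_2", "TURN_I_3",
]

# Canonical (phi, psi) pairs used by the class templates (degrees).
ALPHA = (-57.0, -47.0)
THREE10 = (-49.0, -26.0)
STRAND = (-120.0, 135.0)
LOOP_A = (-80.0, 55.0)
LOOP_B = (-100.0, 45.0)
#: Type I beta-turn central residues i+1 and i+2.
TURN_I_2 = (-60.0, -30.0)
TURN_I_3 = (-90.0, 0.0)

# Ideal peptide geometry (lengths in angstrom, angles in degrees).
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
B_CA_CB = 1.521
A_N_CA_C = 111.0
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.8
A_N_CA_CB = 110.4
#: Improper torsion C-N-CA-CB fixing L-chirality (about -124 deg in
#: deposited structures).
T_C_N_CA_CB = -122.6


@dataclass
class BackboneSpec:
    """Sequence plus per-residue torsions for the backbone builder."""

    sequence: str
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    class_label: str | None = None
    anchor_positions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        n = len(self.sequence)
        if len(self.phi) != n or len(self.psi) != n:
            raise ValueError("phi/psi length must equal sequence length")
        if self.omega is None:
            self.omega = np.full(n, 180.0)
        else:
            self.omega = np.asarray(self.omega, dtype=float)
            if len(self.omega) != n:
                raise ValueError("omega length must equal sequence length")


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d given atoms a-b-c, |c-d|, angle(b,c,d) and torsion(a,b,c,d)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(spec: BackboneSpec, chain_id: str = "A", first_number: int = 1) -> PeptideStructure:
    """Build backbone coordinates (N, CA, C, O, CB except Gly) from a spec.

    Recomputing dihedrals on the result reproduces the spec torsions to
    better than 1e-3 degrees (before noise).  Gaussian noise of
    ``spec.noise_sigma`` degrees is applied independently to each phi/psi
    when the sigma is positive, reproducibly under ``spec.seed``.
    """
    n = len(spec.sequence)
    if n < 4:
        raise ValueError("need at least 4 residues to define any dihedral")
    phi = spec.phi.copy()
    psi = spec.psi.copy()
    omega = spec.omega.copy()
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        phi = phi + rng.normal(0.0, spec.noise_sigma, n)
        psi = psi + rng.normal(0.0, spec.noise_sigma, n)

    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    # First residue in a canonical pose.
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (B_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - A_N_CA_C)
    C[0] = CA[0] + B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(n - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], B_C_N, A_CA_C_N, psi[i])
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], B_N_CA, A_C_N_CA, omega[i + 1])
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], B_CA_C, A_N_CA_C, phi[i + 1])

    residues = []
    for i, letter in enumerate(spec.sequence.upper()):
        atoms = {"N": N[i], "CA": CA[i], "C": C[i]}
        # Carbonyl O is anti to the next N across the CA-C bond; the last
        # residue uses its spec psi the same way.
        atoms["O"] = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi[i] + 180.0)
        if letter != "G":
            atoms["CB"] = place_atom(C[i], N[i], CA[i], B_CA_CB, A_N_CA_CB, T_C_N_CA_CB)
        residues.append(Residue(first_number + i, "", one_to_three(letter), atoms))
    return PeptideStructure(chain_id, residues)


# ---------------------------------------------------------------------------
# Class templates

#: The six backbone shape descriptors and a representative class for each.
SHAPE_OF_CLASS = {
    "1a": "helix-strand",
    "1c": "helix-strand",
    "1d": "helix-strand",
    "1b": "310-strand",
    "2": "loop",
    "3": "all-helix",
    "4": "helix-beta-turn",
    "1a-R": "strand-helix",
    "1b-R": "strand-helix",
    "1c-R": "strand-helix",
    "1d-R": "strand-helix",
}


def _default_anchor_letters(n: int) -> str:
    return ("LLFLL" if n == 5 else "LLFL")[:n]


def build_class_template(
    class_label: str,
    anchor_letters: str | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> BackboneSpec:
    """Backbone spec whose built structure exhibits the class's shape.

    Anchor letters (hydrophobic Phi residues) are placed at the class's
    consensus spacing inside an otherwise Phi-free background, so sequence
    scanning of the template recovers exactly the generating class family.
    """
    if class_label not in PATTERN_LIBRARY:
        raise ValueError(f"unknown class label: {class_label}")
    pat = PATTERN_LIBRARY[class_label]
    anchor_letters = anchor_letters or _default_anchor_letters(pat.n_anchors)
    if len(anchor_letters) != pat.n_anchors:
        raise ValueError(f"class {class_label} needs {pat.n_anchors} anchor letters")
    if any(ch not in PHI_RESIDUES for ch in anchor_letters.upper()):
        raise ValueError("anchor letters must be hydrophobic (L/V/I/F/M)")

    flank = 2
    offsets = pat.offsets
    length = offsets[-1] + 1 + 2 * flank
    anchors = tuple(flank + o for o in offsets)
    # Phi-free background so sequence scanning recovers exactly this class.
    seq = list(("ASEQG" * 8)[:length])
    for pos, letter in zip(anchors, anchor_letters.upper()):
        seq[pos] = letter
    sequence = "".join(seq)

    phi = np.empty(length)
    psi = np.empty(length)
    shape = SHAPE_OF_CLASS[class_label]
    a = anchors  # chain-order anchor positions

    def fill(lo, hi, pair):  # inclusive range
        phi[lo : hi + 1] = pair[0]
        psi[lo : hi + 1] = pair[1]

    if shape == "all-helix":
        # 3-turn alpha-helix spanning all anchors; the chain exits the
        # groove after the last anchor (P4 left empty).
        fill(0, a[0] - 1, LOOP_A)
        fill(a[0], length - 1, ALPHA)
    elif shape == "helix-strand":
        # alpha-helix through Phi2+2, then beta-strand to the C terminus.
        split = a[2]  # Phi3 onward is strand
        fill(0, split - 1, ALPHA)
        fill(split, length - 1, STRAND)
    elif shape == "310-strand":
        # 1.5-turn 3-10 helix presenting Phi1/Phi2, then a 3-residue strand.
        split = a[2]
        fill(0, split - 1, THREE10)
        fill(split, length - 1, STRAND)
    elif shape == "loop":
        # mostly loop with one turn of helix at Phi2..Phi3.
        for i in range(length):
            fill(i, i, LOOP_A if i % 2 == 0 else LOOP_B)
        fill(a[1], a[2] - 1, ALPHA)
        fill(a[2], a[2], STRAND)
    elif shape == "helix-beta-turn":
        # 3-turn helix through Phi3, then a type I beta-turn placing Phi4.
        fill(0, a[0] - 1, LOOP_A)
        fill(a[0], a[3], ALPHA)
        t = a[3] + 1  # turn position i; i+3 == Phi4
        fill(t, t, STRAND)
        fill(t + 1, t + 1, TURN_I_2)
        fill(t + 2, t + 2, TURN_I_3)
        fill(t + 3, length - 1, STRAND)
    elif shape == "strand-helix":
        # beta-strand at the N terminus, then alpha-helix (minus direction).
        split = a[1]
        fill(0, split - 1, STRAND)
        fill(split, length - 1, ALPHA)
    else:  # pragma: no cover
        raise AssertionError(shape)

    return BackboneSpec(
        sequence=sequence,
        phi=phi,
        psi=psi,
        noise_sigma=noise_sigma,
        seed=seed,
        class_label=class_label,
        anchor_positions=anchors,
    )


# ---------------------------------------------------------------------------
# Mock complexes

@dataclass
class MockComplexSpec:
    """Parameters for a mock groove around a built peptide."""

    backbone: BackboneSpec
    hbond_distance: float = 2.9
    pocket_jitter: float = 0.0
    displace_anchors: float = 0.0
    seed: int = 0


def _sidechain_point(res: Residue) -> np.ndarray:
    return res.atoms.get("CB", res.atoms["CA"])


_VDW_N = 1.55
_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}


def _vdw_clearance(point: np.ndarray, peptide: PeptideStructure, skip) -> float:
    """Smallest (distance - vdW sum) between point (an N atom) and peptide atoms."""
    worst = np.inf
    for ridx, res in enumerate(peptide.residues):
        for name, pos in res.atoms.items():
            if (ridx, name) in skip:
                continue
            r = _VDW.get(name[0])
            if r is None:
                continue
            worst = min(worst, float(np.linalg.norm(point - pos)) - (r + _VDW_N))
    return worst


def _hbond_angle_ok(nz, o, c, min_angle: float = 90.0) -> bool:
    v1, v2 = c - o, nz - o
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0))) >= min_angle


def _place_pseudo_nz(peptide: PeptideStructure, i: int, j: int, d: float) -> np.ndarray:
    """Pseudo filter-lysine NZ near the carbonyls of residues i and j.

    First tries the niche geometry (equidistant from both O atoms, both
    C-O..NZ angles >= 90 deg, no vdW overlap with the rest of the chain);
    when the local geometry cannot host it, falls back to a single H-bond
    to residue j's carbonyl.  Deterministic grid searches throughout.
    """
    o1, c1 = peptide.residues[i].atoms["O"], peptide.residues[i].atoms["C"]
    o2, c2 = peptide.residues[j].atoms["O"], peptide.residues[j].atoms["C"]
    skip_both = {(i, "O"), (j, "O")}

    best, best_score = None, -np.inf
    sep = float(np.linalg.norm(o2 - o1))
    for dist in (d, d + 0.2, d + 0.4):
        if sep / 2.0 >= dist:
            continue
        axis12 = (o2 - o1) / sep
        u = (o1 - c1) + (o2 - c2)
        u = u - np.dot(u, axis12) * axis12
        nu = np.linalg.norm(u)
        if nu < 1e-8:
            continue
        u /= nu
        w = np.cross(axis12, u)
        h = math.sqrt(dist * dist - (sep / 2.0) ** 2)
        mid = 0.5 * (o1 + o2)
        for theta in np.linspace(0.0, 2.0 * math.pi, 73):
            nz = mid + h * (math.cos(theta) * u + math.sin(theta) * w)
            if not (_hbond_angle_ok(nz, o1, c1) and _hbond_angle_ok(nz, o2, c2)):
                continue
            score = _vdw_clearance(nz, peptide, skip_both)
            if score > best_score:
                best, best_score = nz, score
    if best is not None and best_score > -0.3:
        return best

    # Fallback: one hydrogen bond to residue j's carbonyl.
    skip_one = {(j, "O")}
    rng_dirs = _fibonacci_sphere(200)
    oc = (c2 - o2) / np.linalg.norm(c2 - o2)
    best, best_score = None, -np.inf
    for direction in rng_dirs:
        if np.dot(direction, oc) > -0.1:  # keep C-O..NZ angle > ~95 deg
            continue
        nz = o2 + d * direction
        score = _vdw_clearance(nz, peptide, skip_one)
        if score > best_score:
            best, best_score = nz, score
    if best is None or best_score <= -0.3:
        raise ValueError("cannot place a clash-free pseudo-lysine NZ")
    return best


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    phi_ang = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi_ang), r * np.sin(phi_ang), z])


def build_mock_complex(spec: MockComplexSpec):
    """Build a peptide plus a mock pocket frame around it.

    Pocket markers P0..P4 sit on the peptide's own anchor side-chain points
    (optionally displaced by ``displace_anchors`` angstroms along a fixed
    axis, for planted-displacement tests) and a pseudo filter-lysine NZ is
    placed ``hbond_distance`` angstroms from the carbonyl O atoms of the
    Phi2+1 and Phi3 residues of the conserved turn (plus NESs), realizing a
    niche-type coordination.

    Returns ``(peptide, frame)`` where frame is a
    :class:`~nescan.groove_interactions.PocketFrame`.
    """
    from .groove_interactions import PocketFrame

    bspec = spec.backbone
    if bspec.anchor_positions is None or bspec.class_label is None:
        raise ValueError("backbone spec must come from build_class_template")
    peptide = build_backbone(bspec)
    rng = np.random.default_rng(spec.seed)
    anchors = list(bspec.anchor_positions)
    pat = PATTERN_LIBRARY[bspec.class_label]
    # Chain-order anchors occupy pockets in increasing order for (+) shapes
    # and decreasing order for (-) shapes.
    minus = pat.reversed_
    n_anchor = len(anchors)
    # Five-anchor class 4 and the P4-skipping class 3 start at P0; the
    # four-anchor class-1/2 families occupy P1..P4.
    base = 0 if (n_anchor == 5 or bspec.class_label == "3") else 1
    pocket_order = [base + k for k in range(n_anchor)]
    if minus:
        pocket_order = pocket_order[::-1]
    centers = {}
    anchor_cas = {}
    axis = np.array([0.0, 0.0, 1.0])
    for chain_idx, pocket_idx in enumerate(pocket_order):
        res = peptide.residues[anchors[chain_idx]]
        point = _sidechain_point(res).copy()
        if spec.pocket_jitter > 0:
            point = point + rng.normal(0.0, spec.pocket_jitter, 3)
        label = f"P{pocket_idx}"
        centers[label] = point
        anchor_cas[label] = res.atoms["CA"] + spec.displace_anchors * axis
    # Pseudo filter lysine: NZ equidistant from the two turn carbonyls.
    if minus:
        # For (-) NESs the N-terminal strand carbonyls coordinate the
        # lysine; adjacent strand carbonyls are close enough to share it
        # (no niche motif, matching the minus-NES observation).
        i, j = 0, 1
    else:
        # Phi2+1 and Phi3 of the conserved turn (niche-type coordination).
        # Classes with a Phi0 register (3, 4) carry the turn one anchor later.
        if n_anchor == 5 or bspec.class_label == "3":
            phi2, phi3 = anchors[2], anchors[3]
        else:
            phi2, phi3 = anchors[1], anchors[2]
        i, j = phi2 + 1, phi3
    nz = _place_pseudo_nz(peptide, i, j, spec.hbond_distance)
    lysine_atoms = {"NZ": nz}
    frame = PocketFrame(
        pocket_centers=centers,
        reference_anchor_cas=anchor_cas,
        filter_lysine_number=568,
        filter_lysine_atoms=lysine_atoms,
        groove_residues=[],
    )
    return peptide, frame


def build_clash_pair(n_extra: int = 4):
    """A true all-helix NES, a too-long helix, and a frame that blocks it.

    Models the selectivity-filter scenario: the groove constriction (here a
    pseudo filter-lysine NZ) sits where the chain would continue past the
    last anchor pocket.  The true class-3 peptide ends before it; the false
    positive extends its helix by ``n_extra`` residues straight through it.

    Returns ``(true_peptide, false_peptide, frame)``; both peptides share
    coordinates over the common leading residues (deterministic builder),
    so no superposition is needed.
    """
    true_spec = build_class_template("3")
    n = len(true_spec.sequence)
    ext_spec = BackboneSpec(
        sequence=true_spec.sequence + "A" * n_extra,
        phi=np.concatenate([true_spec.phi, np.full(n_extra, ALPHA[0])]),
        psi=np.concatenate([true_spec.psi, np.full(n_extra, ALPHA[1])]),
        class_label=true_spec.class_label,
        anchor_positions=true_spec.anchor_positions,
    )
    true_pep, frame = build_mock_complex(MockComplexSpec(backbone=true_spec))
    false_pep = build_backbone(ext_spec)
    # The constriction: put the NZ where the extended chain's backbone goes.
    nz = false_pep.residues[n + 1].atoms["CA"]
    from .groove_interactions import PocketFrame

    blocked = PocketFrame(
        pocket_centers=frame.pocket_centers,
        reference_anchor_cas=frame.reference_anchor_cas,
        filter_lysine_number=frame.filter_lysine_number,
        filter_lysine_atoms={"NZ": nz},
        groove_residues=frame.groove_residues,
    )
    return true_pep, false_pep, blocked


# ---------------------------------------------------------------------------
# Sequence fixtures

_BACKGROUND_NON_PHI = "ADEGHKNPQRSTWYC"
_PHI = "LVIFM"


def generate_sequences(
    n: int,
    length: int,
    nes_classes: list[str] | tuple[str, ...] = ("1a",),
    phi_frequency: float = 0.05,
    seed: int = 0,
):
    """Random sequences with one embedded NES motif each, plus a truth table.

    Background residues are hydrophobic (Phi) with probability
    ``phi_frequency``; the embedded motif's X positions are drawn from the
    non-Phi alphabet so the planted anchors are exactly the motif anchors.

    Returns ``(records, truth)`` where records is a list of (id, sequence)
    and truth a list of dicts with keys sequence_id, class, start,
    anchor_positions.
    """
    if n <= 0 or length <= 0:
        raise ValueError("n and length must be positive")
    if not 0.0 <= phi_frequency <= 1.0:
        raise ValueError("phi_frequency must be in [0, 1]")
    for c in nes_classes:
        if c not in PATTERN_LIBRARY:
            raise ValueError(f"unknown class label: {c}")
    rng = np.random.default_rng(seed)
    records = []
    truth = []
    for k in range(n):
        label = nes_classes[k % len(nes_classes)]
        pat = PATTERN_LIBRARY[label]
        span = pat.span
        if span > length:
            raise ValueError(f"length {length} shorter than class {label} span {span}")
        bg = rng.random(length)
        seq = [
            (_PHI[rng.integers(len(_PHI))] if bg[i] < phi_frequency
             else _BACKGROUND_NON_PHI[rng.integers(len(_BACKGROUND_NON_PHI))])
            for i in range(length)
        ]
        start = int(rng.integers(0, length - span + 1))
        offsets = pat.offsets
        offset_set = set(offsets)
        for o in range(span):
            if o in offset_set:
                seq[start + o] = _PHI[rng.integers(len(_PHI))]
            else:
                seq[start + o] = _BACKGROUND_NON_PHI[rng.integers(len(_BACKGROUND_NON_PHI))]
        seq_id = f"synth_{k:04d}"
        records.append((seq_id, "".join(seq)))
        truth.append(
            {
                "sequence_id": seq_id,
                "class": label,
                "start": start,
                "anchor_positions": tuple(start + o for o in offsets),
            }
        )
    return records, truth


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n{seq}\n")


def write_truth_tsv(truth, path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tclass\tstart\tanchor_positions\n")
        for row in truth:
            anchors = ",".join(str(p) for p in row["anchor_positions"])
            fh.write(f"{row['sequence_id']}\t{row['class']}\t{row['start']}\t{anchors}\n")


def evaluate_matcher(matches: list[PatternMatch], truth: list[dict]):
    """Per-class and overall precision/recall of matches against truth.

    A match is a true positive when its (sequence id, class, anchor
    positions) triple coincides with an embedded motif.
    """
    truth_keys = {
        (row["sequence_id"], row["class"], tuple(row["anchor_positions"]))
        for row in truth
    }
    classes = sorted({row["class"] for row in truth}, key=CLASS_ORDER.index)
    per_class = {}
    tp_all = fp_all = 0
    found: set = set()
    for m in matches:
        key = (m.sequence_id, m.class_label, m.anchor_positions)
        if key in truth_keys:
            found.add(key)
        elif m.class_label in classes:
            fp_all += 1
    tp_all = len(found)
    for c in classes:
        truth_c = {k for k in truth_keys if k[1] == c}
        found_c = {k for k in found if k[1] == c}
        fp_c = sum(
            1
            for m in matches
            if m.class_label == c
            and (m.sequence_id, m.class_label, m.anchor_positions) not in truth_keys
        )
        tp_c = len(found_c)
        per_class[c] = {
            "tp": tp_c,
            "fp": fp_c,
            "fn": len(truth_c) - tp_c,
            "precision": tp_c / (tp_c + fp_c) if tp_c + fp_c else float("nan"),
            "recall": tp_c / len(truth_c) if truth_c else float("nan"),
        }
    overall = {
        "tp": tp_all,
        "fp": fp_all,
        "fn": len(truth_keys) - tp_all,
        "precision": tp_all / (tp_all + fp_all) if tp_all + fp_all else float("nan"),
        "recall": tp_all / len(truth_keys) if truth_keys else float("nan"),
    }
    return {"per_class": per_class, "overall": overall}
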