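"""Structure I/O and geometric primitives.

Reads CRM1-NES complex structures (PDB or mmCIF, via gemmi), exposes an
ordered per-chain residue/atom container, and provides the geometry used by
the downstream classifiers: backbone torsions (phi/psi/omega), least-squares
rigid superposition, and the Sc<->Hs/Mm CRM1 residue-numbering map for the
groove helices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Residue",
    "PeptideStructure",
    "DihedralSeries",
    "SuperpositionResult",
    "StructureError",
    "load_complex",
    "write_pdb",
    "dihedral_angle",
    "compute_dihedrals",
    "superpose",
    "apply_transform",
    "map_crm1_numbering",
    "CHAIN_BREAK_CN",
]

#: C(i)-N(i+1) distance above which two consecutive residues are treated as
#: a chain break (no peptide bond; torsions across it are undefined).
CHAIN_BREAK_CN = 2.0

BACKBONE_ATOMS = ("N", "CA", "C")


class StructureError(ValueError):
    """Structured parsing/validation failure, naming chain and residue."""


@dataclass
class Residue:
    author_number: int
    icode: str
    name: str
    atoms: dict[str, np.ndarray]

    @property
    def label(self) -> str:
        return f"{self.name}{self.author_number}{self.icode.strip()}"

    def coord(self, atom: str) -> np.ndarray:
        try:
            return self.atoms[atom]
        except KeyError:
            raise StructureError(f"residue {self.label} lacks atom {atom}") from None


@dataclass
class PeptideStructure:
    """One polymer chain: ordered residues with backbone (+CB) coordinates."""

    chain_id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(_three_to_one(r.name) for r in self.residues)

    @property
    def author_numbers(self) -> list[int]:
        return [r.author_number for r in self.residues]

    def coords(self, atom: str = "CA") -> np.ndarray:
        """(n, 3) array of one named atom per residue."""
        return np.array([r.coord(atom) for r in self.residues])

    def residue_by_number(self, author_number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.author_number == author_number and r.icode.strip() == icode.strip():
                return r
        raise StructureError(
            f"chain {self.chain_id}: no residue numbered {author_number}{icode}"
        )

    def chain_breaks(self) -> list[int]:
        """Indices i where the C(i)-N(i+1) bond is broken or unmeasurable."""
        breaks = []
        for i in range(len(self.residues) - 1):
            a, b = self.residues[i], self.residues[i + 1]
            if "C" not in a.atoms or "N" not in b.atoms:
                breaks.append(i)
                continue
            if np.linalg.norm(a.atoms["C"] - b.atoms["N"]) >= CHAIN_BREAK_CN:
                breaks.append(i)
        return breaks

    def validate_backbone(self, require_o: bool = False) -> None:
        missing = []
        want = BACKBONE_ATOMS + (("O",) if require_o else ())
        for r in self.residues:
            for atom in want:
                if atom not in r.atoms:
                    missing.append(f"{self.chain_id}/{r.label}/{atom}")
        if missing:
            raise StructureError("missing backbone atoms: " + ", ".join(missing))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PeptideStructure":
        out = []
        for r in self.residues:
            out.append(
                Residue(
                    r.author_number,
                    r.icode,
                    r.name,
                    {k: rotation @ v + translation for k, v in r.atoms.items()},
                )
            )
        return PeptideStructure(self.chain_id, out)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def _three_to_one(name: str) -> str:
    return _THREE_TO_ONE.get(name.upper(), "X")


def one_to_three(letter: str) -> str:
    return _ONE_TO_THREE[letter.upper()]


# ---------------------------------------------------------------------------
# Loading / writing

def load_complex(path, fmt: str | None = None) -> dict[str, PeptideStructure]:
    """Load every polymer chain of a PDB/mmCIF file.

    Waters and non-polymer heteroatoms are dropped; alternate locations are
    resolved to the highest-occupancy conformer (ties to altloc 'A').
    Returns a mapping chain id -> :class:`PeptideStructure`.
    """
    import gemmi

    path = Path(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    st.remove_waters()
    chains: dict[str, PeptideStructure] = {}
    model = st[0]
    for chain in model:
        residues = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            atoms: dict[str, np.ndarray] = {}
            best_occ: dict[str, float] = {}
            for atom in res:
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                name = atom.name
                occ = atom.occ
                # altloc policy: highest occupancy wins, ties to 'A' (the
                # first conformer encountered keeps priority on equal occ).
                if name in atoms and occ <= best_occ[name]:
                    continue
                atoms[name] = pos
                best_occ[name] = occ
            if atoms:
                icode = res.seqid.icode if res.seqid.icode.strip() else ""
                residues.append(Residue(res.seqid.num, icode, res.name, atoms))
        if residues:
            residues.sort(key=lambda r: (r.author_number, r.icode))
            chains[chain.name] = PeptideStructure(chain.name, residues)
    if not chains:
        raise StructureError(f"{path}: no polymer chains found")
    return chains


def write_pdb(chains: dict[str, PeptideStructure] | PeptideStructure, path) -> None:
    """Write chains as fixed-column PDB (coordinates at 3-decimal precision)."""
    if isinstance(chains, PeptideStructure):
        chains = {chains.chain_id: chains}
    serial = 0
    lines = []
    for chain in chains.values():
        for res in chain.residues:
            for name in ("N", "CA", "C", "O", "CB"):
                if name not in res.atoms:
                    continue
                serial += 1
                x, y, z = res.atoms[name]
                element = name[0]
                lines.append(
                    f"ATOM  {serial:>5} {name:^4} {res.name:>3} "
                    f"{chain.chain_id[:1]}{res.author_number:>4}{res.icode[:1] or ' '}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element:>2}"
                )
            # any remaining atoms (e.g. NZ on a mock lysine)
            for name, pos in res.atoms.items():
                if name in ("N", "CA", "C", "O", "CB"):
                    continue
                serial += 1
                x, y, z = pos
                lines.append(
                    f"ATOM  {serial:>5} {name:^4} {res.name:>3} "
                    f"{chain.chain_id[:1]}{res.author_number:>4}{res.icode[:1] or ' '}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {name[0]:>2}"
                )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Torsions

def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


@dataclass
class DihedralSeries:
    """Per-residue backbone torsions in degrees; NaN where undefined.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1);
    omega(i) = CA(i-1)-C(i-1)-N(i)-CA(i).  phi/omega are undefined for the
    first residue, psi for the last, and all torsions spanning a chain break.
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray

    def __len__(self) -> int:
        return len(self.phi)


def compute_dihedrals(p: PeptideStructure) -> DihedralSeries:
    """Backbone phi/psi/omega series for a chain, honouring chain breaks."""
    p.validate_backbone()
    n = len(p)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    omega = np.full(n, np.nan)
    breaks = set(p.chain_breaks())
    res = p.residues
    for i in range(n):
        if i > 0 and (i - 1) not in breaks:
            prev = res[i - 1]
            phi[i] = dihedral_angle(
                prev.atoms["C"], res[i].atoms["N"], res[i].atoms["CA"], res[i].atoms["C"]
            )
            omega[i] = dihedral_angle(
                prev.atoms["CA"], prev.atoms["C"], res[i].atoms["N"], res[i].atoms["CA"]
            )
        if i < n - 1 and i not in breaks:
            nxt = res[i + 1]
            psi[i] = dihedral_angle(
                res[i].atoms["N"], res[i].atoms["CA"], res[i].atoms["C"], nxt.atoms["N"]
            )
    return DihedralSeries(phi=phi, psi=psi, omega=omega)


# ---------------------------------------------------------------------------
# Superposition

@dataclass
class SuperpositionResult:
    """Least-squares rigid-body fit of mobile onto reference coordinates."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Kabsch superposition of paired coordinate sets (proper rotation only).

    ``mobile`` and ``reference`` are (n, 3) arrays with n >= 3 paired atoms.
    The returned transform maps mobile coordinates into the reference frame.
    """
    from scipy.spatial.transform import Rotation

    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = len(mobile)
    if n < 3:
        raise ValueError("superposition needs at least 3 paired atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    mob0 = mobile - mc
    ref0 = reference - rc
    if np.linalg.matrix_rank(ref0, tol=1e-8) < 2:
        raise ValueError("reference atoms are collinear or degenerate")
    rot, _ = Rotation.align_vectors(ref0, mob0)
    R = rot.as_matrix()
    translation = rc - R @ mc
    fitted = mob0 @ R.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=translation, rmsd=rmsd, n_atoms=n)


def apply_transform(p: PeptideStructure, result: SuperpositionResult) -> PeptideStructure:
    return p.transformed(result.rotation, result.translation)


# ---------------------------------------------------------------------------
# CRM1 residue-numbering map

#: Groove-helix region (HEAT repeats 11-12) over which the two-point
#: anchored Sc<->Hs offset is trusted.
_SC_GROOVE_RANGE = (500, 650)
#: ScCRM1 Lys579 corresponds to Hs/MmCRM1 Lys568.
_SC_TO_HS_OFFSET = -11

FILTER_LYSINE = {"Sc": 579, "Hs": 568, "Mm": 568}


def map_crm1_numbering(residue: int, source: str) -> int:
    """Map a CRM1 groove residue number between yeast and human/mouse.

    Anchored at Sc Lys579 <-> Hs/Mm Lys568 (offset -11), applied only within
    the HEAT 11-12 groove helices; outside that range the number is returned
    unchanged with a warning.
    """
    source = source.strip()
    if source in ("Sc",):
        lo, hi = _SC_GROOVE_RANGE
        if lo <= residue <= hi:
            return residue + _SC_TO_HS_OFFSET
    elif source in ("Hs", "Mm", "Hs/Mm"):
        lo, hi = (_SC_GROOVE_RANGE[0] + _SC_TO_HS_OFFSET,
                  _SC_GROOVE_RANGE[1] + _SC_TO_HS_OFFSET)
        if lo <= residue <= hi:
            return residue - _SC_TO_HS_OFFSET
    else:
        raise ValueError(f"unknown organism tag: {source!r}")
    warnings.warn(
        f"residue {residue} outside mapped groove region; returned unchanged",
        stacklevel=2,
    )
    return residue


def select_groove_residues(
    crm1: PeptideStructure, nes: PeptideStructure, cutoff: float = 8.0
) -> list[int]:
    """Reconstruct the groove residue selection around a bound NES.

    Returns author numbers of CRM1 residues having any atom within
    ``cutoff`` angstroms of any NES atom.
    """
    nes_coords = np.concatenate(
        [np.array(list(r.atoms.values())) for r in nes.residues]
    )
    selected = []
    for r in crm1.residues:
        coords = np.array(list(r.atoms.values()))
        d = np.linalg.norm(coords[:, None, :] - nes_coords[None, :, :], axis=-1)
        if d.min() < cutoff:
            selected.append(r.author_number)
    return selected
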