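"""Consensus-pattern scanning for CRM1 nuclear export signals (NESs).

An NES presents 3-5 hydrophobic anchor residues (Leu/Val/Ile/Phe/Met, the
"Phi" residues) to the hydrophobic pockets P0-P4 of the CRM1 groove.  The
anchors are spaced according to a small library of consensus classes: the
forward classes 1a-1d (helix-strand binders), 2 (loop-like), 3 (all-helix)
and 4 (helix/beta-turn, five anchors), plus reversed (-R) variants of the
class-1 family for NESs that thread the groove in the minus polypeptide
direction.  Classes 2 and 3 read identically in both directions and
therefore carry no -R variant; class 4 likewise has no reversed variant in
the library, giving eleven patterns in total.

This module defines the pattern library, scans amino-acid sequences for
matches, and annotates matches with the classic amphipathic-helix heuristic
(hydrophobics at i, i+4, i+7 / i, i+3, i+7 / i, i+3, i+7, i+10).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "PHI_RESIDUES",
    "NesPattern",
    "PatternMatch",
    "PATTERN_LIBRARY",
    "pattern_library",
    "scan_sequence",
    "scan_reverse_classes",
    "annotate_amphipathic",
    "best_per_locus",
    "read_fasta",
    "matches_to_rows",
    "write_matches_tsv",
    "write_matches_json",
]

#: Hydrophobic anchor alphabet.  Fixed; no extended hydrophobics.
PHI_RESIDUES = frozenset("LVIFM")

_STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: The three hydrophobic offset templates used to flag a potential
#: amphipathic helix.
AMPHIPATHIC_TEMPLATES: tuple[tuple[int, ...], ...] = (
    (0, 4, 7),
    (0, 3, 7),
    (0, 3, 7, 10),
)


@dataclass(frozen=True)
class NesPattern:
    """One NES consensus class.

    ``gaps`` holds the number of X (any-residue) spacers between consecutive
    anchors, read N- to C-terminal; e.g. class 2 (Phi1-X-Phi2-XX-Phi3-X-Phi4)
    has gaps ``(1, 2, 1)``.
    """

    class_label: str
    gaps: tuple[int, ...]
    reversed_: bool = False

    def __post_init__(self) -> None:
        if not 3 <= len(self.gaps) <= 4:
            raise ValueError(
                f"{self.class_label}: {len(self.gaps) + 1} anchors outside [4, 5]"
            )

    @property
    def n_anchors(self) -> int:
        return len(self.gaps) + 1

    @property
    def symmetric(self) -> bool:
        """True when the spacing reads identically in both chain directions."""
        return self.gaps == self.gaps[::-1]

    @property
    def span(self) -> int:
        """Window length in residues covered by a match."""
        return sum(self.gaps) + self.n_anchors

    @property
    def offsets(self) -> tuple[int, ...]:
        """Anchor offsets from the first anchor."""
        out, pos = [0], 0
        for g in self.gaps:
            pos += g + 1
            out.append(pos)
        return tuple(out)

    @property
    def anchor_labels(self) -> tuple[str, ...]:
        """Phi labels for the anchors, N- to C-terminal.

        Four-anchor classes use Phi1..Phi4; the five-anchor class 4 starts
        at Phi0.
        """
        start = 0 if self.n_anchors == 5 else 1
        return tuple(f"Phi{start + i}" for i in range(self.n_anchors))


def _build_library() -> dict[str, NesPattern]:
    forward = {
        "1a": (3, 2, 1),
        "1b": (2, 2, 1),
        "1c": (3, 3, 1),
        "1d": (2, 3, 1),
        "2": (1, 2, 1),
        "3": (2, 3, 2),
        "4": (2, 3, 2, 3),
    }
    lib: dict[str, NesPattern] = {
        label: NesPattern(label, gaps) for label, gaps in forward.items()
    }
    # Reversed variants exist only for the class-1 family: classes 2 and 3
    # are palindromic, and class 4 carries no -R variant in the taxonomy.
    for label in ("1a", "1b", "1c", "1d"):
        lib[f"{label}-R"] = NesPattern(
            f"{label}-R", forward[label][::-1], reversed_=True
        )
    return lib


#: The eleven consensus patterns, keyed by class label.
PATTERN_LIBRARY: dict[str, NesPattern] = _build_library()

#: Deterministic class ordering used for sorting and tie-breaking.
CLASS_ORDER: tuple[str, ...] = (
    "1a", "1b", "1c", "1d", "2", "3", "4", "1a-R", "1b-R", "1c-R", "1d-R",
)


def pattern_library() -> dict[str, NesPattern]:
    """Return a copy of the eleven-class pattern library."""
    return dict(PATTERN_LIBRARY)


@dataclass(frozen=True)
class PatternMatch:
    """A consensus match on a sequence (0-based internal coordinates)."""

    sequence_id: str
    start: int
    anchor_positions: tuple[int, ...]
    class_label: str
    anchor_residues: str
    amphipathic: bool = False
    #: For class-3 matches the structures show the chain exiting the groove
    #: after the fourth anchor, so the anchors are better read Phi0..Phi3
    #: with P4 unused.  Both labelings are reported; this one awaits
    #: structure evidence.
    structural_labels: tuple[str, ...] | None = None

    @property
    def end(self) -> int:
        """Exclusive end of the matched window."""
        return self.anchor_positions[-1] + 1

    @property
    def anchors_1based(self) -> tuple[int, ...]:
        return tuple(p + 1 for p in self.anchor_positions)

    def sort_key(self) -> tuple[int, int]:
        return (self.start, CLASS_ORDER.index(self.class_label))


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in _STANDARD_AA:
            raise ValueError(
                f"non-standard residue {ch!r} at position {i + 1} (1-based)"
            )
    return seq


def scan_sequence(
    seq: str,
    classes: Iterable[str] | None = None,
    allow_overlaps: bool = True,
    sequence_id: str = "",
) -> list[PatternMatch]:
    """Scan ``seq`` for NES consensus matches.

    Parameters
    ----------
    seq
        Amino-acid sequence (standard 20-letter alphabet, case-insensitive).
    classes
        Class labels to scan for; ``None`` means all eleven.
    allow_overlaps
        When False, overlapping matches are reduced with
        :func:`best_per_locus`.

    Returns matches sorted by (start, class label).  An empty sequence
    yields an empty list.
    """
    seq = _validate_sequence(seq)
    if classes is None:
        labels = list(CLASS_ORDER)
    else:
        labels = list(classes)
        if not labels:
            raise ValueError("classes must be non-empty")
        unknown = [c for c in labels if c not in PATTERN_LIBRARY]
        if unknown:
            raise ValueError(f"unknown class label(s): {unknown}")

    matches: list[PatternMatch] = []
    for label in labels:
        pat = PATTERN_LIBRARY[label]
        offsets = pat.offsets
        for start in range(len(seq) - offsets[-1]):
            positions = tuple(start + o for o in offsets)
            letters = "".join(seq[p] for p in positions)
            if all(ch in PHI_RESIDUES for ch in letters):
                m = PatternMatch(
                    sequence_id=sequence_id,
                    start=start,
                    anchor_positions=positions,
                    class_label=label,
                    anchor_residues=letters,
                    structural_labels=(
                        ("Phi0", "Phi1", "Phi2", "Phi3") if label == "3" else None
                    ),
                )
                m = replace(m, amphipathic=annotate_amphipathic(m, seq))
                matches.append(m)
    matches.sort(key=PatternMatch.sort_key)
    if not allow_overlaps:
        matches = best_per_locus(matches)
    return matches


def scan_reverse_classes(
    seq: str,
    forward_classes: Iterable[str] = ("1a", "1b", "1c", "1d"),
    sequence_id: str = "",
) -> list[PatternMatch]:
    """Scan for the reversed (-R) variants of the given forward classes.

    Symmetric classes (2, 3) are scanned as themselves: their matches are
    identical in either chain direction.  Coordinates of all matches refer
    to the input sequence read N- to C-terminal.
    """
    labels = []
    for c in forward_classes:
        if c not in PATTERN_LIBRARY:
            raise ValueError(f"unknown class label: {c}")
        rev = f"{c}-R"
        labels.append(rev if rev in PATTERN_LIBRARY else c)
    return scan_sequence(seq, labels, sequence_id=sequence_id)


def mirror_match(m: PatternMatch, length: int) -> PatternMatch:
    """Map a match found on the reversed sequence back onto the original.

    Position ``i`` on the reversed sequence corresponds to ``length-1-i``
    on the original; anchor order is flipped so positions stay increasing.
    """
    positions = tuple(sorted(length - 1 - p for p in m.anchor_positions))
    return replace(
        m,
        start=positions[0],
        anchor_positions=positions,
        anchor_residues=m.anchor_residues[::-1],
    )


def annotate_amphipathic(match: PatternMatch, seq: str) -> bool:
    """Heuristic amphipathic-helix flag for a match window.

    True when the Phi positions inside the matched window (anchors plus any
    additional hydrophobic letters) contain a subset at relative offsets
    (0,4,7), (0,3,7) or (0,3,7,10).
    """
    seq = seq.upper()
    lo, hi = match.start, match.anchor_positions[-1]
    phis = {i for i in range(lo, hi + 1) if seq[i] in PHI_RESIDUES}
    for template in AMPHIPATHIC_TEMPLATES:
        for p in phis:
            if all(p + off in phis for off in template):
                return True
    return False


def best_per_locus(matches: Sequence[PatternMatch]) -> list[PatternMatch]:
    """Reduce overlapping matches to one representative per locus.

    Matches are grouped into loci by window overlap (transitively); within
    a locus the winner has the most anchors, then the earliest start, then
    the lowest class ordinal.  Deterministic and purely lexicographic.
    """
    if not matches:
        return []
    ordered = sorted(matches, key=PatternMatch.sort_key)
    loci: list[list[PatternMatch]] = []
    locus_end = -1
    for m in ordered:
        if loci and m.start <= locus_end:
            loci[-1].append(m)
        else:
            loci.append([m])
        locus_end = max(locus_end, m.end - 1)
    winners = []
    for group in loci:
        winners.append(
            min(
                group,
                key=lambda m: (
                    -len(m.anchor_positions),
                    m.start,
                    CLASS_ORDER.index(m.class_label),
                ),
            )
        )
    return winners


# ---------------------------------------------------------------------------
# I/O helpers

def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    for record in SeqIO.parse(str(path), "fasta"):
        yield record.id, str(record.seq)


def matches_to_rows(matches: Iterable[PatternMatch]) -> list[dict]:
    """Serialize matches with 1-based author-style coordinates."""
    rows = []
    for m in matches:
        rows.append(
            {
                "sequence_id": m.sequence_id,
                "class": m.class_label,
                "start_1based": m.start + 1,
                "anchors_1based": ",".join(str(p) for p in m.anchors_1based),
                "anchor_letters": m.anchor_residues,
                "amphipathic": m.amphipathic,
            }
        )
    return rows


def write_matches_tsv(matches: Iterable[PatternMatch], path) -> None:
    rows = matches_to_rows(matches)
    cols = [
        "sequence_id", "class", "start_1based",
        "anchors_1based", "anchor_letters", "amphipathic",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def write_matches_json(matches: Iterable[PatternMatch], path) -> None:
    with open(path, "w") as fh:
        json.dump(matches_to_rows(matches), fh, indent=2)
        fh.write("\n")
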