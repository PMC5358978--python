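# nescan

Sequence and structure characterization of CRM1 nuclear export signals
(NESs).

CRM1 (Exportin-1 / XPO1) exports hundreds of different protein cargoes from
the nucleus by recognizing short NES peptides: 8–15 residues presenting 3–5
hydrophobic anchors (Φ = Leu/Val/Ile/Phe/Met, labeled Φ0–Φ4) to five
pockets (P0–P4) in the HEAT-repeat 11–12 groove. Sequence consensus alone
is a weak predictor — roughly half of consensus-matching candidate NESs do
not bind CRM1 — because the groove also imposes structural requirements:
the bound peptide must present its anchors in register with the pockets,
carry one conserved turn of helix spanning Φ2X₂₋₃Φ3 whose ψ angles walk
from helical into β-strand values, and hydrogen-bond its backbone carbonyls
to the groove-constricting filter lysine (ScCRM1 Lys579 / HsCRM1 Lys568)
rather than clash with it.

`nescan` implements both halves of this picture for structural
bioinformaticians working on nuclear export:

* **Consensus matcher** — the eleven-class NES pattern library
  (1a/1b/1c/1d, 2, 3, the five-anchor class 4, and the reversed
  1a-R…1d-R for minus-orientation NESs), with amphipathic-helix
  annotation and FASTA/TSV/JSON I/O.
* **Structural classifier** — backbone φ/ψ/ω dihedrals, DSSP-style
  secondary-structure labels (α vs 3₁₀ separated by carbonyl H-bond
  ladders), conserved-turn detection with the ψ-progression test,
  conformational class calling (helix–strand, 3₁₀–strand, loop,
  all-helix, helix–β-turn, strand–helix), Kabsch superposition,
  pocket assignment with anchor Cα displacements, filter-lysine
  hydrogen-bond/niche-motif detection, and the van-der-Waals steric
  filter, combined into the three-criterion "active NES" verdict.
* **Synthetic builder** — ideal-geometry peptide backbones from φ/ψ
  templates (NeRF chain extension), mock groove frames, and random
  sequences with embedded motifs plus truth tables for matcher
  evaluation.

## Worked example

Scan the X11L2 NES sequence and classify a synthetic class-4 peptide:

```python
>>> from nescan import scan_sequence
>>> for m in scan_sequence("SSLQELVQQFEALPGDLV", {"3", "4"}):
...     print(m.class_label, m.anchors_1based, m.anchor_residues)
3 (3, 6, 10, 13) LLFL
4 (3, 6, 10, 13, 17) LLFLL
```

With X11L2 residue 55 at position 1, anchors (3, 6, 10, 13) are
Leu57/Leu60/Phe64/Leu67 — the classic class-3 reading — and the class-4
reading extends to Leu71 through the C-terminal β-turn.

```bash
$ nescan synth --class 4 --seed 1 --out scratch/x11l2_like.pdb
19 residues (4) -> scratch/x11l2_like.pdb
$ nescan classify scratch/x11l2_like.pdb --nes-chain A
{
  "class": "4",
  "shape": "helix-beta-turn",
  "orientation": "plus",
  "is_nes_like": true,
  "notes": []
}
```

The classifier reads the 3-turn α-helix followed by a type I β-turn from
the coordinates alone and calls the five-anchor class 4 — the conformation
in which X11L2 binds CRM1. The full pipeline (`nescan run --config
config.json`) adds pocket assignment, filter-lysine hydrogen bonds and the
clash verdict when a pocket-frame JSON is supplied.

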