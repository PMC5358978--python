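# Methods

## The problem

CRM1 (Exportin-1/XPO1) recognizes nuclear export signals almost entirely
through side-chain contacts: 3–5 hydrophobic anchors (Φ ∈ {L,V,I,F,M})
dock into five pockets P0–P4 of the HEAT 11–12 groove, while the peptide
backbone is left largely free. This is why NES sequences are so diverse —
and why sequence consensus over-predicts. The structural picture adds three
constraints that `nescan` operationalizes: (1) anchors must land in 3–5
pockets in a consistent (+) or (−) chain direction; (2) every bound NES
carries a single conserved turn of helix at Φ2X₂₋₃Φ3, whose ψ angles climb
from helical toward β values along the pocket direction; (3) backbone
carbonyls of that element (Φ2+1 and Φ3 for (+) NESs, N-terminal strand
carbonyls for (−) NESs) hydrogen-bond the groove-constricting filter lysine
(ScCRM1 Lys579 ↔ Hs/MmCRM1 Lys568), whose side chain otherwise blocks any
chain that fails to transition or terminate at the constriction.

## Consensus matching

The library holds eleven patterns defined by inter-anchor spacer counts
("gaps"): 1a (3,2,1), 1b (2,2,1), 1c (3,3,1), 1d (2,3,1), 2 (1,2,1),
3 (2,3,2), 4 (2,3,2,3) and the reversed class-1 family 1a-R…1d-R with
mirrored gaps. Classes 2 and 3 are palindromic and therefore identical in
both chain directions; the `symmetric` flag on a pattern is defined as
exactly that palindromicity (class 4's five-anchor spacing is not
palindromic, and the library carries no 4-R variant). Scanning is exact
enumeration — every start position of every requested class — so the
brute-force test oracle differs from the implementation only in
bookkeeping. Class-3 matches also report the alternative Φ0…Φ3 register
(P4 unused), which is how the all-helix class-3 peptides actually bind;
that relabeling is flagged as pending structure evidence. The
amphipathic-helix annotation checks the window's hydrophobic positions
against the i, i+4, i+7 / i, i+3, i+7 / i, i+3, i+7, i+10 offset
templates. Overlapping matches are all reported by default; the
best-per-locus reducer prefers more anchors, then earlier start, then
lower class ordinal (purely lexicographic).

## Geometry

Torsions use the four-point atan2 form with the IUPAC sign convention
(validated against an independent plane-normal formulation and against
biotite in the tests). Chain breaks are declared when C(i)–N(i+1) ≥ 2.0 Å
and suppress torsions across the break. Superposition is a proper-rotation
Kabsch fit (via `scipy.spatial.transform.Rotation.align_vectors`),
cross-checked in tests against a hand-written SVD implementation. The
Sc↔Hs/Mm CRM1 numbering map is a two-point anchored offset (579↔568,
−11) applied only within residues 500–650 (the groove helices), identity
with a warning elsewhere; the 85-residue groove selection used for
cross-complex RMSD is reconstructed as all CRM1 residues with any atom
within 8 Å of the bound NES (the deposited entries do not enumerate it).

## Secondary structure and the conserved turn

Per-residue labels H/G/E/T/L are assigned from dihedral gates plus
hydrogen-bond geometry:

* helical gate φ ∈ (−100, −30), ψ ∈ (−77, 10) — wide enough to hold both
  α (−57, −47) and 3₁₀ (−49, −26) conformers under coordinate noise; runs
  shorter than 3 are demoted;
* α vs 3₁₀ within a run is decided by the run-averaged carbonyl ladders,
  O(i)···N(i+3) vs O(i)···N(i+4) restricted to partners inside the run:
  an α-helix keeps both near 3.1 Å while a 3₁₀ helix bonds i→i+3 (~2.8 Å)
  and breaks i→i+4 (~4.9 Å), so a gap above 0.8 Å calls 3₁₀. Averaging is
  deliberate: per-residue votes are fragile exactly because ideal α
  geometry puts both ladders close together. Missing O atoms fall back to
  H;
* E requires ψ ∈ [85, 180] with φ < −45 (a terminal residue with only φ
  defined counts when φ ≤ −100);
* T marks type I β-turns: central residues within ±30° of (−60, −30) and
  (−90, 0) and Cα(i)–Cα(i+3) < 7 Å.

The conserved turn is a 4-residue window whose first three ψ lie in
(−90, 45) and whose last lies in [85, 180] for (+) NESs — mirrored along
the chain for (−) NESs — or whose strand slot is a chain terminus (the
all-helix class-3 case, where the helix simply ends in the groove). The
turn-helical window is wider than the SSE helical gate because the final
helical ψ of the element has already begun its climb toward β (the
observed series run up to ψ ≈ +16 at the third position). "Gradually
increasing" ψ progression is non-strict monotonicity along the pocket
direction with one tolerated backtrack of ≤ 5°, an allowance for
coordinate noise. When anchor positions are known the window is confined
to the Φ2…Φ3 span (4 or 5 residues, since the spacing may be X₂ or X₃);
otherwise every window is scanned.

## Class calling

The decision table mirrors the observed shape families, in priority
order: long α-helix followed by a type I β-turn → class 4; β-strand before
the main helix with nothing after → strand–helix, (−), class from the
1-R spacing that matches the sequence; uninterrupted helix reaching the
chain end → all-helix, class 3 (Φ0…Φ3 register, P4 empty); 3₁₀ run then
strand → 1b; α run (≥ 2 turns) then strand → 1a/1c/1d by anchor spacing;
loop-dominated chains (≥ 50% L) with the conserved turn → class 2.
Sequence match and structural call may disagree (observed for NESs whose
1b-matching sequences bind in the 1a register); both are always reported.
A groove-derived pocket order, when available, overrides the geometric
orientation reading; without a groove an ambiguous orientation is noted.

## Groove interactions

Pocket centers are centroids of the reference NES's Φ side-chain heavy
atoms (a stated convention — the deposited entries define pockets only
pictorially). Anchor assignment greedily matches Φ side-chain centroids
(Cβ when no further side chain exists, as in synthetic builds) to pocket
centers one-to-one under a 4.0 Å cutoff — chosen to exceed the largest
observed mean anchor displacement (1.8 Å at Φ0) plus spread — with ties
broken by lower residue number then lower pocket index, making the result
independent of input order. Hydrogen bonds to the filter lysine require
NZ···O ≤ 3.5 Å and a C–O···NZ angle ≥ 90° (hydrogens are not modeled;
the source structures at 2.1–2.4 Å lack them). Two bonded carbonyls
spaced 2 or 3 apart form a niche3/niche4 motif. The steric filter uses
fixed van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 Å) and flags
overlaps above 0.4 Å — the conventional serious-clash threshold, which
also keeps genuine hydrogen-bond contacts (N···O ≈ 2.9 Å, overlap 0.17 Å)
below the line. The three-criterion verdict requires ≥ 3 assigned
pockets, a located conserved turn, and at least one filter-lysine H-bond
with no clash.

## Synthetic data

The builder places N/CA/C/O (+Cβ for non-Gly) by NeRF internal-coordinate
extension with ideal bond geometry (N–CA 1.458, CA–C 1.525, C–N 1.329 Å;
ω = 180° unless specified; Cβ improper C–N–CA–Cβ = −122.6°, the
L-chirality value observed in deposited structures). Recomputing dihedrals
on a build reproduces the spec to < 1e-3°, which is what makes the
builder a usable oracle for the classifier. Class templates place anchor
letters at the class spacing inside a Φ-free background and use canonical
segment dihedrals: α (−57, −47), 3₁₀ (−49, −26), strand (−120, 135), loop
(−80, 55)/(−100, 45) alternation, type I turn (−60, −30)/(−90, 0). Noise
is independent Gaussian on φ and ψ (default σ = 8°), reproducible under a
seed. Mock grooves plant pocket markers on the template's own anchor
side-chain points (optionally displaced by a known amount for
displacement-recovery tests) and a pseudo-lysine NZ equidistant from the
two turn carbonyls, positioned on the solution circle to maximize van der
Waals clearance; where the local geometry cannot host the two-carbonyl
niche (all-helix and minus templates), a single-carbonyl bond is planted
instead — consistent with the observation that niche motifs are absent in
(−) NESs. The blocked-groove fixture extends a class-3 helix past its last
anchor and puts the constriction exactly in its path, so the true NES
passes the filter and the overlong helix clashes by construction.

What the mocks do not emulate: real side chains beyond Cβ, groove plasticity,
solvent, crystal contacts, or genuinely ambiguous electron density. Passing
tests therefore demonstrate that the measurement machinery is correct on
known geometry, not that the thresholds are optimal for every deposited
structure; the accession script exists to check the latter where downloads
are possible.

## Problem sizes and determinism

The test and acceptance workloads use 1,000 random sequences (length ≤
200) for matcher/oracle agreement, 100 noisy builds per backbone shape for
class recovery, and 100 embedded-motif sequences of length 300 for
precision/recall — sizes at which every check is exact or tightly
convergent while the whole suite stays fast. All stochastic steps draw
from seeded NumPy generators; identical seeds reproduce byte-identical
FASTA output and coordinates. Under σ = 8° a small fraction (~1–3%) of
α-helical builds genuinely drift into 3₁₀ geometry and are labeled
accordingly; per-shape recovery stays at or above 95%.

## Known limitations

* The matcher is a consensus enumerator by design; it inherits the ~50%
  false-positive character of consensus matching and does not attempt
  activity prediction.
* Pocket centers and the 85-residue groove selection are reconstruction
  conventions; absolute displacement and RMSD values against deposited
  entries depend on them at the 0.1–0.3 Å level.
* Orientation calling without a groove is geometric only and flagged
  ambiguous for shapes that read plausibly in either direction.
* The numbering map covers only the HEAT 11–12 groove region; it is not a
  general CRM1 alignment.
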