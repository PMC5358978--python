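#!/usr/bin/env python
"""Optional checks against deposited CRM1-NES structures (needs network).

Downloads mmCIF entries from the PDB (or reads them from --cache-dir),
then recomputes with the package:

* the conserved-turn psi series of HDAC5 (5UWI) and CPEB4 (5DIF);
* groove C-alpha RMSD of each new complex against the PKI-bound reference
  (3NBY), pairing residues through the Sc<->Mm numbering offset;
* per-pocket anchor displacements of the new complexes;
* the filter-lysine steric verdict for the false-positive peptides bound
  to the K579A mutant groove (5UWT Hxk2, 5UWW DEAF1) after superposition
  onto the wild-type reference groove.

These checks require coordinate downloads and are therefore not part of
the offline test suite.  Usage:

    python scripts/accession_checks.py --cache-dir scratch/pdb
"""

from __future__ import annotations

import argparse
import json
import sys
import urllib.request
from pathlib import Path

import numpy as np

from nescan.sequence_patterns import scan_sequence
from nescan.structure_core import (
    compute_dihedrals,
    load_complex,
    map_crm1_numbering,
    superpose,
)
from nescan.conformation_classifier import find_conserved_turn, psi_progression
from nescan.groove_interactions import (
    assign_anchors,
    build_pocket_frame,
    clash_filter,
)

RCSB = "https://files.rcsb.org/download/{}.cif"

REFERENCE = "3NBY"  # PKI(Phi0L)-bound MmCRM1
NEW_COMPLEXES = ["5UWI", "5UWH", "5UWO", "5UWJ", "5UWU", "5UWP", "5UWQ", "5UWS"]
TURN_ENTRIES = {"5UWI": "HDAC5", "5DIF": "CPEB4"}
FALSE_POSITIVES = {"5UWT": "Hxk2", "5UWW": "DEAF1"}


def fetch(accession: str, cache: Path) -> Path:
    cache.mkdir(parents=True, exist_ok=True)
    path = cache / f"{accession}.cif"
    if not path.exists():
        print(f"downloading {accession} ...", file=sys.stderr)
        urllib.request.urlretrieve(RCSB.format(accession), path)
    return path


def split_chains(chains):
    """Heuristic role assignment: CRM1 is the longest chain, the NES the
    shortest peptide-sized chain."""
    ordered = sorted(chains.values(), key=len)
    nes = ordered[0]
    crm1 = ordered[-1]
    if len(nes) > 30:
        raise ValueError("no peptide-sized chain found")
    return crm1, nes


def nes_phi_anchor_numbers(nes):
    """Anchor author numbers from the best consensus match on the chain."""
    matches = scan_sequence(nes.sequence)
    if not matches:
        # fall back: all hydrophobic residues
        return [r.author_number for r in nes.residues
                if r.name in ("LEU", "VAL", "ILE", "PHE", "MET")][:5]
    best = max(matches, key=lambda m: len(m.anchor_positions))
    return [nes.residues[i].author_number for i in best.anchor_positions]


def groove_pairing(ref_crm1, mob_crm1, ref_groove_numbers, mob_is_sc=True):
    ref_cas, mob_cas = [], []
    for num in ref_groove_numbers:
        mob_num = map_crm1_numbering(num, "Mm") if mob_is_sc else num
        try:
            ref_res = ref_crm1.residue_by_number(num)
            mob_res = mob_crm1.residue_by_number(mob_num)
        except Exception:
            continue
        if "CA" in ref_res.atoms and "CA" in mob_res.atoms:
            ref_cas.append(ref_res.atoms["CA"])
            mob_cas.append(mob_res.atoms["CA"])
    return np.array(mob_cas), np.array(ref_cas)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cache-dir", type=Path, default=Path("scratch/pdb"))
    parser.add_argument("--out", type=Path, default=Path("scratch/accession_checks.json"))
    args = parser.parse_args()
    report: dict = {}

    ref_chains = load_complex(fetch(REFERENCE, args.cache_dir))
    ref_crm1, ref_nes = split_chains(ref_chains)
    ref_anchor_numbers = nes_phi_anchor_numbers(ref_nes)
    ref_crm1_chain = ref_crm1.chain_id
    ref_nes_chain = ref_nes.chain_id
    frame = build_pocket_frame(
        ref_chains, ref_crm1_chain, ref_nes_chain, ref_anchor_numbers,
        filter_lysine_number=568,
    )
    report["reference"] = {
        "accession": REFERENCE,
        "anchors": ref_anchor_numbers,
        "groove_residues": len(frame.groove_residues),
    }

    # conserved-turn psi series
    for acc, name in TURN_ENTRIES.items():
        try:
            chains = load_complex(fetch(acc, args.cache_dir))
            _, nes = split_chains(chains)
            turn = find_conserved_turn(compute_dihedrals(nes))
            entry = {"accession": acc}
            if turn is not None:
                entry.update(psi_progression(turn))
            report[f"turn_{name}"] = entry
        except Exception as exc:
            report[f"turn_{name}"] = {"error": str(exc)}

    # groove rmsd + anchor displacements for the new complexes
    displacements = []
    for acc in NEW_COMPLEXES:
        try:
            chains = load_complex(fetch(acc, args.cache_dir))
            crm1, nes = split_chains(chains)
            mob, ref = groove_pairing(ref_crm1, crm1, frame.groove_residues)
            fit = superpose(mob, ref)
            moved = nes.transformed(fit.rotation, fit.translation)
            amap = assign_anchors(moved, frame)
            displacements.append(amap)
            clash = clash_filter(moved, frame)
            report[f"complex_{acc}"] = {
                "groove_ca_rmsd": round(fit.rmsd, 3),
                "n_groove_atoms": fit.n_atoms,
                "pockets": dict(sorted(amap.assignments.items())),
                "clashing_with_Lys568": clash.clashing,
            }
        except Exception as exc:
            report[f"complex_{acc}"] = {"error": str(exc)}

    if displacements:
        from nescan.groove_interactions import anchor_displacements

        table = anchor_displacements(displacements)
        report["cohort_displacements"] = {
            k: {"mean": round(v["mean"], 2), "sd": round(v["sd"], 2)}
            for k, v in table.items()
        }

    # false positives on the wild-type groove
    for acc, name in FALSE_POSITIVES.items():
        try:
            chains = load_complex(fetch(acc, args.cache_dir))
            crm1, pep = split_chains(chains)
            mob, ref = groove_pairing(ref_crm1, crm1, frame.groove_residues)
            fit = superpose(mob, ref)
            moved = pep.transformed(fit.rotation, fit.translation)
            clash = clash_filter(moved, frame)
            report[f"false_positive_{name}"] = {
                "accession": acc,
                "clashing_with_Lys568": clash.clashing,
                "worst_overlap": clash.worst_overlap,
            }
        except Exception as exc:
            report[f"false_positive_{name}"] = {"error": str(exc)}

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(report, indent=2) + "\n")
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
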