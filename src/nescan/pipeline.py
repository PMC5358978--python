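"""Declarative pipeline: configuration, orchestration and report bundles.

A single JSON config drives sequence scanning and/or structural analysis;
every report bundle embeds the thresholds, seed, package version and a
config hash so a run can be reproduced byte-for-byte (timestamps live only
in the log file).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from .sequence_patterns import (
    matches_to_rows,
    read_fasta,
    scan_sequence,
    write_matches_tsv,
)
from .structure_core import compute_dihedrals, load_complex
from .conformation_classifier import assign_sse, classify_peptide
from .groove_interactions import (
    PocketFrame,
    assign_anchors,
    clash_filter,
    detect_filter_hbonds,
    nes_criteria_report,
)

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_PARTIAL = 3


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_THRESHOLD_KEYS = {
    "hbond_cutoff": 3.5,
    "hbond_min_angle": 90.0,
    "clash_overlap": 0.4,
    "pocket_cutoff": 4.0,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    out_dir: str
    fasta: str | None = None
    classes: list[str] | None = None
    structures: list[dict] = field(default_factory=list)
    frame: str | None = None
    thresholds: dict = field(default_factory=lambda: dict(_THRESHOLD_KEYS))
    seed: int = 0

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in payload:
            raise ConfigError("config requires 'out_dir'")
        thresholds = dict(_THRESHOLD_KEYS)
        extra = set(payload.get("thresholds", {})) - set(_THRESHOLD_KEYS)
        if extra:
            raise ConfigError(f"unknown threshold keys: {sorted(extra)}")
        thresholds.update(payload.get("thresholds", {}))
        for entry in payload.get("structures", []):
            bad = set(entry) - {"path", "nes_chain", "crm1_chain"}
            if bad:
                raise ConfigError(f"unknown structure entry keys: {sorted(bad)}")
            if "path" not in entry or "nes_chain" not in entry:
                raise ConfigError("each structure entry needs 'path' and 'nes_chain'")
        return cls(
            out_dir=payload["out_dir"],
            fasta=payload.get("fasta"),
            classes=payload.get("classes"),
            structures=list(payload.get("structures", [])),
            frame=payload.get("frame"),
            thresholds=thresholds,
            seed=int(payload.get("seed", 0)),
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
        return cls.from_dict(payload)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _analyze_structure(entry: dict, frame: PocketFrame | None, thresholds: dict) -> dict:
    chains = load_complex(entry["path"])
    nes = chains[entry["nes_chain"]]
    d = compute_dihedrals(nes)
    sse = assign_sse(d, nes)
    matches = scan_sequence(nes.sequence, sequence_id=entry["nes_chain"])
    orientation_hint = None
    groove: dict = {}
    if frame is not None:
        amap = assign_anchors(nes, frame, cutoff=thresholds["pocket_cutoff"])
        orientation_hint = amap.orientation
        hbonds, motifs, expectation = detect_filter_hbonds(
            nes,
            frame,
            cutoff=thresholds["hbond_cutoff"],
            min_angle=thresholds["hbond_min_angle"],
            expected_direction=amap.orientation,
        )
        clash = clash_filter(nes, frame, overlap_threshold=thresholds["clash_overlap"])
        call = classify_peptide(nes, matches=matches, orientation_hint=orientation_hint)
        criteria = nes_criteria_report(amap, call.turn, hbonds, clash)
        groove = {
            "anchors": {str(k): v for k, v in amap.assignments.items()},
            "occupancy": amap.occupancy,
            "displacement": amap.displacement,
            "orientation": amap.orientation,
            "hbonds": [
                {"residue": h.residue_number, "distance": round(h.distance, 3),
                 "angle": round(h.angle, 1)}
                for h in hbonds
            ],
            "niche_motifs": [
                {"pair": list(m.residue_pair), "type": m.motif_type} for m in motifs
            ],
            "expected_donors": expectation,
            "clash": {"clashing": clash.clashing, "worst_overlap": clash.worst_overlap},
            "criteria": criteria,
        }
    else:
        call = classify_peptide(nes, matches=matches)

    per_residue = [
        {
            "resnum": r.author_number,
            "name": r.name,
            "phi": None if d.phi[i] != d.phi[i] else round(float(d.phi[i]), 2),
            "psi": None if d.psi[i] != d.psi[i] else round(float(d.psi[i]), 2),
            "sse": sse[i],
        }
        for i, r in enumerate(nes.residues)
    ]
    return {
        "path": str(entry["path"]),
        "nes_chain": entry["nes_chain"],
        "sequence": nes.sequence,
        "class_call": {
            "class": call.class_label,
            "shape": call.shape,
            "orientation": call.orientation,
            "is_nes_like": call.is_nes_like,
            "notes": call.notes,
        },
        "sequence_matches": matches_to_rows(matches),
        "per_residue": per_residue,
        "groove": groove,
    }


def run_pipeline(config: RunConfig) -> tuple[int, dict]:
    """Execute the configured analyses; return (exit_code, bundle).

    Failures are isolated per input: a bad structure yields an error record
    and exit code 3, leaving the other reports intact.
    """
    from . import __version__

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {
        "tool_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "thresholds": dict(config.thresholds),
        "sequence_reports": [],
        "structure_reports": [],
        "errors": [],
    }

    if config.fasta:
        for seq_id, seq in read_fasta(config.fasta):
            try:
                matches = scan_sequence(
                    seq,
                    set(config.classes) if config.classes else None,
                    sequence_id=seq_id,
                )
            except ValueError as exc:
                bundle["errors"].append({"input": seq_id, "error": str(exc)})
                continue
            bundle["sequence_reports"].append(
                {"sequence_id": seq_id, "matches": matches_to_rows(matches)}
            )

    frame = PocketFrame.from_json(config.frame) if config.frame else None
    for entry in config.structures:
        try:
            bundle["structure_reports"].append(
                _analyze_structure(entry, frame, config.thresholds)
            )
        except Exception as exc:
            bundle["errors"].append({"input": str(entry.get("path")), "error": str(exc)})

    (out_dir / "report.json").write_text(json.dumps(bundle, indent=2) + "\n")
    for rep in bundle["structure_reports"]:
        stem = Path(rep["path"]).stem
        lines = ["resnum\tname\tphi\tpsi\tsse"]
        for row in rep["per_residue"]:
            lines.append(
                f"{row['resnum']}\t{row['name']}\t{row['phi']}\t{row['psi']}\t{row['sse']}"
            )
        (out_dir / f"{stem}_{rep['nes_chain']}_residues.tsv").write_text(
            "\n".join(lines) + "\n"
        )
    log = (
        f"nescan {__version__}\nconfig_hash {config.digest()}\nseed {config.seed}\n"
        f"timestamp {time.strftime('%Y-%m-%dT%H:%M:%S')}\n"
    )
    (out_dir / "run.log").write_text(log)
    code = EXIT_PARTIAL if bundle["errors"] else EXIT_OK
    return code, bundle
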