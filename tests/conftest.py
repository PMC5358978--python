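"""Shared fixtures: brute-force oracles and synthetic inputs."""

from __future__ import annotations

import numpy as np
import pytest

# ---------------------------------------------------------------------------
# Independent brute-force consensus oracle.
#
# The gap table is frozen here on purpose (not imported from the package):
# the forward spacings come from the consensus taxonomy, the reversed ones
# by reversing them, and the oracle tests every start position directly.

ORACLE_GAPS = {
    "1a": (3, 2, 1),
    "1b": (2, 2, 1),
    "1c": (3, 3, 1),
    "1d": (2, 3, 1),
    "2": (1, 2, 1),
    "3": (2, 3, 2),
    "4": (2, 3, 2, 3),
    "1a-R": (1, 2, 3),
    "1b-R": (1, 2, 2),
    "1c-R": (1, 3, 3),
    "1d-R": (1, 3, 2),
}
ORACLE_PHI = set("LVIFM")


def brute_force_scan(seq: str, classes=None):
    """Enumerate every (class, start) anchor placement directly."""
    seq = seq.upper()
    hits = []
    for label in sorted(ORACLE_GAPS) if classes is None else sorted(classes):
        gaps = ORACLE_GAPS[label]
        offsets = [0]
        for g in gaps:
            offsets.append(offsets[-1] + g + 1)
        for start in range(len(seq)):
            positions = [start + o for o in offsets]
            if positions[-1] >= len(seq):
                break
            if all(seq[p] in ORACLE_PHI for p in positions):
                hits.append((label, start, tuple(positions)))
    return set(hits)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


def random_protein(rng, length, phi_frac=0.25):
    non_phi = "ADEGHKNPQRSTWYC"
    phi = "LVIFM"
    letters = [
        phi[rng.integers(5)] if rng.random() < phi_frac else non_phi[rng.integers(15)]
        for _ in range(length)
    ]
    return "".join(letters)


# ---------------------------------------------------------------------------
# Structure fixtures

@pytest.fixture(scope="session")
def alpha_helix_peptide():
    from nescan.synthetic_builder import BackboneSpec, build_backbone

    n = 15
    return build_backbone(
        BackboneSpec("ASEQLVAEFKLAAMS", np.full(n, -57.0), np.full(n, -47.0))
    )


@pytest.fixture(scope="session")
def class_templates():
    """Noise-free built peptides for every class label."""
    from nescan.synthetic_builder import build_backbone, build_class_template

    out = {}
    for label in ("1a", "1b", "1c", "1d", "2", "3", "4", "1a-R", "1b-R", "1c-R", "1d-R"):
        spec = build_class_template(label)
        out[label] = (spec, build_backbone(spec))
    return out


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a random translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.normal(0, 20, 3)
    return R, t
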