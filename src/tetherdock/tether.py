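"""Linker-length filtering of docking poses.

Two covalently linked domains constrain feasible rigid-body poses: the
Cα–Cα distance between the static domain's C-terminal residue and the
mobile domain's N-terminal residue cannot exceed what the inter-domain
linker can span. Poses beyond the cutoff (60 Å by default, inclusive)
are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .poses import Pose
from .structure import ResidueKey, Structure

__all__ = ["TetherSpec", "TetherReport", "termini_distance", "filter_by_tether", "physical_bound"]

MAX_CA_CA_EXTENSION = 3.8  # Å per residue, fully extended chain


@dataclass(frozen=True)
class TetherSpec:
    """Which termini are linked and how far the linker can reach."""

    static_terminus: ResidueKey
    mobile_terminus: ResidueKey
    cutoff: float = 60.0
    n_linker_residues: int | None = None

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class TetherReport:
    n_input: int
    n_kept: int
    n_dropped: int
    cutoff: float


def termini_distance(
    pose: Pose, spec: TetherSpec, static: Structure, mobile: Structure
) -> float:
    """Cα–Cα distance (Å) between the linked termini in the posed coordinates."""
    try:
        i = static.atom_index(spec.static_terminus, "CA")
    except KeyError as exc:
        raise ValueError(f"static terminus {spec.static_terminus} has no CA") from exc
    try:
        j = mobile.atom_index(spec.mobile_terminus, "CA")
    except KeyError as exc:
        raise ValueError(f"mobile terminus {spec.mobile_terminus} has no CA") from exc
    ca_static = static.atoms[i].position
    ca_mobile = pose.transform.apply(mobile.atoms[j].position.reshape(1, 3))[0]
    return float(np.linalg.norm(ca_mobile - ca_static))


def filter_by_tether(
    poses: Sequence[Pose], spec: TetherSpec, static: Structure, mobile: Structure
) -> tuple[list[Pose], TetherReport]:
    """Keep poses whose termini distance is <= cutoff (inclusive), order preserved."""
    if not poses:
        raise ValueError("poses must be non-empty")
    kept = [
        p
        for p in poses
        if termini_distance(p, spec, static, mobile) <= spec.cutoff
    ]
    report = TetherReport(
        n_input=len(poses),
        n_kept=len(kept),
        n_dropped=len(poses) - len(kept),
        cutoff=spec.cutoff,
    )
    return kept, report


def physical_bound(n_linker_residues: int) -> float:
    """Maximum Cα–Cα span of an n-residue linker (3.8 Å per residue)."""
    if n_linker_residues < 1:
        raise ValueError("n_linker_residues must be >= 1")
    return n_linker_residues * MAX_CA_CA_EXTENSION
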