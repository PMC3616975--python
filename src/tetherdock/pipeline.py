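"""End-to-end orchestration: couple -> dock -> triage -> rank.

A single YAML config drives the whole workflow; every default is echoed into
the run log so parameter provenance is auditable, and stage counts (poses
generated / passed tether / clusters / representatives) are logged the same
way. Identical config plus seeds gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Any, Sequence

import numpy as np
import yaml

from . import clustering, coupling, interface, tether
from .poses import (
    PerturbationSpec,
    Pose,
    sample_poses,
    seed_placement,
    write_manifest,
)
from .structure import (
    DomainDefinition,
    Ensemble,
    ResidueKey,
    Structure,
    select_indices,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_couple", "run_dock", "run_triage"]


@dataclass
class PipelineConfig:
    """Validated knobs for every pipeline stage (defaults match the defaults
    of the underlying operations)."""

    # torsion coupling
    n_bins: int = 24
    n_permutations: int = 100
    coupling_seed: int = 0
    min_coupling: float = 0.05
    # sampler
    sampler: PerturbationSpec = field(default_factory=PerturbationSpec)
    n_poses: int = 10000
    sampling_seed: int = 0
    contact_gap: float = 4.0
    clash_min_dist: float = 2.5
    clash_max_violations: int = 5
    # tether
    tether_cutoff: float = 60.0
    # clustering / ranking
    top_k: int = 5
    # metric cutoffs
    hydrophobic_cutoff: float = 5.0
    ionic_cutoff: float = 6.0
    stacking_min: float = 4.5
    stacking_max: float = 7.0
    probe_radius: float = 1.4
    n_sphere_points: int = 960

    def __post_init__(self) -> None:
        for name in (
            "min_coupling",
            "tether_cutoff",
            "hydrophobic_cutoff",
            "ionic_cutoff",
            "stacking_min",
            "stacking_max",
            "probe_radius",
            "contact_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_poses < 1 or self.top_k < 1:
            raise ValueError("n_poses and top_k must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sampler = PerturbationSpec(**raw.pop("sampler", {}))
        return cls(sampler=sampler, **raw)

    def log_defaults(self) -> None:
        d = asdict(self)
        logger.info("pipeline config: %s", json.dumps(d, default=str, sort_keys=True))


def run_couple(
    ensembles: Ensemble | Sequence[Ensemble],
    config: PipelineConfig,
    *,
    torsion_labels=None,
) -> tuple[coupling.CouplingMatrix, list[coupling.SiteGroup]]:
    """Torsion extraction -> corrected-MI matrix -> site groups."""
    config.log_defaults()
    series = coupling.extract_torsions(ensembles)
    matrix = coupling.residue_coupling_matrix(
        series,
        n_bins=config.n_bins,
        n_permutations=config.n_permutations,
        seed=config.coupling_seed,
        torsion_labels=torsion_labels,
    )
    sites = coupling.cluster_sites(matrix, config.min_coupling)
    logger.info(
        "couple: %d residues, %d significant pairs, %d site groups",
        len(matrix.residue_order),
        int(matrix.significance_mask.sum() // 2),
        len(sites),
    )
    return matrix, sites


def run_dock(
    static: Structure,
    mobile: Structure,
    site_static: Sequence[ResidueKey],
    site_mobile: Sequence[ResidueKey],
    config: PipelineConfig,
    *,
    manifest_path=None,
) -> tuple[Pose, list[Pose]]:
    """Seed placement plus Gaussian pose sampling with clash annotation."""
    seed_pose = seed_placement(
        static, mobile, site_static, site_mobile, config.contact_gap
    )
    poses = sample_poses(
        seed_pose,
        config.sampler,
        config.n_poses,
        config.sampling_seed,
        static,
        mobile,
        clash_min_dist=config.clash_min_dist,
        clash_max_violations=config.clash_max_violations,
        screen_clashes=True,
    )
    logger.info("dock: generated %d poses (seed %d)", len(poses), config.sampling_seed)
    if manifest_path is not None:
        write_manifest(poses, manifest_path)
    return seed_pose, poses


def run_triage(
    poses: Sequence[Pose],
    static: Structure,
    mobile: Structure,
    tether_spec: tether.TetherSpec,
    config: PipelineConfig,
    static_domain: DomainDefinition,
    mobile_domain: DomainDefinition,
) -> dict[str, Any]:
    """Tether filter -> cluster -> representatives -> per-representative metrics.

    Returns a dict with survivors, the cluster result, the top cluster ids,
    representative poses, their interface reports, and the stage counts.
    """
    survivors, report = tether.filter_by_tether(poses, tether_spec, static, mobile)
    logger.info(
        "triage: %d/%d poses within tether cutoff %.1f Å",
        report.n_kept,
        report.n_input,
        report.cutoff,
    )
    result: dict[str, Any] = {
        "tether_report": report,
        "survivors": survivors,
        "clusters": None,
        "top": [],
        "representatives": [],
        "reports": [],
    }
    if len(survivors) == 0:
        logger.info("triage: no poses survive the tether filter; stopping cleanly")
        return result
    if len(survivors) == 1:
        result["representatives"] = [survivors[0]]
    else:
        static_sel = select_indices(static, None, "CA")
        mobile_sel = select_indices(mobile, None, "CA")
        matrix = clustering.pairwise_matrix(
            survivors, static, mobile, static_sel, mobile_sel
        )
        cres = clustering.nmrclust(matrix)
        top = clustering.top_clusters(cres, config.top_k)
        by_id = {p.id: p for p in survivors}
        reps = [by_id[cres.representatives[lab]] for lab in top]
        logger.info(
            "triage: %d clusters, top %d representatives: %s",
            len(cres.sizes),
            len(reps),
            [p.id for p in reps],
        )
        result["clusters"] = cres
        result["top"] = top
        result["representatives"] = reps

    for p in result["representatives"]:
        placed_mobile = mobile.with_coords(p.transform.apply(mobile.coords))
        merged = Structure(list(static.atoms) + list(placed_mobile.atoms))
        result["reports"].append(
            interface.interface_report(
                merged,
                static_domain,
                mobile_domain,
                hydrophobic_cutoff=config.hydrophobic_cutoff,
                ionic_cutoff=config.ionic_cutoff,
                stacking_range=(config.stacking_min, config.stacking_max),
                probe_radius=config.probe_radius,
                n_sphere_points=config.n_sphere_points,
            )
        )
    return result
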