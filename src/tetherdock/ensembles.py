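"""Stability analytics over conformational ensembles.

Superposition-based RMSF profiles (fluctuation of one domain after fitting
on the other measures how rigidly the complex holds together), per-frame
segment RMSD monitors, distance time series, and assembly of the per-model
ranking table: interaction energy mean ± sd, pseudokinase-domain RMSF,
buried surface area, ionic/hydrophobic contact counts, and the fluctuation
of a nominated helix (αC-style KH_RMSF).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import kabsch
from .interface import (
    DEFAULT_NONBONDED,
    NonbondedParams,
    buried_surface_area,
    hydrophobic_contacts,
    interaction_energy,
    ionic_contacts,
)
from .structure import (
    DomainDefinition,
    Ensemble,
    ResidueKey,
    Structure,
    select_indices,
)

__all__ = [
    "RMSFProfile",
    "TimeSeries",
    "RankingRow",
    "superpose_ensemble",
    "rmsf",
    "segment_rmsd_series",
    "distance_series",
    "ranking_table",
    "RANKING_COLUMNS",
]


@dataclass
class RMSFProfile:
    residue_keys: list[ResidueKey]
    rmsf: np.ndarray  # Å, per residue
    fit_selection: str

    def __post_init__(self) -> None:
        if len(self.rmsf) != len(self.residue_keys):
            raise ValueError("rmsf length must match residue keys")
        if np.any(self.rmsf < 0):
            raise ValueError("rmsf must be >= 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.rmsf))


@dataclass
class TimeSeries:
    frames: np.ndarray
    values: np.ndarray
    unit: str
    label: str

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.values):
            raise ValueError("frames and values must have equal length")


@dataclass
class RankingRow:
    label: str
    e_bind_mean: float
    e_bind_sd: float
    pk_rmsf: float
    bsa: float
    ionic_contacts: int
    hydrophobic_contacts: int
    kh_rmsf: float
    failed: bool = False


RANKING_COLUMNS = [
    "Type",
    "Interaction Energy (kcal/mol)",
    "PK_RMSF (Å)",
    "BSA(Å^2)",
    "Contacts",
    "KH_RMSF (Å)",
]


def superpose_ensemble(ensemble: Ensemble, fit_indices: np.ndarray) -> Ensemble:
    """Kabsch-fit every frame onto frame 0 over the fit selection (idempotent)."""
    if len(fit_indices) < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    coords = ensemble.coords
    ref = coords[0][fit_indices]
    fitted = np.empty_like(coords)
    fitted[0] = coords[0]
    for k in range(1, len(coords)):
        R, t = kabsch(coords[k][fit_indices], ref)
        fitted[k] = coords[k] @ R.T + t
    return ensemble.with_coords(fitted)


def rmsf(
    ensemble: Ensemble,
    fit_indices: np.ndarray,
    measure_indices: np.ndarray,
    *,
    fit_label: str = "fit",
) -> RMSFProfile:
    """Per-residue Cα-style RMSF of the measure selection after fitting.

    Deviations are taken from the time-mean position of each atom (the
    conventional definition). Measure indices are grouped by residue; the
    per-residue value is the RMS fluctuation over its atoms and frames.
    """
    if ensemble.n_frames < 2:
        raise ValueError("rmsf needs at least 2 frames")
    fitted = superpose_ensemble(ensemble, fit_indices)
    coords = fitted.coords[:, measure_indices, :]  # (F, M, 3)
    mean_pos = coords.mean(axis=0)
    sq_dev = np.sum((coords - mean_pos) ** 2, axis=2)  # (F, M)
    per_atom = np.sqrt(sq_dev.mean(axis=0))  # (M,)

    atoms = [ensemble.frames[0].atoms[i] for i in measure_indices]
    keys: list[ResidueKey] = []
    values: list[float] = []
    by_res: dict[ResidueKey, list[float]] = {}
    for a, v in zip(atoms, per_atom):
        by_res.setdefault(a.residue_key, []).append(float(v))
    for k in dict.fromkeys(a.residue_key for a in atoms):
        keys.append(k)
        values.append(float(np.sqrt(np.mean(np.square(by_res[k])))))
    return RMSFProfile(keys, np.array(values), fit_label)


def segment_rmsd_series(
    ensemble: Ensemble,
    reference: Structure,
    fit_indices: np.ndarray,
    measure_indices: np.ndarray,
    *,
    label: str = "segment_rmsd",
) -> TimeSeries:
    """Per-frame RMSD of the measure selection after fitting each frame to
    the reference over the fit selection."""
    if len(fit_indices) == 0 or len(measure_indices) == 0:
        raise ValueError("selections must be non-empty")
    ref_xyz = reference.coords
    ref_fit = ref_xyz[fit_indices]
    ref_measure = ref_xyz[measure_indices]
    out = np.empty(ensemble.n_frames)
    for k, frame in enumerate(ensemble.frames):
        xyz = frame.coords
        R, t = kabsch(xyz[fit_indices], ref_fit)
        moved = xyz[measure_indices] @ R.T + t
        out[k] = np.sqrt(np.mean(np.sum((moved - ref_measure) ** 2, axis=1)))
    return TimeSeries(np.arange(ensemble.n_frames), out, "Å", label)


def distance_series(
    ensemble: Ensemble,
    group_a: np.ndarray,
    group_b: np.ndarray,
    mode: str = "centroid",
    *,
    label: str = "distance",
) -> TimeSeries:
    """Per-frame distance between two atom groups.

    mode: 'centroid' (unweighted centroid of each group), 'min' (closest
    atom pair), or 'CA' (alias of centroid for single-atom Cα groups).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("groups must be non-empty")
    coords = ensemble.coords
    xa = coords[:, group_a, :]
    xb = coords[:, group_b, :]
    if mode in ("centroid", "CA"):
        vals = np.linalg.norm(xa.mean(axis=1) - xb.mean(axis=1), axis=1)
    elif mode == "min":
        diff = xa[:, :, None, :] - xb[:, None, :, :]
        vals = np.sqrt(np.sum(diff**2, axis=3)).min(axis=(1, 2))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TimeSeries(np.arange(ensemble.n_frames), vals, "Å", label)


def ranking_table(
    models: Sequence[tuple[str, Ensemble, dict]],
    params: NonbondedParams = DEFAULT_NONBONDED,
    *,
    n_sphere_points: int = 240,
) -> tuple[list[RankingRow], pd.DataFrame]:
    """Per-model metric panel, rows sorted by mean interaction energy.

    Each model is (label, ensemble, config) where config holds
    ``domain_a``/``domain_b`` (DomainDefinition of the static/kinase-like and
    mobile/pseudokinase-like domains) and ``kh_range`` (chain, first, last)
    for the monitored helix. Contact counts are frame-averaged then rounded
    half-up; single-frame models get sd 0.
    """
    rows: list[RankingRow] = []
    for label, ensemble, cfg in models:
        dom_a: DomainDefinition = cfg["domain_a"]
        dom_b: DomainDefinition = cfg["domain_b"]
        try:
            frame0 = ensemble.frames[0]
            fit_idx = select_indices(frame0, dom_a, "CA")
            measure_idx = select_indices(frame0, dom_b, "CA")
            e_vals, bsa_vals, ion_vals, hyd_vals = [], [], [], []
            for frame in ensemble.frames:
                e = interaction_energy(frame, dom_a, dom_b, params)
                e_vals.append(e.e_bind)
                bsa_vals.append(
                    buried_surface_area(
                        frame, dom_a, dom_b, n_sphere_points=n_sphere_points
                    )
                )
                ion_vals.append(len(ionic_contacts(frame, dom_a, dom_b)))
                hyd_vals.append(len(hydrophobic_contacts(frame, dom_a, dom_b)))
            if ensemble.n_frames >= 2:
                pk = rmsf(ensemble, fit_idx, measure_idx, fit_label=dom_a.label).mean
                kh_cfg = cfg.get("kh_range")
                if kh_cfg is not None:
                    kh_dom = DomainDefinition("kh", *kh_cfg)
                    kh_idx = select_indices(frame0, kh_dom, "CA")
                    kh = rmsf(ensemble, fit_idx, kh_idx, fit_label=dom_a.label).mean
                else:
                    kh = float("nan")
            else:
                pk = 0.0
                kh = 0.0
            e_arr = np.asarray(e_vals)
            rows.append(
                RankingRow(
                    label=label,
                    e_bind_mean=float(e_arr.mean()),
                    e_bind_sd=float(e_arr.std(ddof=0)) if len(e_arr) > 1 else 0.0,
                    pk_rmsf=pk,
                    bsa=float(np.mean(bsa_vals)),
                    ionic_contacts=int(np.floor(np.mean(ion_vals) + 0.5)),
                    hydrophobic_contacts=int(np.floor(np.mean(hyd_vals) + 0.5)),
                    kh_rmsf=kh,
                )
            )
        except (ValueError, KeyError) as exc:
            rows.append(
                RankingRow(
                    label=f"{label} [failed: {exc}]",
                    e_bind_mean=float("nan"),
                    e_bind_sd=float("nan"),
                    pk_rmsf=float("nan"),
                    bsa=float("nan"),
                    ionic_contacts=0,
                    hydrophobic_contacts=0,
                    kh_rmsf=float("nan"),
                    failed=True,
                )
            )
    rows.sort(key=lambda r: (r.failed, r.e_bind_mean if not r.failed else 0.0))
    df = pd.DataFrame(
        {
            RANKING_COLUMNS[0]: [r.label for r in rows],
            RANKING_COLUMNS[1]: [
                f"{r.e_bind_mean:.1f}±{r.e_bind_sd:.1f}" if not r.failed else "failed"
                for r in rows
            ],
            RANKING_COLUMNS[2]: [round(r.pk_rmsf, 2) for r in rows],
            RANKING_COLUMNS[3]: [round(r.bsa, 1) for r in rows],
            RANKING_COLUMNS[4]: [
                f"{r.ionic_contacts}/{r.hydrophobic_contacts}" for r in rows
            ],
            RANKING_COLUMNS[5]: [round(r.kh_rmsf, 2) for r in rows],
        }
    )
    return rows, df
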