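"""Corrected mutual information between residue torsion distributions.

Across an ensemble of conformations, each residue contributes the backbone
phi/psi/omega dihedrals and up to four side-chain chi dihedrals. Pairwise
statistical coupling between residues is measured as histogram (plugin)
mutual information in nats over a fixed 15°-bin discretization, corrected by
a frame-permutation null: a residue-pair entry is the summed excess MI
(observed minus null mean) over its torsion pairs, zeroed wherever the
observed MI does not exceed the null's 95th percentile. Highly coupled
residues are then grouped by average-linkage hierarchical clustering into
candidate interface / allosteric sites.

Omega torsions are extracted but excluded from coupling by default — they
are nearly constant at 180° and contribute only noise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .geometry import dihedral
from .structure import Ensemble, ResidueKey

logger = logging.getLogger(__name__)

__all__ = [
    "TorsionSeries",
    "CouplingMatrix",
    "SiteGroup",
    "extract_torsions",
    "pair_mutual_information",
    "coupling_null",
    "residue_coupling_matrix",
    "cluster_sites",
    "export_network",
    "write_matrix_tsv",
]

DEFAULT_N_BINS = 24  # 15 degree bins over [-180, 180)

# backbone torsion atom quadruples, relative residue offsets
_BACKBONE = {
    "phi": ((-1, "C"), (0, "N"), (0, "CA"), (0, "C")),
    "psi": ((0, "N"), (0, "CA"), (0, "C"), (1, "N")),
    "omega": ((0, "CA"), (0, "C"), (1, "N"), (1, "CA")),
}

# chi torsion atom names per residue type
_CHI = {
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "LYS": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "CE"),
        ("CG", "CD", "CE", "NZ"),
    ],
    "ARG": [
        ("N", "CA", "CB", "CG"),
        ("CA", "CB", "CG", "CD"),
        ("CB", "CG", "CD", "NE"),
        ("CG", "CD", "NE", "CZ"),
    ],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
}


@dataclass(frozen=True)
class TorsionSeries:
    """Per-frame values of one torsion of one residue, degrees in [-180, 180)."""

    residue_key: ResidueKey
    torsion_label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        v = ((v + 180.0) % 360.0) - 180.0
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CouplingMatrix:
    """Symmetric corrected-MI matrix over residues (nats), with significance mask."""

    residue_order: list[ResidueKey]
    values: np.ndarray
    significance_mask: np.ndarray
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        n = len(self.residue_order)
        if self.values.shape != (n, n) or self.significance_mask.shape != (n, n):
            raise ValueError("matrix shapes must match residue order")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("coupling matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")


@dataclass
class SiteGroup:
    """A cluster of mutually coupled residues (a candidate site)."""

    label: str
    residue_keys: set[ResidueKey]
    mean_internal_coupling: float

    def __post_init__(self) -> None:
        if not self.residue_keys:
            raise ValueError("site group must be non-empty")


def _frame_positions(ensemble: Ensemble) -> tuple[np.ndarray, dict]:
    coords = ensemble.coords  # (F, A, 3)
    index: dict[tuple[ResidueKey, str], int] = {}
    for i, a in enumerate(ensemble.frames[0].atoms):
        index.setdefault((a.residue_key, a.name), i)
    return coords, index


def extract_torsions(
    ensemble: Ensemble | Sequence[Ensemble],
) -> list[TorsionSeries]:
    """Extract phi/psi/omega and chi1..chi4 series from an ensemble.

    A list of ensembles (independent runs of the same system) is accepted and
    concatenated along frames after per-ensemble validation. Torsions whose
    atoms are missing (chain termini, truncated side chains) are skipped with
    a logged warning.
    """
    if isinstance(ensemble, Ensemble):
        ensembles = [ensemble]
    else:
        ensembles = list(ensemble)
        ref_sig = [
            (a.name, a.residue_key) for a in ensembles[0].frames[0].atoms
        ]
        for k, e in enumerate(ensembles[1:], start=1):
            if [(a.name, a.residue_key) for a in e.frames[0].atoms] != ref_sig:
                raise ValueError(f"ensemble {k} topology differs from ensemble 0")

    all_coords = np.concatenate([e.coords for e in ensembles], axis=0)
    _, index = _frame_positions(ensembles[0])
    frame0 = ensembles[0].frames[0]
    residues = frame0.residues
    resnames = {k: frame0.residue_name(k) for k in residues}

    series: list[TorsionSeries] = []
    for pos, key in enumerate(residues):
        # backbone
        for label, quad in _BACKBONE.items():
            idx = []
            ok = True
            for off, name in quad:
                p = pos + off
                if not (0 <= p < len(residues)):
                    ok = False
                    break
                j = index.get((residues[p], name))
                if j is None:
                    ok = False
                    break
                idx.append(j)
            if not ok:
                continue
            series.append(_series_from_indices(all_coords, idx, key, label))
        # side chain
        for ci, quad in enumerate(_CHI.get(resnames[key], []), start=1):
            idx = [index.get((key, name)) for name in quad]
            if any(j is None for j in idx):
                logger.warning("residue %s: missing atoms for chi%d, skipped", key, ci)
                continue
            series.append(_series_from_indices(all_coords, idx, key, f"chi{ci}"))
    return series


def _series_from_indices(coords, idx, key, label) -> TorsionSeries:
    p0, p1, p2, p3 = (coords[:, j, :] for j in idx)
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=1, keepdims=True))
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(m1 * n2, axis=1)
    vals = np.degrees(np.arctan2(y, x))
    return TorsionSeries(key, label, vals)


def _discretize(values: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    return np.clip(np.digitize(values, edges) - 1, 0, n_bins - 1)


def _mi_from_bins(ai: np.ndarray, bi: np.ndarray, n_bins: int) -> float:
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * (np.log(joint[nz]) - np.log(np.outer(px, py)[nz]))))


def pair_mutual_information(
    a: TorsionSeries, b: TorsionSeries, n_bins: int = DEFAULT_N_BINS
) -> float:
    """Plugin MI (nats) of the discretized joint torsion distribution, >= 0."""
    if len(a) != len(b):
        raise ValueError(f"series length mismatch: {len(a)} vs {len(b)}")
    return _mi_from_bins(
        _discretize(a.values, n_bins), _discretize(b.values, n_bins), n_bins
    )


@dataclass
class NullSummary:
    """Permutation-null MI summary for one torsion pair."""

    mean: float
    p95: float


def coupling_null(
    a: TorsionSeries,
    b: TorsionSeries,
    n_permutations: int = 100,
    seed: int = 0,
    n_bins: int = DEFAULT_N_BINS,
) -> NullSummary:
    """Null MI distribution under random frame permutation of one series.

    Destroys cross-series dependence while preserving each marginal, so the
    null captures the finite-sample MI bias of independent torsions.
    """
    if n_permutations < 50:
        raise ValueError("n_permutations must be >= 50")
    rng = np.random.default_rng(seed)
    ai = _discretize(a.values, n_bins)
    bi = _discretize(b.values, n_bins)
    vals = np.empty(n_permutations)
    for k in range(n_permutations):
        vals[k] = _mi_from_bins(ai, rng.permutation(bi), n_bins)
    # upper order statistic ("higher"): the interpolated quantile of a finite
    # null is anti-conservative and would exceed the nominal 5% level
    return NullSummary(
        mean=float(vals.mean()), p95=float(np.quantile(vals, 0.95, method="higher"))
    )


def residue_coupling_matrix(
    series_set: Sequence[TorsionSeries],
    n_bins: int = DEFAULT_N_BINS,
    n_permutations: int = 100,
    seed: int = 0,
    *,
    torsion_labels: Iterable[str] | None = None,
    min_spread: float = 1.0,
) -> CouplingMatrix:
    """Residue-pair corrected MI: summed excess over significant torsion pairs.

    For each inter-residue torsion pair, MI_observed is kept only if it
    exceeds the permutation null's 95th percentile, contributing
    max(0, MI_observed - null_mean); contributions sum over torsion pairs.
    ``torsion_labels`` restricts which torsions enter (default: all but
    omega). Torsions whose circular spread is under ``min_spread`` degrees
    are constant and skipped.
    """
    if torsion_labels is None:
        keep = lambda s: s.torsion_label != "omega"  # noqa: E731
    else:
        wanted = set(torsion_labels)
        keep = lambda s: s.torsion_label in wanted  # noqa: E731

    by_residue: dict[ResidueKey, list[TorsionSeries]] = {}
    order: list[ResidueKey] = []
    for s in series_set:
        if s.residue_key not in by_residue:
            order.append(s.residue_key)
            by_residue[s.residue_key] = []
        if keep(s) and _circular_spread(s.values) >= min_spread:
            by_residue[s.residue_key].append(s)
    if len(order) < 2:
        raise ValueError("need torsions for at least 2 residues")

    n = len(order)
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    rng = np.random.default_rng(seed)
    for i, j in itertools.combinations(range(n), 2):
        total = 0.0
        significant = False
        for sa in by_residue[order[i]]:
            for sb in by_residue[order[j]]:
                obs = pair_mutual_information(sa, sb, n_bins)
                null = coupling_null(
                    sa, sb, n_permutations, seed=int(rng.integers(2**31)), n_bins=n_bins
                )
                if obs > null.p95:
                    total += max(0.0, obs - null.mean)
                    significant = True
        if significant:
            values[i, j] = values[j, i] = total
            mask[i, j] = mask[j, i] = True
    return CouplingMatrix(order, values, mask, n_permutations, seed)


def _circular_spread(values: np.ndarray) -> float:
    rad = np.radians(values)
    R = np.hypot(np.mean(np.cos(rad)), np.mean(np.sin(rad)))
    # circular SD in degrees
    return float(np.degrees(np.sqrt(max(0.0, -2.0 * np.log(max(R, 1e-12))))))


def cluster_sites(
    matrix: CouplingMatrix, min_coupling: float = 0.05
) -> list[SiteGroup]:
    """Group coupled residues by average-linkage clustering of the MI matrix.

    Distance between residues is max(values) - value; the dendrogram is cut
    at the distance corresponding to ``min_coupling`` and groups of >= 2
    residues whose mean internal coupling is at least ``min_coupling`` are
    returned, largest first.
    """
    vals = matrix.values
    vmax = vals.max()
    if vmax <= 0:
        return []
    dist = vmax - vals
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=vmax - min_coupling, criterion="distance")

    groups: list[SiteGroup] = []
    for lab in np.unique(labels):
        members = [i for i in range(len(labels)) if labels[i] == lab]
        if len(members) < 2:
            continue
        sub = vals[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        mean_internal = float(sub[iu].mean())
        if mean_internal >= min_coupling:
            groups.append(
                SiteGroup(
                    label=f"site{len(groups)}",
                    residue_keys={matrix.residue_order[i] for i in members},
                    mean_internal_coupling=mean_internal,
                )
            )
    groups.sort(key=lambda g: (-len(g.residue_keys), -g.mean_internal_coupling))
    for k, g in enumerate(groups):
        g.label = f"site{k}"
    return groups


def _residue_tag(key: ResidueKey) -> str:
    chain, num, icode = key
    return f"{chain}{num}{icode}"


def export_network(matrix: CouplingMatrix, path, threshold: float = 0.0) -> int:
    """Write significant residue-pair edges above ``threshold`` as TSV.

    Returns the number of edges written. Suitable for force-directed layout
    tools (source, target, weight columns).
    """
    n = len(matrix.residue_order)
    count = 0
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for i in range(n):
            for j in range(i + 1, n):
                if matrix.significance_mask[i, j] and matrix.values[i, j] > threshold:
                    fh.write(
                        f"{_residue_tag(matrix.residue_order[i])}\t"
                        f"{_residue_tag(matrix.residue_order[j])}\t"
                        f"{matrix.values[i, j]:.6f}\n"
                    )
                    count += 1
    return count


def write_matrix_tsv(matrix: CouplingMatrix, path) -> None:
    """Write the coupling matrix with residue labels as row/column headers."""
    import pandas as pd

    tags = [_residue_tag(k) for k in matrix.residue_order]
    pd.DataFrame(matrix.values, index=tags, columns=tags).to_csv(path, sep="\t")
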