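"""NMRCLUST-style clustering of docking poses by tethered RMSD.

The pose-comparison metric is the RMSD of the mobile domain's Cα atoms after
optimal (Kabsch) superposition of the static domain — global motion cancels,
leaving only the relative domain placement. Average-linkage agglomeration is
cut at the step minimizing a combined penalty of normalized average
intra-cluster spread plus normalized cluster count (each scaled onto
[1, n_steps]), so no cutoff needs to be chosen by hand. Representatives are
medoids: the member minimizing mean distance to the rest of its cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .geometry import kabsch
from .poses import Pose
from .structure import Structure

__all__ = [
    "PoseDistanceMatrix",
    "ClusterResult",
    "tethered_rmsd",
    "pairwise_matrix",
    "nmrclust",
    "top_clusters",
]


@dataclass
class PoseDistanceMatrix:
    pose_ids: list[str]
    values: np.ndarray  # (n, n) tethered RMSD, Å

    def __post_init__(self) -> None:
        n = len(self.pose_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match pose ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("diagonal must be zero")


@dataclass
class ClusterResult:
    labels: dict[str, int]
    representatives: dict[int, str]
    penalty_trace: np.ndarray  # combined penalty per agglomeration step
    chosen_step: int
    spreads: dict[int, float]  # mean intra-cluster distance per cluster
    sizes: dict[int, int]


def _posed_ca(
    pose: Pose, static: Structure, mobile: Structure, sel_static: np.ndarray, sel_mobile: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    s = static.coords[sel_static]
    m = pose.transform.apply(mobile.coords)[sel_mobile]
    return s, m


def tethered_rmsd(
    pose_i: Pose,
    pose_j: Pose,
    static: Structure,
    mobile: Structure,
    static_sel: np.ndarray,
    mobile_sel: np.ndarray,
) -> float:
    """RMSD (Å) of mobile-selection atoms after superposing the static selection.

    Both poses share the same static coordinates, so the static-domain fit is
    only nontrivial when poses carry whole-complex motion; it is kept for
    generality and exactness.
    """
    if len(static_sel) < 3:
        raise ValueError("need at least 3 static atoms for superposition")
    si, mi = _posed_ca(pose_i, static, mobile, static_sel, mobile_sel)
    sj, mj = _posed_ca(pose_j, static, mobile, static_sel, mobile_sel)
    R, t = kabsch(sj, si)
    mj_fit = mj @ R.T + t
    return float(np.sqrt(np.mean(np.sum((mj_fit - mi) ** 2, axis=1))))


def pairwise_matrix(
    poses: Sequence[Pose],
    static: Structure,
    mobile: Structure,
    static_sel: np.ndarray,
    mobile_sel: np.ndarray,
) -> PoseDistanceMatrix:
    """All-pairs tethered RMSD matrix."""
    if len(poses) < 2:
        raise ValueError("need at least 2 poses")
    # static coords identical across poses -> superposition is identity and the
    # RMSD reduces to a plain mobile-selection RMSD; compute directly.
    mobile_xyz = mobile.coords
    placed = np.stack([p.transform.apply(mobile_xyz)[mobile_sel] for p in poses])
    n = len(poses)
    values = np.zeros((n, n))
    for i in range(n):
        diff = placed[i + 1 :] - placed[i]
        if len(diff):
            values[i, i + 1 :] = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
    values = values + values.T
    return PoseDistanceMatrix([p.id for p in poses], values)


def nmrclust(matrix: PoseDistanceMatrix) -> ClusterResult:
    """Average-linkage agglomeration with automatic penalty-based cut.

    At each merge step the average spread (mean intra-cluster pairwise
    distance over clusters with >= 2 members) and the cluster count are each
    linearly rescaled onto [1, n_steps]; the chosen step minimizes their sum.
    Representatives are medoids.
    """
    n = len(matrix.pose_ids)
    if n < 2:
        raise ValueError("need at least 2 poses to cluster")
    D = matrix.values
    Z = linkage(squareform(D, checks=False), method="average")
    n_steps = n - 1

    spreads = np.empty(n_steps)
    counts = np.empty(n_steps)
    labelings = []
    for step in range(1, n_steps + 1):
        labels = fcluster(Z, t=n - step, criterion="maxclust")
        labelings.append(labels)
        counts[step - 1] = len(np.unique(labels))
        cluster_spreads = []
        for lab in np.unique(labels):
            idx = np.where(labels == lab)[0]
            if len(idx) >= 2:
                sub = D[np.ix_(idx, idx)]
                cluster_spreads.append(sub[np.triu_indices(len(idx), 1)].mean())
        spreads[step - 1] = np.mean(cluster_spreads) if cluster_spreads else 0.0

    def rescale(x: np.ndarray) -> np.ndarray:
        lo, hi = x.min(), x.max()
        if hi - lo < 1e-12:
            return np.ones_like(x)
        return 1.0 + (n_steps - 1.0) * (x - lo) / (hi - lo)

    penalty = rescale(spreads) + rescale(counts)
    chosen = int(np.argmin(penalty)) + 1
    labels = labelings[chosen - 1]

    label_map = {matrix.pose_ids[i]: int(labels[i]) for i in range(n)}
    representatives: dict[int, str] = {}
    spread_map: dict[int, float] = {}
    size_map: dict[int, int] = {}
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        size_map[int(lab)] = len(idx)
        if len(idx) == 1:
            representatives[int(lab)] = matrix.pose_ids[idx[0]]
            spread_map[int(lab)] = 0.0
            continue
        sub = D[np.ix_(idx, idx)]
        mean_dist = sub.sum(axis=1) / (len(idx) - 1)
        representatives[int(lab)] = matrix.pose_ids[idx[int(np.argmin(mean_dist))]]
        spread_map[int(lab)] = float(sub[np.triu_indices(len(idx), 1)].mean())
    return ClusterResult(
        labels=label_map,
        representatives=representatives,
        penalty_trace=penalty,
        chosen_step=chosen,
        spreads=spread_map,
        sizes=size_map,
    )


def top_clusters(result: ClusterResult, k: int = 5) -> list[int]:
    """Cluster ids ordered by size (ties -> lower mean spread), first k."""
    order = sorted(
        result.sizes,
        key=lambda lab: (-result.sizes[lab], result.spreads[lab]),
    )
    if k > len(order):
        warnings.warn(
            f"requested top {k} clusters but only {len(order)} exist", stacklevel=2
        )
        return order
    return order[:k]
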