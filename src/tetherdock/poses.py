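"""Rigid-body pose seeding and Gaussian perturbation sampling for a tethered
two-domain system.

One domain is held static; the other ("mobile") carries a rigid transform.
The seed pose joins the two domains face-to-face through user-nominated
surface patches (e.g. sites found by torsion-coupling analysis). Around that
seed, poses are drawn with the classic local-docking move set: Gaussian
translations along the line connecting the domain centers (3 Å SD by
default) and in the two perpendicular directions (8 Å SD), a Gaussian
rotation about the center axis (8° SD), and a Gaussian tilt of that axis
(8° SD) about a uniformly random perpendicular direction.

Every stochastic operation takes an explicit seed or numpy Generator and is
a pure function of its inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure import Structure, ResidueKey

__all__ = [
    "RigidTransform",
    "PerturbationSpec",
    "Pose",
    "seed_placement",
    "perturb",
    "sample_poses",
    "clash_screen",
    "recover_perturbation",
    "center_axis_frame",
    "write_manifest",
    "read_manifest",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal to 1e-8")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must have det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: (self.compose(other)).apply(x) == self.apply(other.apply(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


@dataclass(frozen=True)
class PerturbationSpec:
    """Gaussian move-set widths for local rigid-body sampling.

    Defaults follow the standard local-docking perturbation: 8° about the
    center axis, 8° tilt of the axis, 3 Å along the center line, 8 Å in each
    perpendicular direction.
    """

    axial_rotation_sd: float = 8.0  # degrees
    tilt_sd: float = 8.0  # degrees
    axial_translation_sd: float = 3.0  # Å
    perpendicular_translation_sd: float = 8.0  # Å

    def __post_init__(self) -> None:
        for name in (
            "axial_rotation_sd",
            "tilt_sd",
            "axial_translation_sd",
            "perpendicular_translation_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Pose:
    """A rigid placement of the mobile domain, with provenance."""

    id: str
    transform: RigidTransform
    parent_id: str | None = None
    seed: int | None = None
    clash_violations: int | None = None
    clash_ok: bool | None = None

    def mobile_coords(self, mobile: Structure) -> np.ndarray:
        return self.transform.apply(mobile.coords)


def _heavy_coords(structure: Structure) -> np.ndarray:
    return structure.coords[structure.heavy_indices()]


def _patch_centroid(structure: Structure, site: Sequence[ResidueKey]) -> np.ndarray:
    site = set(site)
    pts = [
        a.position
        for a in structure.atoms
        if a.residue_key in site and a.element != "H"
    ]
    if not pts:
        raise ValueError(f"site residues not found: {sorted(site)}")
    return np.mean(pts, axis=0)


def _min_interdomain_distance(static_xyz: np.ndarray, mobile_xyz: np.ndarray) -> float:
    tree = cKDTree(static_xyz)
    d, _ = tree.query(mobile_xyz, k=1)
    return float(d.min())


def seed_placement(
    static: Structure,
    mobile: Structure,
    site_static: Sequence[ResidueKey],
    site_mobile: Sequence[ResidueKey],
    contact_gap: float = 4.0,
    *,
    tol: float = 0.1,
) -> Pose:
    """Join two domains through their nominated surface patches.

    The mobile domain is rotated (about its centroid) so its patch-to-centroid
    axis anti-aligns with the static one, then slid along the static patch's
    outward axis until the minimum interdomain heavy-atom distance equals
    ``contact_gap`` (bisection to ``tol`` Å).
    """
    s_xyz = _heavy_coords(static)
    m_xyz = _heavy_coords(mobile)
    c_s = s_xyz.mean(axis=0)
    c_m = m_xyz.mean(axis=0)
    p_s = _patch_centroid(static, site_static)
    p_m = _patch_centroid(mobile, site_mobile)

    u_s = p_s - c_s
    u_m = p_m - c_m
    if np.linalg.norm(u_s) < 1e-9 or np.linalg.norm(u_m) < 1e-9:
        raise ValueError("patch centroid coincides with domain centroid")
    u_s /= np.linalg.norm(u_s)
    u_m /= np.linalg.norm(u_m)

    for label, xyz, p, u in (("static", s_xyz, p_s, u_s), ("mobile", m_xyz, p_m, u_m)):
        if np.max((xyz - p) @ u) > 2.0:
            warnings.warn(
                f"{label} site patch appears buried "
                "(domain atoms extend beyond the patch along its outward axis)",
                stacklevel=2,
            )

    rot, _ = Rotation.align_vectors([-u_s], [u_m])
    R0 = rot.as_matrix()

    def place(gap_offset: float) -> RigidTransform:
        # x -> R0 (x - c_m) + c_m + (target - rotated patch centroid)
        p_m_rot = R0 @ (p_m - c_m) + c_m
        target = p_s + gap_offset * u_s
        return RigidTransform(R0, c_m - R0 @ c_m + (target - p_m_rot))

    def min_dist(g: float) -> float:
        tr = place(g)
        return _min_interdomain_distance(s_xyz, tr.apply(m_xyz))

    lo, hi = -50.0, 300.0
    if min_dist(hi) < contact_gap:
        raise ValueError("no contact-gap placement achievable along the patch axis")
    # walk lo up until below the gap (domains overlapping/contacting)
    while min_dist(lo) > contact_gap and lo < hi:
        lo += 10.0
        if lo >= hi:
            raise ValueError("no contact-gap placement achievable along the patch axis")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < contact_gap:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol / 4:
            break
    g = 0.5 * (lo + hi)
    return Pose(id="seed", transform=place(g), parent_id=None, seed=None)


def center_axis_frame(
    pose: Pose, static: Structure, mobile: Structure
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal frame (e, p1, p2) of the center axis plus the mobile centroid.

    e points from the static heavy-atom centroid to the posed mobile centroid;
    p1, p2 are a deterministic perpendicular pair.
    """
    s_c = _heavy_coords(static).mean(axis=0)
    m_c = pose.transform.apply(_heavy_coords(mobile)).mean(axis=0)
    e = m_c - s_c
    norm = np.linalg.norm(e)
    if norm < 1e-9:
        raise ValueError("domain centroids coincide; center axis undefined")
    e /= norm
    helper = np.eye(3)[np.argmin(np.abs(e))]
    p1 = np.cross(e, helper)
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(e, p1)
    return e, p1, p2, m_c


def perturb(
    pose: Pose,
    spec: PerturbationSpec,
    rng: np.random.Generator,
    static: Structure,
    mobile: Structure,
    *,
    pose_id: str | None = None,
) -> Pose:
    """One Gaussian rigid-body move away from ``pose``.

    Order of operations (fixed): translate by N(0, axial_sd) along the center
    axis plus N(0, perp_sd) along each perpendicular direction; rotate by
    N(0, axial_rotation_sd) about the center axis; tilt that axis by
    N(0, tilt_sd) about a uniformly random perpendicular direction. Rotations
    pivot at the translated mobile centroid, so the centroid displacement is
    exactly the drawn translation.
    """
    e, p1, p2, m_c = center_axis_frame(pose, static, mobile)

    d_axial = rng.normal(0.0, spec.axial_translation_sd)
    d_p1 = rng.normal(0.0, spec.perpendicular_translation_sd)
    d_p2 = rng.normal(0.0, spec.perpendicular_translation_sd)
    alpha = rng.normal(0.0, spec.axial_rotation_sd)
    beta = rng.normal(0.0, spec.tilt_sd)
    theta = rng.uniform(0.0, 2.0 * np.pi)

    dt = d_axial * e + d_p1 * p1 + d_p2 * p2
    R_ax = Rotation.from_rotvec(np.radians(alpha) * e).as_matrix()
    tilt_axis = np.cos(theta) * p1 + np.sin(theta) * p2
    R_tilt = Rotation.from_rotvec(np.radians(beta) * tilt_axis).as_matrix()
    R_c = R_tilt @ R_ax

    pivot = m_c + dt
    # x -> R_c (x + dt - pivot) + pivot, applied after the parent transform
    delta = RigidTransform(R_c, pivot - R_c @ (pivot - dt))
    new_transform = delta.compose(pose.transform)
    return Pose(
        id=pose_id if pose_id is not None else f"{pose.id}:perturbed",
        transform=new_transform,
        parent_id=pose.id,
        seed=pose.seed,
    )


def recover_perturbation(
    parent: Pose, child: Pose, static: Structure, mobile: Structure
) -> dict[str, float]:
    """Decompose a child pose into the move-set coordinates of ``perturb``.

    Returns axial/perpendicular translation components (Å) and the axial
    rotation angle (degrees, via swing–twist decomposition about the center
    axis) plus the tilt angle.
    """
    e, p1, p2, m_c_parent = center_axis_frame(parent, static, mobile)
    m_ref = _heavy_coords(mobile).mean(axis=0)
    m_c_child = child.transform.apply(m_ref.reshape(1, 3))[0]
    m_c_parent_exact = parent.transform.apply(m_ref.reshape(1, 3))[0]
    dt = m_c_child - m_c_parent_exact

    R_delta = child.transform.rotation @ parent.transform.rotation.T
    q = Rotation.from_matrix(R_delta).as_quat()  # (x, y, z, w)
    v, w = q[:3], q[3]
    proj = float(np.dot(v, e))
    alpha = np.degrees(2.0 * np.arctan2(proj, w))
    alpha = ((alpha + 180.0) % 360.0) - 180.0
    twist_q = np.array([*(proj * e), w])
    nrm = np.linalg.norm(twist_q)
    if nrm < 1e-12:  # pure 180-degree swing; no twist component
        twist = Rotation.identity()
    else:
        twist = Rotation.from_quat(twist_q / nrm)
    swing = Rotation.from_matrix(R_delta) * twist.inv()
    beta = np.degrees(np.linalg.norm(swing.as_rotvec()))
    return {
        "axial": float(np.dot(dt, e)),
        "perp1": float(np.dot(dt, p1)),
        "perp2": float(np.dot(dt, p2)),
        "axial_angle": float(alpha),
        "tilt_angle": float(beta),
    }


def sample_poses(
    seed_pose: Pose,
    spec: PerturbationSpec,
    n: int,
    seed: int,
    static: Structure,
    mobile: Structure,
    *,
    clash_min_dist: float = 2.5,
    clash_max_violations: int = 5,
    screen_clashes: bool = False,
    strict: bool = False,
) -> list[Pose]:
    """Draw ``n`` independent perturbations of the seed pose.

    Deterministic for a fixed (seed_pose, spec, n, seed). With
    ``screen_clashes`` poses are annotated with interdomain clash counts;
    ``strict`` additionally drops flagged poses (the default retains them,
    marked, since no side-chain repacking is attempted).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    static_tree = cKDTree(_heavy_coords(static)) if screen_clashes else None
    m_xyz = _heavy_coords(mobile)
    out: list[Pose] = []
    for i in range(n):
        p = perturb(seed_pose, spec, rng, static, mobile, pose_id=f"pose{i:05d}")
        p = replace(p, seed=seed)
        if screen_clashes:
            posed = p.transform.apply(m_xyz)
            count = static_tree.query_ball_point(
                posed, r=clash_min_dist, return_length=True
            ).sum()
            ok = bool(count <= clash_max_violations)
            p = replace(p, clash_violations=int(count), clash_ok=ok)
            if strict and not ok:
                continue
        out.append(p)
    return out


def clash_screen(
    pose: Pose,
    static: Structure,
    mobile: Structure,
    min_dist: float = 2.5,
    max_violations: int = 5,
) -> tuple[bool, int]:
    """Count interdomain heavy-atom pairs closer than ``min_dist``.

    Returns (passes, violation_count); passes means count <= max_violations.
    """
    tree = cKDTree(_heavy_coords(static))
    posed = pose.transform.apply(_heavy_coords(mobile))
    count = int(tree.query_ball_point(posed, r=min_dist, return_length=True).sum())
    return count <= max_violations, count


MANIFEST_COLUMNS = (
    ["pose_id", "parent_id", "seed"]
    + [f"r{i}{j}" for i in range(3) for j in range(3)]
    + ["tx", "ty", "tz", "clash_violations", "clash_ok"]
)


def write_manifest(poses: Sequence[Pose], path) -> None:
    """Write poses as a TSV manifest (id, provenance, 12 transform numbers, clash info)."""
    import pandas as pd

    rows: list[dict] = []
    for p in poses:
        R = p.transform.rotation
        t = p.transform.translation
        row = {
            "pose_id": p.id,
            "parent_id": p.parent_id if p.parent_id is not None else "",
            "seed": p.seed if p.seed is not None else "",
        }
        for i in range(3):
            for j in range(3):
                row[f"r{i}{j}"] = R[i, j]
        row["tx"], row["ty"], row["tz"] = t
        row["clash_violations"] = (
            p.clash_violations if p.clash_violations is not None else ""
        )
        row["clash_ok"] = p.clash_ok if p.clash_ok is not None else ""
        rows.append(row)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> list[Pose]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"pose_id": str, "parent_id": str})
    poses = []
    for _, row in df.iterrows():
        R = np.array(
            [[row[f"r{i}{j}"] for j in range(3)] for i in range(3)], dtype=float
        )
        t = np.array([row["tx"], row["ty"], row["tz"]], dtype=float)
        parent = row["parent_id"] if isinstance(row["parent_id"], str) and row["parent_id"] else None
        seed = int(row["seed"]) if not _isna(row["seed"]) else None
        cv = row.get("clash_violations")
        ok = row.get("clash_ok")
        poses.append(
            Pose(
                id=str(row["pose_id"]),
                transform=RigidTransform(R, t),
                parent_id=parent,
                seed=seed,
                clash_violations=int(cv) if not _isna(cv) else None,
                clash_ok=bool(ok) if not _isna(ok) else None,
            )
        )
    return poses


def _isna(x) -> bool:
    import pandas as pd

    return x is None or (isinstance(x, str) and not x) or pd.isna(x)
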