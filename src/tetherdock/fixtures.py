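"""Deterministic synthetic structure generators used as test beds.

Every generator is a pure function of its arguments (including the seed).
Structures are built from ideal bond lengths and angles with the NeRF
internal-coordinate scheme, so construction dihedrals are recovered exactly
by torsion extraction. The generators emulate the *statistical* structure of
real data (coupled rotamer jumps, thermal jitter, pose families), not its
physics: no force field is sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import place_atom
from .poses import Pose, RigidTransform
from .structure import Atom, Ensemble, ResidueKey, Structure

__all__ = [
    "PlantedFeature",
    "InfeasibleFeatureError",
    "make_helix_domain",
    "make_two_domain_complex",
    "make_jitter_ensemble",
    "make_rotamer_ensemble",
    "make_pose_groups",
]

# ideal backbone geometry (Engh-Huber-like)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

ONE_TO_THREE = {
    "A": "ALA", "G": "GLY", "S": "SER", "V": "VAL", "L": "LEU", "I": "ILE",
    "K": "LYS", "R": "ARG", "D": "ASP", "E": "GLU", "F": "PHE", "Y": "TYR",
}

# Side-chain internal-coordinate templates.
# Each entry: (atom, (ref_a, ref_b, ref_c), bond, angle, dihedral)
# where dihedral is a number or ("chiN", offset) meaning chiN + offset.
_SC = {
    "ALA": [("CB", ("C", "N", "CA"), 1.53, 110.5, -122.6)],
    "SER": [
        ("CB", ("C", "N", "CA"), 1.53, 110.5, -122.6),
        ("OG", ("N", "CA", "CB"), 1.417, 110.8, ("chi1", 0.0)),
    ],
    "VAL": [
        ("CB", ("C", "N", "CA"), 1.54, 111.5, -122.6),
        ("CG1", ("N", "CA", "CB"), 1.52, 110.5, ("chi1", 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi1", 120.0)),
    ],
    "LEU": [
        ("CB", ("C", "N", "CA"), 1.53, 110.5, -122.6),
        ("CG", ("N", "CA", "CB"), 1.53, 116.3, ("chi1", 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.52, 110.7, ("chi2", 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.52, 110.7, ("chi2", 120.0)),
    ],
    "ILE": [
        ("CB", ("C", "N", "CA"), 1.54, 111.5, -122.6),
        ("CG1", ("N", "CA", "CB"), 1.53, 110.4, ("chi1", 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.52, 110.5, ("chi1", -120.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.52, 113.8, ("chi2", 0.0)),
    ],
    "LYS": [
        ("CB", ("C", "N", "CA"), 1.53, 110.5, -122.6),
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi1", 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi2", 0.0)),
        ("CE", ("CB", "CG", "CD"), 1.52, 111.3, ("chi3", 0.0)),
        ("NZ", ("CG", "CD", "CE"), 1.49, 111.9, ("chi4", 0.0)),
    ],
    "ARG": [
        ("CB", ("C", "N", "CA"), 1.53, 110.5, -122.6),
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi1", 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 111.3, ("chi2", 0.0)),
        ("NE", ("CB", "CG", "CD"), 1.46, 112.0, ("chi3", 0.0)),
        ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, ("chi4", 0.0)),
        ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
    ],
    "ASP": [
        ("CB", ("C", "N", "CA"), 1.53, 110.5, -122.6),
        ("CG", ("N", "CA", "CB"), 1.52, 112.6, ("chi1", 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.4, ("chi2", 0.0)),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.4, ("chi2", 180.0)),
    ],
    "GLU": [
        ("CB", ("C", "N", "CA"), 1.53, 110.5, -122.6),
        ("CG", ("N", "CA", "CB"), 1.52, 114.1, ("chi1", 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.52, 112.6, ("chi2", 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.4, ("chi3", 0.0)),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.4, ("chi3", 180.0)),
    ],
    "PHE": [
        ("CB", ("C", "N", "CA"), 1.53, 110.5, -122.6),
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, ("chi1", 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.7, ("chi2", 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.7, ("chi2", 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
    "GLY": [],
}
_SC["TYR"] = _SC["PHE"] + [("OH", ("CD1", "CE1", "CZ"), 1.38, 120.0, 180.0)]

# default side-chain dihedrals (roughly extended rotamers)
_DEFAULT_CHI = {"chi1": -65.0, "chi2": 175.0, "chi3": 180.0, "chi4": 180.0}
_DEFAULT_CHI_OVERRIDES = {"PHE": {"chi2": 90.0}, "TYR": {"chi2": 90.0},
                          "ASP": {"chi2": -20.0}}


class InfeasibleFeatureError(ValueError):
    """The requested planted interface features cannot coexist in one rigid placement."""


def _element_of(name: str) -> str:
    return name[0]


def make_helix_domain(
    sequence: str,
    phi: float = -57.0,
    psi: float = -47.0,
    *,
    chain: str = "A",
    start_residue: int = 1,
    omega: float = 180.0,
    chi: Mapping[int, Mapping[str, float]] | None = None,
) -> Structure:
    """Build an ideal-geometry peptide at constant (phi, psi).

    The default dihedrals give a canonical α-helix. ``chi`` optionally maps a
    residue *index* (0-based within the sequence) to side-chain dihedral
    overrides, e.g. ``{3: {"chi1": 180.0}}``. Supported residues:
    A G S V L I K R D E F Y.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for letter in sequence:
        if letter not in ONE_TO_THREE:
            raise ValueError(f"unsupported residue letter {letter!r}")
    chi = chi or {}

    atoms: list[Atom] = []
    serial = 1
    backbone: list[dict[str, np.ndarray]] = []

    for i, letter in enumerate(sequence):
        resname = ONE_TO_THREE[letter]
        if i == 0:
            n = np.zeros(3)
            ca = np.array([BOND_N_CA, 0.0, 0.0])
            ang = np.radians(ANGLE_N_CA_C)
            c = ca + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            prev = backbone[i - 1]
            n = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi)
            ca = place_atom(prev["CA"], prev["C"], n, BOND_N_CA, ANGLE_C_N_CA, omega)
            c = place_atom(prev["C"], n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        backbone.append({"N": n, "CA": ca, "C": c})

    for i, letter in enumerate(sequence):
        resname = ONE_TO_THREE[letter]
        key: ResidueKey = (chain, start_residue + i, "")
        placed = dict(backbone[i])
        # carbonyl oxygen: anti to the next N (psi + 180 off the same refs)
        placed["O"] = place_atom(
            placed["N"], placed["CA"], placed["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0
        )
        chi_values = dict(_DEFAULT_CHI)
        chi_values.update(_DEFAULT_CHI_OVERRIDES.get(resname, {}))
        chi_values.update(chi.get(i, {}))
        for name, refs, bond, angle, dih in _SC[resname]:
            if isinstance(dih, tuple):
                dih_val = chi_values[dih[0]] + dih[1]
            else:
                dih_val = dih
            placed[name] = place_atom(
                placed[refs[0]], placed[refs[1]], placed[refs[2]], bond, angle, dih_val
            )
        for name in ["N", "CA", "C", "O"] + [s[0] for s in _SC[resname]]:
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=_element_of(name),
                    residue_key=key,
                    residue_name=resname,
                    position=placed[name],
                )
            )
            serial += 1
    return Structure(atoms)


@dataclass(frozen=True)
class PlantedFeature:
    """One ground-truth interface feature for ``make_two_domain_complex``.

    kind: hydrophobic_pair | ionic_pair | stacking_pair. ``target_distance``
    is exact (±0.05 Å) for the feature the rigid placement is solved on
    (the first one); later features are verified to fall at or under
    ``target_distance`` (treated as a cutoff) unless ``exact`` is set.
    """

    kind: str
    residue_a: ResidueKey
    residue_b: ResidueKey
    target_distance: float
    exact: bool = False

    def __post_init__(self) -> None:
        if self.kind not in {"hydrophobic_pair", "ionic_pair", "stacking_pair"}:
            raise ValueError(f"unknown feature kind {self.kind}")


def _sidechain_heavy(structure: Structure, key: ResidueKey) -> np.ndarray:
    pts = [
        a.position
        for a in structure.atoms
        if a.residue_key == key
        and a.element != "H"
        and a.name not in {"N", "CA", "C", "O"}
    ]
    if not pts:
        raise ValueError(f"residue {key} has no side-chain heavy atoms")
    return np.asarray(pts)


def _charged_group(structure: Structure, key: ResidueKey) -> np.ndarray:
    from .structure import DEFAULT_CLASS_TABLE

    resname = structure.residue_name(key)
    names = DEFAULT_CLASS_TABLE.charged_group_atoms.get(resname)
    if not names:
        raise ValueError(f"residue {key} ({resname}) has no charged group")
    return np.asarray(
        [a.position for a in structure.atoms if a.residue_key == key and a.name in names]
    )

def _ring_centroid(structure: Structure, key: ResidueKey) -> np.ndarray:
    from .structure import DEFAULT_CLASS_TABLE

    resname = structure.residue_name(key)
    names = DEFAULT_CLASS_TABLE.ring_atoms.get(resname)
    if not names:
        raise ValueError(f"residue {key} ({resname}) is not aromatic")
    pts = [
        a.position for a in structure.atoms if a.residue_key == key and a.name in names
    ]
    return np.mean(pts, axis=0)


def _feature_distance(
    feature: PlantedFeature, a: Structure, b_coords_fn, b: Structure
) -> float:
    """Defining distance of a feature given a callable posing B's coords."""
    if feature.kind == "stacking_pair":
        pa = _ring_centroid(a, feature.residue_a)
        pb_ref = _ring_centroid(b, feature.residue_b)
        return float(np.linalg.norm(b_coords_fn(pb_ref.reshape(1, 3))[0] - pa))
    if feature.kind == "ionic_pair":
        xa = _charged_group(a, feature.residue_a)
        xb = b_coords_fn(_charged_group(b, feature.residue_b))
    else:
        xa = _sidechain_heavy(a, feature.residue_a)
        xb = b_coords_fn(_sidechain_heavy(b, feature.residue_b))
    from scipy.spatial.distance import cdist

    return float(cdist(xa, xb).min())


def make_two_domain_complex(
    domain_a: Structure,
    domain_b: Structure,
    gap: float = 4.0,
    planted_features: Sequence[PlantedFeature] = (),
    *,
    tol: float = 0.05,
) -> tuple[Structure, list[dict]]:
    """Rigidly place domain B against domain A and verify planted features.

    With no features, B is slid along the line between domain centroids until
    the minimum interdomain heavy-atom distance equals ``gap``. With
    features, B is first rotated so the two feature patches face each other
    (as in pose seeding), then slid until the first feature's defining
    distance equals its target within ``tol``; remaining features are
    verified (exact ones within ``tol``, others at or under their target).
    Returns the merged complex and a ground-truth feature ledger.
    """
    from scipy.spatial.distance import cdist
    from scipy.spatial.transform import Rotation

    a_xyz = np.asarray(
        [at.position for at in domain_a.atoms if at.element != "H"]
    )
    b_xyz_all = domain_b.coords
    b_heavy_idx = domain_b.heavy_indices()

    if planted_features:
        f0 = planted_features[0]
        c_a = a_xyz.mean(axis=0)
        c_b = b_xyz_all[b_heavy_idx].mean(axis=0)
        p_a = _feature_point(domain_a, f0, side="a")
        p_b = _feature_point(domain_b, f0, side="b")
        u_a = (p_a - c_a) / np.linalg.norm(p_a - c_a)
        u_b = (p_b - c_b) / np.linalg.norm(p_b - c_b)
        rot, _ = Rotation.align_vectors([-u_a], [u_b])
        R0 = rot.as_matrix()

        def pose_fn(g: float):
            p_b_rot = R0 @ (p_b - c_b) + c_b
            shift = (p_a + g * u_a) - p_b_rot
            return lambda x: (np.asarray(x) - c_b) @ R0.T + c_b + shift

        def f0_dist(g: float) -> float:
            return _feature_distance(f0, domain_a, pose_fn(g), domain_b)

        lo, hi = 0.0, 200.0
        while f0_dist(lo) > f0.target_distance and lo > -50.0:
            lo -= 5.0
        if f0_dist(lo) > f0.target_distance or f0_dist(hi) < f0.target_distance:
            raise InfeasibleFeatureError(
                f"cannot reach target distance for {f0.kind} {f0.residue_a}-{f0.residue_b}"
            )
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if f0_dist(mid) < f0.target_distance:
                lo = mid
            else:
                hi = mid
        g = 0.5 * (lo + hi)
        coords_fn = pose_fn(g)
    else:
        c_a = a_xyz.mean(axis=0)
        c_b = b_xyz_all[b_heavy_idx].mean(axis=0)
        u = c_b - c_a
        if np.linalg.norm(u) < 1e-9:
            u = np.array([1.0, 0.0, 0.0])
        u = u / np.linalg.norm(u)

        def mind(g: float) -> float:
            moved = b_xyz_all[b_heavy_idx] + g * u
            return float(cdist(a_xyz, moved).min())

        lo, hi = -100.0, 500.0
        while mind(lo) > gap and lo < hi:
            lo += 10.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if mind(mid) < gap:
                lo = mid
            else:
                hi = mid
        g = 0.5 * (lo + hi)
        coords_fn = lambda x: np.asarray(x) + g * u  # noqa: E731

    ledger: list[dict] = []
    for i, feat in enumerate(planted_features):
        d = _feature_distance(feat, domain_a, coords_fn, domain_b)
        achieved_exact = i == 0 or feat.exact
        if achieved_exact and abs(d - feat.target_distance) > tol:
            raise InfeasibleFeatureError(
                f"feature {feat.kind} {feat.residue_a}-{feat.residue_b}: "
                f"achieved {d:.3f} Å vs target {feat.target_distance:.3f} Å"
            )
        if not achieved_exact and d > feat.target_distance + tol:
            raise InfeasibleFeatureError(
                f"feature {feat.kind} {feat.residue_a}-{feat.residue_b}: "
                f"achieved {d:.3f} Å exceeds cutoff {feat.target_distance:.3f} Å"
            )
        ledger.append(
            {
                "kind": feat.kind,
                "residue_a": feat.residue_a,
                "residue_b": feat.residue_b,
                "target_distance": feat.target_distance,
                "achieved_distance": d,
            }
        )

    new_b = domain_b.with_coords(coords_fn(b_xyz_all))
    merged = Structure(
        list(domain_a.atoms) + list(new_b.atoms),
        annotations={
            "domain_a": set(domain_a.residues),
            "domain_b": set(domain_b.residues),
        },
    )
    return merged, ledger


def _feature_point(structure: Structure, feature: PlantedFeature, side: str) -> np.ndarray:
    key = feature.residue_a if side == "a" else feature.residue_b
    if feature.kind == "stacking_pair":
        return _ring_centroid(structure, key)
    if feature.kind == "ionic_pair":
        return _charged_group(structure, key).mean(axis=0)
    return _sidechain_heavy(structure, key).mean(axis=0)


def make_jitter_ensemble(
    structure: Structure,
    sigma_profile: float | Mapping[ResidueKey, float],
    n_frames: int,
    seed: int,
) -> Ensemble:
    """Gaussian per-coordinate jitter around a reference structure.

    ``sigma_profile`` is a single SD in Å or a per-residue mapping (missing
    residues get 0, so a fit region can be kept noiseless).
    """
    rng = np.random.default_rng(seed)
    base = structure.coords
    if isinstance(sigma_profile, Mapping):
        sigmas = np.array(
            [sigma_profile.get(a.residue_key, 0.0) for a in structure.atoms]
        )
    else:
        sigmas = np.full(len(structure.atoms), float(sigma_profile))
    if np.any(sigmas < 0):
        raise ValueError("sigma must be >= 0")
    frames = []
    for _ in range(n_frames):
        noise = rng.normal(0.0, 1.0, size=base.shape) * sigmas[:, None]
        frames.append(structure.with_coords(base + noise))
    return Ensemble(frames)


def make_rotamer_ensemble(
    n_residues: int,
    coupled_pairs: Sequence[tuple[int, int, np.ndarray]],
    n_frames: int,
    seed: int,
    *,
    wells: tuple[float, float] = (-60.0, 180.0),
    well_noise: float = 5.0,
    sequence_letter: str = "L",
) -> tuple[Ensemble, dict]:
    """Ensemble whose side-chain chi1 angles hop between two rotamer wells.

    ``coupled_pairs`` lists (i, j, joint) with ``joint`` a 2x2 probability
    table over the well states of residues i and j (0-based indices); all
    other residues flip independently (uniform). The backbone is a static
    ideal helix; wells sit at gauche-/trans so a 15° discretization separates
    them cleanly. Returns the ensemble plus a ground-truth ledger.
    """
    for i, j, joint in coupled_pairs:
        joint = np.asarray(joint, dtype=float)
        if joint.shape != (2, 2) or not np.isclose(joint.sum(), 1.0) or np.any(joint < 0):
            raise ValueError(f"invalid joint table for pair ({i}, {j})")
        if not (0 <= i < n_residues and 0 <= j < n_residues) or i == j:
            raise ValueError(f"invalid residue pair ({i}, {j})")

    rng = np.random.default_rng(seed)
    sequence = sequence_letter * n_residues
    coupled_idx = {i for i, j, _ in coupled_pairs} | {j for i, j, _ in coupled_pairs}

    # sample well states: (n_frames, n_residues) in {0, 1}
    states = rng.integers(0, 2, size=(n_frames, n_residues))
    for i, j, joint in coupled_pairs:
        joint = np.asarray(joint, dtype=float)
        flat = rng.choice(4, size=n_frames, p=joint.ravel())
        states[:, i] = flat // 2
        states[:, j] = flat % 2

    frames = []
    for f in range(n_frames):
        chi = {
            r: {"chi1": wells[states[f, r]] + rng.normal(0.0, well_noise)}
            for r in range(n_residues)
        }
        frames.append(make_helix_domain(sequence, chi=chi))
    ensemble = Ensemble(frames)
    ledger = {
        "coupled_pairs": [(i, j) for i, j, _ in coupled_pairs],
        "wells": wells,
        "states": states,
        "sequence": sequence,
    }
    return ensemble, ledger


def make_pose_groups(
    seed_pose: Pose,
    n_groups: int,
    separation: float,
    spread: float,
    n_per_group: int,
    seed: int,
) -> tuple[list[Pose], list[int]]:
    """Planted pose families for clustering tests.

    Group centers are pure translations of the seed pose spaced ``separation``
    apart (pure translation of the mobile domain shifts tethered RMSD by
    exactly the translation norm); members add isotropic Gaussian translation
    jitter with total 3-D SD ``spread``. Returns poses and ground-truth labels.
    """
    if separation <= spread:
        raise ValueError("separation must exceed spread")
    rng = np.random.default_rng(seed)
    per_comp = spread / np.sqrt(3.0)
    poses: list[Pose] = []
    labels: list[int] = []
    for g in range(n_groups):
        center = np.array([g * separation, 0.0, 0.0])
        for m in range(n_per_group):
            jitter = rng.normal(0.0, per_comp, size=3)
            delta = RigidTransform(np.eye(3), center + jitter)
            poses.append(
                Pose(
                    id=f"g{g}m{m}",
                    transform=delta.compose(seed_pose.transform),
                    parent_id=seed_pose.id,
                    seed=seed,
                )
            )
            labels.append(g)
    return poses, labels
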