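"""Shared geometric primitives: dihedrals, Kabsch superposition, NeRF placement."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["dihedral", "kabsch", "superpose", "place_atom", "rmsd"]


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in [-180, 180)."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    return float(((ang + 180.0) % 360.0) - 180.0)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing ||R @ mobile.T + t - target||.

    Returns (R, t) such that mobile @ R.T + t best fits target in least squares.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValueError("kabsch requires two equal (n>=3, 3) arrays")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - R @ mc
    return R, t


def superpose(
    coords: np.ndarray,
    fit_mobile: np.ndarray,
    fit_target: np.ndarray,
) -> np.ndarray:
    """Transform `coords` by the Kabsch fit of fit_mobile onto fit_target."""
    R, t = kabsch(fit_mobile, fit_target)
    return coords @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (no-fit) RMSD between matched coordinate sets, Å."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place atom D from internal coordinates relative to A-B-C (NeRF).

    bond = |C-D| in Å, angle = B-C-D in degrees, dihedral = A-B-C-D in degrees.
    """
    ang = np.radians(angle)
    dih = -np.radians(dihedral_deg)  # sign matches the measured A-B-C-D dihedral
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
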