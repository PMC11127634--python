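"""Low-level rigid-body geometry helpers.

Conventions: coordinates in Å, angles in degrees at the public surface,
radians internally.  Rotation matrices act on column vectors; a frame is a
pair ``(axes, origin)`` with ``axes`` a right-handed orthonormal 3×3 matrix
whose *columns* are the frame's x, y, z axes expressed in lab coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def rotvec_to_matrix(r: np.ndarray) -> np.ndarray:
    return Rotation.from_rotvec(r).as_matrix()


def matrix_to_rotvec(m: np.ndarray) -> np.ndarray:
    return Rotation.from_matrix(m).as_rotvec()


def rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()


def kabsch(mobile: np.ndarray, target: np.ndarray, weights=None):
    """Optimal rigid superposition ``target ≈ R @ mobile + t``.

    Returns ``(R, t, rmsd)`` with a proper rotation (det = +1).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching (n, 3) arrays")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    cm = np.average(mobile, axis=0, weights=weights)
    ct = np.average(target, axis=0, weights=weights)
    rot, _ = Rotation.align_vectors(target - ct, mobile - cm, weights=weights)
    R = rot.as_matrix()
    t = ct - R @ cm
    # recompute the residual directly: the eigenvalue-based rssd loses
    # precision to cancellation for near-exact superpositions
    d = mobile @ R.T + t - target
    if weights is None:
        rmsd = np.sqrt((d**2).sum() / mobile.shape[0])
    else:
        w = np.asarray(weights, float)
        rmsd = np.sqrt(((d**2).sum(axis=1) * w).sum() / w.sum())
    return R, t, float(rmsd)


def dihedral_deg(p1, p2, p3, p4) -> float:
    """IUPAC-signed torsion angle in (−180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < 1e-10:
        raise ValueError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear point triple, torsion undefined")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(m @ n2, n1 @ n2))
    # map -180 exactly to +180 so the range is (-180, 180]
    if ang <= -180.0 + 1e-12:
        ang += 360.0
    return float(ang)


def angle_deg(p1, p2, p3) -> float:
    """Bond angle p1-p2-p3 in degrees."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    c = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement of atom d bonded to c.

    ``bond`` = |c-d| (Å), ``angle`` = b-c-d (deg), ``torsion`` = a-b-c-d (deg).
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def normalize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def is_rotation(m: np.ndarray, tol: float = 1e-9) -> bool:
    m = np.asarray(m, float)
    return (
        np.allclose(m.T @ m, np.eye(3), atol=tol)
        and abs(np.linalg.det(m) - 1.0) < tol
    )
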