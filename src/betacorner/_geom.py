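"""Low-level vector geometry shared across modules.

All coordinates are in Angstrom; all angles in degrees unless a function
name says otherwise.  Rotations are proper (det = +1) throughout.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


import math


def wrap_angle(deg: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    if isinstance(deg, (int, float)):
        wrapped = (deg + 180.0) % 360.0 - 180.0
        return 180.0 if wrapped == -180.0 else wrapped
    wrapped = np.mod(np.asarray(deg, dtype=float) + 180.0, 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.ndim(deg) == 0:
        return float(wrapped)
    return wrapped


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention.

    Looking down the p1->p2 bond, a clockwise rotation of the far bond
    relative to the near bond is positive.  Returned in (-180, 180].

    Scalar arithmetic throughout: this sits in the hot path of loop closure
    and torsion scans, where numpy dispatch on 3-vectors dominates runtime.
    """
    b0x, b0y, b0z = p0[0] - p1[0], p0[1] - p1[1], p0[2] - p1[2]
    b1x, b1y, b1z = p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2]
    b2x, b2y, b2z = p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2]
    n1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    b1x, b1y, b1z = b1x / n1, b1y / n1, b1z / n1
    d0 = b0x * b1x + b0y * b1y + b0z * b1z
    vx, vy, vz = b0x - d0 * b1x, b0y - d0 * b1y, b0z - d0 * b1z
    d2 = b2x * b1x + b2y * b1y + b2z * b1z
    wx, wy, wz = b2x - d2 * b1x, b2y - d2 * b1y, b2z - d2 * b1z
    x = vx * wx + vy * wy + vz * wz
    cx, cy, cz = b1y * vz - b1z * vy, b1z * vx - b1x * vz, b1x * vy - b1y * vx
    y = cx * wx + cy * wy + cz * wz
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def angle(p0, p1, p2) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    v1 = p0 - p1
    v2 = p2 - p1
    cosa = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosa, -1.0, 1.0))))


def place_atom(p1, p2, p3, bond: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Place atom X from three reference atoms (natural extension reference frame).

    X satisfies |X - p3| = bond, angle(X, p3, p2) = bond_angle and
    dihedral(p1, p2, p3, X) = torsion (degrees).
    """
    theta = math.radians(bond_angle)
    chi = math.radians(torsion)
    # local displacement in the frame of the p2->p3 bond
    d0 = -bond * math.cos(theta)
    d1 = bond * math.sin(theta) * math.cos(chi)
    d2 = bond * math.sin(theta) * math.sin(chi)
    bcx, bcy, bcz = p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2]
    nb = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / nb, bcy / nb, bcz / nb
    abx, aby, abz = p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2]
    nx, ny, nz = aby * bcz - abz * bcy, abz * bcx - abx * bcz, abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx, my, mz = ny * bcz - nz * bcy, nz * bcx - nx * bcz, nx * bcy - ny * bcx
    return np.array(
        [
            p3[0] + bcx * d0 + mx * d1 + nx * d2,
            p3[1] + bcy * d0 + my * d1 + ny * d2,
            p3[2] + bcz * d0 + mz * d1 + nz * d2,
        ]
    )


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> tuple[Rotation, float]:
    """Optimal proper rotation superposing centred q onto centred p.

    Returns the rotation and the RMSD (Angstrom) after superposition.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("coordinate sets must share shape (n, 3)")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    rot, _rssd = Rotation.align_vectors(pc, qc)
    # recompute the residual explicitly: the reported rssd loses precision
    # to cancellation and would report ~1e-8 for exact rigid copies
    resid = rot.apply(qc) - pc
    return rot, float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def rmsd_after_superposition(p: np.ndarray, q: np.ndarray) -> float:
    """Least RMSD of q onto p over all proper rotations and translations."""
    return kabsch_rotation(p, q)[1]


def pairwise_rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """All-against-all superposed RMSD for a frame stack of shape (m, n, 3).

    Vectorised Kabsch: cross-covariances for every frame pair are built with
    one einsum and decomposed with a batched SVD, with the usual determinant
    sign correction so only proper rotations are considered.
    """
    x = np.asarray(coords, dtype=float)
    m, n, _ = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    sq = np.einsum("fij,fij->f", xc, xc)  # per-frame sum of squared norms
    iu, ju = np.triu_indices(m, k=1)
    # covariance H = qc^T pc for each pair (q superposed onto p)
    h = np.einsum("pij,pik->pjk", xc[ju], xc[iu])
    u, s, _vt = np.linalg.svd(h)
    det = np.linalg.det(u) * np.linalg.det(_vt)
    s[:, -1] *= np.sign(det)
    trace = s.sum(axis=1)
    msd = np.maximum(sq[iu] + sq[ju] - 2.0 * trace, 0.0) / n
    out = np.zeros((m, m))
    out[iu, ju] = out[ju, iu] = np.sqrt(msd)
    return out


def fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through points (smallest-variance
    principal direction of the centred scatter)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points to fit a plane")
    centred = pts - pts.mean(axis=0)
    _u, _s, vt = np.linalg.svd(centred, full_matrices=False)
    return vt[-1]


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Largest-variance principal direction of a centred point scatter."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    centred = pts - pts.mean(axis=0)
    _u, _s, vt = np.linalg.svd(centred, full_matrices=False)
    return vt[0]


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    cosa = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosa, -1.0, 1.0))))
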