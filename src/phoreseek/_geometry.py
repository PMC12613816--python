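"""Rigid-body geometry helpers shared by the alignment and screening code."""

from __future__ import annotations

import numpy as np

from .errors import DegenerateAlignmentError


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point set ``Q`` onto ``P``.

    Returns ``(R, t, rmsd)`` such that ``R @ q + t`` best approximates the
    corresponding ``p`` in the least-squares sense, with ``R`` a proper
    rotation (det +1).  Raises :class:`DegenerateAlignmentError` when fewer
    than three points are given or the target points are collinear, in which
    case the rotation is under-determined.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise DegenerateAlignmentError(f"need >=3 correspondences, got {n}")
    Pc = P - P.mean(axis=0)
    if _collinear(Pc):
        raise DegenerateAlignmentError("matched points are collinear")
    Qc = Q - Q.mean(axis=0)
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = P.mean(axis=0) - R @ Q.mean(axis=0)
    diff = (Q @ R.T + t) - P
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return R, t, rmsd


def _collinear(centered: np.ndarray, tol: float = 1e-9) -> bool:
    s = np.linalg.svd(centered, compute_uv=False)
    scale = max(s[0], 1.0)
    return bool(s[1] < tol * scale)


def apply_rigid(points: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Apply rotation ``R`` then translation ``t`` to an (n, 3) array."""
    return np.asarray(points, dtype=float) @ np.asarray(R).T + np.asarray(t)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    M = rng.normal(size=(3, 3))
    Qm, Rm = np.linalg.qr(M)
    Qm = Qm @ np.diag(np.sign(np.diag(Rm)))
    if np.linalg.det(Qm) < 0:
        Qm[:, 0] = -Qm[:, 0]
    return Qm
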