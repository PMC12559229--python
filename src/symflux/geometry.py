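"""Rigid-body geometry kernel: superposition, rotations, RMSD.

All public functions take and return coordinates in Å and angles in
degrees; radians only appear internally. Rotations are proper (det +1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "kabsch_superpose",
    "rotate_about_axis",
    "paired_rmsd",
    "point_line_distance",
]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def _as_points(arr: np.ndarray, name: str) -> np.ndarray:
    pts = np.asarray(arr, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return pts


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Solves the orthogonal Procrustes problem for paired point clouds
    (Kabsch algorithm via SVD of the cross-covariance), restricted to
    proper rotations. Returns the optimal :class:`RigidTransform` and the
    RMSD after applying it.

    Parameters
    ----------
    mobile, reference:
        (n, 3) arrays of paired coordinates, n >= 3, not all collinear.
    """
    P = _as_points(mobile, "mobile")
    Q = _as_points(reference, "reference")
    if P.shape != Q.shape:
        raise ValueError(f"point counts differ: {P.shape[0]} vs {Q.shape[0]}")
    n = P.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 paired points")

    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    P0 = P - cp
    Q0 = Q - cq
    # Collinear (or coincident) clouds leave a rotational degree of freedom
    # undetermined; reject rather than return an arbitrary solution.
    if np.linalg.matrix_rank(P0, tol=1e-9 * max(1.0, np.abs(P0).max())) < 2:
        raise ValueError("degenerate (collinear) point cloud")

    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    transform = RigidTransform(R, t)
    fitted = paired_rmsd(transform.apply(P), Q)
    return transform, fitted


def rotate_about_axis(
    coords: np.ndarray,
    axis: np.ndarray,
    angle_deg: float,
    center: np.ndarray | None = None,
) -> np.ndarray:
    """Rotate points by ``angle_deg`` about the line through ``center`` along ``axis``."""
    pts = np.asarray(coords, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    _as_points(pts, "coords")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("rotation axis must be non-zero")
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / norm)
    out = rot.apply(pts - center) + center
    return out[0] if single else out


def paired_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD between two coordinate sets under a fixed correspondence (no fitting)."""
    P = _as_points(P, "P")
    Q = _as_points(Q, "Q")
    if P.shape != Q.shape:
        raise ValueError(f"point counts differ: {P.shape[0]} vs {Q.shape[0]}")
    if P.shape[0] == 0:
        raise ValueError("empty coordinate sets")
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def point_line_distance(
    points: np.ndarray, origin: np.ndarray, direction: np.ndarray
) -> np.ndarray:
    """Perpendicular distance of each point to the line (origin, direction)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("line direction must be non-zero")
    u = direction / norm
    rel = pts - origin
    proj = rel @ u
    perp = rel - np.outer(proj, u)
    return np.linalg.norm(perp, axis=1)
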