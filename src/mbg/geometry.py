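"""Rigid-body mathematics: transforms, Kabsch superposition, RMSD.

Rotations are proper (det = +1) throughout — biomolecules are chiral, so a
superposition must never reflect.  The Kabsch solver enforces this by
flipping the smallest singular direction when the cross-covariance
determinant is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "apply_transform",
    "compose",
    "kabsch_superpose",
    "rmsd",
    "DegeneracyError",
]

_ORTHO_TOL = 1e-9


class DegeneracyError(ValueError):
    """Point set too small or too degenerate for a unique superposition."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation: y = R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-6:
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation matrix is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis: np.ndarray, angle: float,
                        center: np.ndarray | None = None,
                        translation: np.ndarray | None = None) -> "RigidTransform":
        """Rotation by ``angle`` (radians) about ``axis`` through ``center``,
        followed by an optional extra translation."""
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("zero rotation axis")
        k = axis / n
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        if center is not None:
            c = np.asarray(center, dtype=float)
            t = t + c - R @ c
        return cls(R, t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return apply_transform(self, coords)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians, in [0, pi]."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (np.max(np.abs(self.rotation - np.eye(3))) < tol
                and np.max(np.abs(self.translation)) < tol)


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_points: int


def apply_transform(transform: RigidTransform, coords: np.ndarray) -> np.ndarray:
    """y = R x + t applied row-wise; accepts (3,) or (n, 3)."""
    coords = np.asarray(coords, dtype=float)
    return coords @ transform.rotation.T + transform.translation


def compose(t1: RigidTransform, t2: RigidTransform) -> RigidTransform:
    """The transform applying ``t2`` first, then ``t1``."""
    return RigidTransform(t1.rotation @ t2.rotation,
                          t1.rotation @ t2.translation + t1.translation)


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square deviation between paired coordinates; no
    superposition is performed."""
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"coordinate count mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] < 1:
        raise ValueError("need at least one point")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(mobile_coords: np.ndarray,
                     target_coords: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation mapping
    ``mobile_coords`` onto ``target_coords`` (Kabsch, SVD form).

    Raises :class:`DegeneracyError` for n < 3 or a rank-deficient point set
    (all points collinear), where the rotation is not unique.
    """
    P = np.asarray(mobile_coords, dtype=float)
    Q = np.asarray(target_coords, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"coordinate count mismatch: {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise DegeneracyError("need at least 3 points for a superposition")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 => points (nearly) collinear => rotation about the line is free
    if S[1] <= 1e-8 * max(S[0], 1.0):
        raise DegeneracyError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    tr = RigidTransform(R, t)
    return SuperpositionResult(tr, rmsd(apply_transform(tr, P), Q), n)
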