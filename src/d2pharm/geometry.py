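"""Rigid-body geometry: least-squares superposition, transforms, angles.

All coordinates are Cartesian, in angstroms, as ``(n, 3)`` float arrays.
A rigid transform is represented by a :class:`RigidTransform` holding a
proper rotation matrix ``R`` and translation ``t``; points transform as
``x' = x @ R.T + t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class UnderdeterminedError(ValueError):
    """Raised when a superposition is requested with too few point pairs."""


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray  # (3, 3) proper rotation
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_euler(degrees_xyz, translation) -> "RigidTransform":
        ax, ay, az = np.deg2rad(np.asarray(degrees_xyz, dtype=float))
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return RigidTransform(rz @ ry @ rx, np.asarray(translation, dtype=float))


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalise a zero vector")
    return v / n


def superpose(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition (Kabsch) of ``source`` onto ``target``.

    Returns the proper rigid transform minimising
    ``sum_i |R s_i + t - q_i|^2``. Requires at least three point pairs;
    fewer leave the rotation underdetermined.
    """
    P = np.asarray(source, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("superpose expects matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise UnderdeterminedError("underdetermined superposition: need >= 3 pairs")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return RigidTransform(R, t)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex ``b`` of the triple (a, b, c), in degrees."""
    v1 = np.asarray(a, dtype=float) - b
    v2 = np.asarray(c, dtype=float) - b
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("degenerate geometry: coincident points")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def vector_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cosang = np.clip(np.dot(unit(u), unit(v)), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane through ``points`` (SVD)."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return unit(vt[2])
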