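"""Proper rigid transforms (rotation + translation, no scale, no reflection).

The convention throughout the package is rotation-first: ``x' = R @ x + t``.
Serialization is a 4x4 homogeneous matrix in row-major order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x' = R @ x + t`` in millimetres.

    ``rotation`` must be orthonormal with determinant +1 (reflections are
    rejected at construction: a reflection between two scans of the same
    physical bone is always an error).
    """

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValidationError(f"rotation must be 3x3, got {R.shape}")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValidationError("non-finite transform entries")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
            raise ValidationError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValidationError("reflection (det = -1) is not a rigid motion")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, axis, angle_rad: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValidationError("zero rotation axis")
        k = axis / n
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=float))

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"expected 4x4 homogeneous matrix, got {m.shape}")
        return cls(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array (or a single 3-vector) of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first,
        then ``self``: ``(self @ other)(x) = self(other(x))``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_rad(self) -> float:
        """Magnitude of the rotation, in radians.

        Uses atan2 of the skew norm against the trace, which stays accurate
        near zero where arccos of the trace loses ~8 digits.
        """
        R = self.rotation
        skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        s = np.linalg.norm(skew) / 2.0
        c = (np.trace(R) - 1.0) / 2.0
        return float(np.arctan2(s, c))

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - other.rotation).max() <= tol
            and np.abs(self.translation - other.translation).max() <= tol
        )
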