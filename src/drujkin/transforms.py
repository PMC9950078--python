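"""Rigid 6-DOF transforms with an explicit rotation center.

All world coordinates in this package are millimetres in *array order*
``(z, y, x)``: component 0 is the longitudinal (craniocaudal) axis, matching
the axis-0 convention of the volume grids.  A :class:`RigidTransform` maps a
point ``p`` to ``R @ (p - c) + c + t`` where ``c`` is the rotation center.
The homogeneous 4x4 matrix therefore carries an effective translation
``t + c - R @ c``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RigidTransform",
    "rotation_about_axis",
    "random_rigid_transform",
]

_ORTHO_TOL = 1e-9


class InvalidRotationError(ValueError):
    """Raised when a 3x3 matrix is not a proper rotation."""


def _check_rotation(R: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidRotationError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise InvalidRotationError("matrix is not orthonormal (R^T R != I)")
    if not np.isclose(np.linalg.det(R), 1.0, atol=tol):
        raise InvalidRotationError("matrix has det != +1 (improper rotation)")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: rotation about ``center`` followed by translation.

    Parameters
    ----------
    rotation:
        3x3 proper rotation matrix acting on (z, y, x) world vectors.
    translation:
        Translation in mm, (z, y, x).
    center:
        Rotation center in mm, (z, y, x).  Changing the center changes the
        (rotation, translation) split but not the mapping itself.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = _check_rotation(self.rotation)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        c = np.asarray(self.center, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "center", c)

    # -- construction ------------------------------------------------------
    @classmethod
    def identity(cls, center: Sequence[float] | None = None) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), np.zeros(3) if center is None else center)

    @classmethod
    def from_matrix(
        cls, matrix: np.ndarray, center: Sequence[float] | None = None
    ) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix, re-expressed about ``center``."""
        M = np.asarray(matrix, dtype=float)
        if M.shape != (4, 4):
            raise ValueError(f"expected 4x4 homogeneous matrix, got {M.shape}")
        R = _check_rotation(M[:3, :3])
        t0 = M[:3, 3]
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        # t0 = t + c - R c  =>  t = t0 - c + R c
        t = t0 - c + R @ c
        return cls(R, t, c)

    # -- core --------------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        """4x4 row-major homogeneous matrix (center folded into translation)."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation + self.center - self.rotation @ self.center
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array (or single point) of (z, y, x) mm."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        out = (p - self.center) @ self.rotation.T + self.center + self.translation
        return out[0] if single else out

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        v = np.atleast_2d(np.asarray(vectors, dtype=float))
        out = v @ self.rotation.T
        return out[0] if np.asarray(vectors).ndim == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first), about self.center."""
        return RigidTransform.from_matrix(self.matrix @ other.matrix, self.center)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix), self.center)

    def with_center(self, center: Sequence[float]) -> "RigidTransform":
        """Same mapping, re-expressed about a different rotation center."""
        return RigidTransform.from_matrix(self.matrix, center)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "center_mm": self.center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls.from_matrix(np.asarray(d["matrix"]), d.get("center_mm"))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def isclose(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))


def rotation_about_axis(
    point: Sequence[float], direction: Sequence[float], angle_deg: float
) -> RigidTransform:
    """Rotation by ``angle_deg`` about the axis through ``point`` along ``direction``.

    Rodrigues' formula; ``direction`` need not be unit length.
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("axis direction must be nonzero")
    k = d / n
    a = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
    return RigidTransform(R, np.zeros(3), np.asarray(point, dtype=float))


def random_rigid_transform(
    rng: np.random.Generator,
    max_translation_mm: float,
    max_rotation_deg: float,
    center: Sequence[float] | None = None,
) -> RigidTransform:
    """Uniform random small rigid transform for perturbation / recovery studies.

    Translation components uniform in ``[-max_t, max_t]``; rotation about a
    uniformly random axis by an angle uniform in ``[-max_r, max_r]``.
    """
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = rng.uniform(-max_rotation_deg, max_rotation_deg)
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    rot = rotation_about_axis(c, axis, ang)
    return RigidTransform(rot.rotation, t, c)
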