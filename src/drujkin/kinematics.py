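"""Relative-pose error decomposition and box-plot summaries.

The methodological error of one registered frame is the apparent motion of
the radius relative to the ulna: with both bones rigidly fixed to each other
in every experiment, the relative transform ``T_ulna⁻¹ ∘ T_radius`` is the
identity for perfect registration and anything else is error.  Each frame is
condensed to two scalars: the Euclidean norm of the translation vector (mm)
and the Euclidean norm of the Tait-Bryan YXZ angle triple (degrees).

Angles use the intrinsic Y-X'-Z'' factorization ``R = Ry(θy)·Rx(θx)·Rz(θz)``
in conventional (x, y, z) basis; rotation matrices carried by
:class:`~drujkin.transforms.RigidTransform` act on (z, y, x) world vectors
and are permuted internally.  Per-condition summaries follow the Tukey
box-plot convention: median, quartiles by linear interpolation, whiskers at
the most extreme samples within 1.5 IQR of the box, the rest outliers.
Accuracy of a condition is its median error; precision is the spread (IQR).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .transforms import RigidTransform, _check_rotation

__all__ = [
    "ErrorSample",
    "ErrorSummary",
    "relative_transform",
    "translation_magnitude",
    "rotation_magnitude",
    "tait_bryan_yxz",
    "compose_yxz",
    "geodesic_angle",
    "lever_arm_error",
    "error_sample",
    "summarize",
]

# permutation between (z, y, x) storage order and conventional (x, y, z)
_P = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])

GIMBAL_EPS = 1e-8


@dataclass(frozen=True)
class ErrorSample:
    """Per-frame registration error, condensed to vector magnitudes."""

    frame: int
    translation_mm: float
    rotation_deg: float
    angles_deg: Tuple[float, float, float]  # (θy, θx, θz)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.translation_mm < 0 or self.rotation_deg < 0:
            raise ValueError("error magnitudes must be non-negative")
        mag = float(np.linalg.norm(self.angles_deg))
        if abs(mag - self.rotation_deg) > 1e-9:
            raise ValueError("rotation magnitude must equal ‖angle triple‖")


@dataclass(frozen=True)
class ErrorSummary:
    """Tukey box-plot statistics of one error sample per condition."""

    label: str
    values: np.ndarray
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("quartiles must satisfy Q1 <= median <= Q3")


def relative_transform(
    t_radius: RigidTransform,
    t_ulna: RigidTransform,
    center: Sequence[float] | None = None,
) -> RigidTransform:
    """Apparent motion of the radius in the ulna frame: ``T_ulna⁻¹ ∘ T_radius``.

    Expressed about ``center`` (default: the radius transform's rotation
    center, typically the registration-mesh centroid, where the relative
    translation is measured).
    """
    c = t_radius.center if center is None else np.asarray(center, dtype=float)
    M = np.linalg.inv(t_ulna.matrix) @ t_radius.matrix
    return RigidTransform.from_matrix(M, c)


def translation_magnitude(transform: RigidTransform) -> float:
    """Euclidean norm of the translation component, mm."""
    return float(np.linalg.norm(transform.translation))


def rotation_magnitude(angles_deg: Sequence[float]) -> float:
    """Euclidean norm of a Tait-Bryan angle triple, degrees."""
    return float(np.linalg.norm(np.asarray(angles_deg, dtype=float)))


def tait_bryan_yxz(
    R: np.ndarray,
    convention: str = "intrinsic",
    return_degenerate: bool = False,
    basis: str = "xyz",
):
    """Decompose a rotation matrix into Tait-Bryan YXZ angles (degrees).

    ``intrinsic`` (default) reads ``R = Ry(θy)·Rx(θx)·Rz(θz)`` — rotations
    about the successively rotated Y, X', Z'' axes.  ``extrinsic`` applies
    Y, X, Z about fixed axes, i.e. ``R = Rz(θz)·Rx(θx)·Ry(θy)``.  θx lies in
    [-90°, 90°].  Near gimbal lock (|cos θx| < 1e-8) θz is set to 0, θy
    absorbs the remaining yaw, and the degeneracy flag is set.

    ``basis='zyx'`` accepts a matrix acting on (z, y, x)-ordered vectors, the
    storage order of :class:`RigidTransform` rotations.
    """
    R = _check_rotation(np.asarray(R, dtype=float))
    if basis == "zyx":
        R = _P @ R @ _P
    elif basis != "xyz":
        raise ValueError(f"unknown basis {basis!r}")
    if convention == "extrinsic":
        # Rz·Rx·Ry is the transpose-of-inverse relation: decompose Rᵀ with
        # the intrinsic formulas and negate
        ay, ax, az, deg = _yxz_intrinsic(R.T)
        out = (-ay, -ax, -az)
    elif convention == "intrinsic":
        ay, ax, az, deg = _yxz_intrinsic(R)
        out = (ay, ax, az)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if return_degenerate:
        return out, deg
    return out


def _yxz_intrinsic(R: np.ndarray) -> Tuple[float, float, float, bool]:
    # R = Ry·Rx·Rz:
    #   R[1,2] = -sin θx ; R[0,2] = sin θy cos θx ; R[2,2] = cos θy cos θx
    #   R[1,0] = cos θx sin θz ; R[1,1] = cos θx cos θz
    sx = np.clip(-R[1, 2], -1.0, 1.0)
    ax = np.arcsin(sx)
    cx = np.cos(ax)
    if abs(cx) < GIMBAL_EPS:
        # gimbal lock: with θz := 0, R[0,0] = cos θy, R[2,0] = -sin θy
        ay = np.arctan2(-R[2, 0], R[0, 0])
        return float(np.degrees(ay)), float(np.degrees(ax)), 0.0, True
    ay = np.arctan2(R[0, 2], R[2, 2])
    az = np.arctan2(R[1, 0], R[1, 1])
    return float(np.degrees(ay)), float(np.degrees(ax)), float(np.degrees(az)), False


def compose_yxz(
    angles_deg: Sequence[float], convention: str = "intrinsic"
) -> np.ndarray:
    """Inverse of :func:`tait_bryan_yxz`: angles (θy, θx, θz) → matrix (xyz basis)."""
    ay, ax, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    cz, sz = np.cos(az), np.sin(az)
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    if convention == "intrinsic":
        return Ry @ Rx @ Rz
    if convention == "extrinsic":
        return Rz @ Rx @ Ry
    raise ValueError(f"unknown convention {convention!r}")


def geodesic_angle(R: np.ndarray) -> float:
    """Single-axis rotation angle of R in degrees (diagnostic only).

    Reported alongside the Euler-norm magnitude for diagnostics; all
    statistics in this package use the Euler norm.
    """
    R = _check_rotation(np.asarray(R, dtype=float))
    return float(np.degrees(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0))))


def lever_arm_error(rotation_deg: float, bone_length_mm: float) -> float:
    """Translation at the far end of a bone implied by a rotation at the near end.

    ``tan(rotation) * bone_length``: a 1° rotational registration error over
    an average male radius (265 mm) displaces the far end by ≈ 4.6 mm, which
    is why small angular errors matter clinically.
    """
    if not abs(rotation_deg) < 90.0:
        raise ValueError("rotation must satisfy |rotation| < 90 degrees")
    if bone_length_mm <= 0:
        raise ValueError("bone length must be > 0")
    return float(np.tan(np.deg2rad(rotation_deg)) * bone_length_mm)


def error_sample(
    frame: int,
    t_radius: RigidTransform,
    t_ulna: RigidTransform,
    center: Sequence[float] | None = None,
    convention: str = "intrinsic",
) -> ErrorSample:
    """Condense one frame's two bone transforms into an :class:`ErrorSample`."""
    rel = relative_transform(t_radius, t_ulna, center)
    angles, degenerate = tait_bryan_yxz(
        rel.rotation, convention=convention, return_degenerate=True, basis="zyx"
    )
    return ErrorSample(
        frame=frame,
        translation_mm=translation_magnitude(rel),
        rotation_deg=rotation_magnitude(angles),
        angles_deg=tuple(angles),
        degenerate=degenerate,
    )


def summarize(values: Sequence[float] | Sequence[ErrorSample], label: str = "") -> ErrorSummary:
    """Tukey box-plot summary of an error sample.

    Quartiles use linear interpolation between order statistics (the numpy
    default); whiskers sit at the most extreme samples inside
    [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; samples outside are outliers.
    """
    vals = [
        v.translation_mm if isinstance(v, ErrorSample) else float(v) for v in values
    ]
    if len(vals) == 0:
        raise ValueError("cannot summarize an empty sample")
    x = np.asarray(vals, dtype=float)
    q1, med, q3 = np.percentile(x, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_bound) & (x <= hi_bound)]
    outliers = x[(x < lo_bound) | (x > hi_bound)]
    return ErrorSummary(
        label=label,
        values=x,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )
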