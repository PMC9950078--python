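"""Grey-value rigid registration of segmented bone models to target frames.

A double-contour point set brackets the cortical boundary: every mesh vertex
spawns an outer point (vertex + δ·normal, in soft tissue) and an inner point
(vertex − δ·normal, in cortex).  Source grey values sampled at those points
form a fixed reference profile; a candidate rigid transform is scored by the
normalized cross-correlation (NCC) between that profile and the target grey
values at the transformed point locations.  NCC is invariant to positive
affine intensity rescaling, which absorbs scan-to-scan exposure differences.

The 6-parameter local search (3 translations mm, 3 rotations ° about a
configurable rotation center, scaled 1 mm ≡ 1°) uses Powell's derivative-free
method and assumes a rough initial alignment — the counterpart of the manual
pre-registration an operator performs.

Limited axial coverage is emulated by clipping the radius and ulna meshes at
a single plane derived from a bounding box on the radius, before the double
contour is built; target volumes are never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage, optimize

from .segmentation import SurfaceMesh
from .transforms import RigidTransform, rotation_about_axis
from .volume import Volume

__all__ = [
    "DoubleContour",
    "RegistrationOptions",
    "RegistrationResult",
    "DegenerateOverlapError",
    "make_double_contour",
    "similarity",
    "register",
    "clip_mesh_to_coverage",
]


class DegenerateOverlapError(RuntimeError):
    """Too few contour points fall inside the target volume to score."""


class OutOfBoundsError(ValueError):
    """Contour points fall outside the source volume at sampling time."""


@dataclass(frozen=True)
class DoubleContour:
    """Paired offset points with their reference grey values.

    ``points[:n]`` are the outer points (soft-tissue side) and ``points[n:]``
    the inner points (cortical side) for a mesh with n vertices.
    """

    points: np.ndarray  # (2n, 3) mm
    values: np.ndarray  # (2n,)
    offset_mm: float

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float).reshape(-1, 3)
        v = np.asarray(self.values, dtype=float).reshape(-1)
        if len(p) != len(v):
            raise ValueError("one reference value per point required")
        if len(p) % 2:
            raise ValueError("double contour must pair outer/inner points")
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def outer_values(self) -> np.ndarray:
        return self.values[: len(self.values) // 2]

    @property
    def inner_values(self) -> np.ndarray:
        return self.values[len(self.values) // 2 :]


@dataclass(frozen=True)
class RegistrationOptions:
    """Optimizer settings; tolerances in the shared mm/degree parameter scale.

    ``score_tol`` must sit well below the curvature of the NCC surface along
    its shallowest mode (rotation about a bone's long axis moves the score by
    ~1e-5 per 0.1 deg); a loose value stalls that mode long before the
    parameter tolerance is reached.
    """

    param_tol: float = 1e-4
    score_tol: float = 1e-9
    max_iterations: int = 500
    max_out_fraction: float = 0.5
    center: Tuple[float, float, float] | None = None  # default: contour centroid
    max_points: int | None = None  # optimize on an even subsample of the contour
    # Target interpolation order during optimization.  Cubic (3) suppresses
    # the grid-snapping bias of trilinear sampling — interpolation errors of
    # the reference and target profiles correlate whenever a candidate pose
    # aligns the grids, pulling the optimum toward grid-aligned poses.
    interpolation_order: int = 3


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    score: float
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("similarity score must be finite")
        if self.iterations < 1:
            raise ValueError("iteration count must be >= 1")


def make_double_contour(mesh: SurfaceMesh, source: Volume, offset_mm: float) -> DoubleContour:
    """Sample the source at vertices offset ±δ along the outward normals.

    Reference values use trilinear interpolation.  For a bright (cortical)
    object the inner points land in cortex and the outer points in the darker
    surroundings, so ``mean(outer) < mean(inner)``.
    """
    if offset_mm <= 0:
        raise ValueError("double-contour offset must be > 0")
    outer = mesh.vertices + offset_mm * mesh.normals
    inner = mesh.vertices - offset_mm * mesh.normals
    points = np.concatenate([outer, inner], axis=0)
    inside = source.contains(points)
    n_out = int((~inside).sum())
    if n_out:
        raise OutOfBoundsError(
            f"{n_out} double-contour point(s) outside the source volume"
        )
    values = source.sample(points)
    return DoubleContour(points=points, values=values, offset_mm=float(offset_mm))


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def similarity(
    dc: DoubleContour,
    target: Volume,
    transform: RigidTransform,
    return_out_fraction: bool = False,
):
    """NCC between the reference profile and the target at transformed points.

    Points mapping outside the target are excluded; if more than half do, the
    overlap is considered degenerate and an error is raised (the optimizer
    cannot recover from a start that far off — re-initialize).
    """
    pts = transform.apply(dc.points)
    inside = target.contains(pts)
    out_frac = 1.0 - float(inside.mean())
    if out_frac > 0.5:
        raise DegenerateOverlapError(
            f"{out_frac:.0%} of contour points map outside the target"
        )
    score = _ncc(dc.values[inside], target.sample(pts[inside]))
    if return_out_fraction:
        return score, out_frac
    return score


def _params_to_transform(
    p: np.ndarray, init: RigidTransform, center: np.ndarray
) -> RigidTransform:
    """[tz, ty, tx, r0, r1, r2] (mm, deg) as a perturbation composed with init."""
    delta = RigidTransform.identity(center)
    for axis_idx in range(3):
        axis = np.zeros(3)
        axis[axis_idx] = 1.0
        delta = delta @ rotation_about_axis(center, axis, p[3 + axis_idx])
    delta = RigidTransform(delta.rotation, p[:3], center)
    return delta @ init


def register(
    dc: DoubleContour,
    target: Volume,
    init: RigidTransform,
    opts: RegistrationOptions | None = None,
) -> RegistrationResult:
    """Maximize NCC over the 6 rigid parameters, starting from ``init``.

    Powell's method on the shared mm/degree scale; converged when the
    parameter step falls below ``param_tol`` or the score improves by less
    than ``score_tol``.  Raises :class:`DegenerateOverlapError` if the
    initialization has insufficient overlap — mirror of a failed manual
    pre-registration.
    """
    opts = opts or RegistrationOptions()
    center = np.asarray(opts.center, float) if opts.center is not None else dc.centroid
    similarity(dc, target, init)  # validates overlap at init
    points, values = dc.points, dc.values
    if opts.max_points is not None and opts.max_points < len(points):
        # even stride over the point list keeps outer/inner pairing balanced
        idx = np.linspace(0, len(points) - 1, opts.max_points).astype(int)
        points, values = points[idx], values[idx]
    order = opts.interpolation_order
    if order > 1:  # prefilter once; per-evaluation sampling skips it
        coeff = ndimage.spline_filter(
            target.data.astype(float, copy=False), order=order
        )
    else:
        coeff = target.data.astype(float, copy=False)
    origin = np.asarray(target.origin)
    spacing = np.asarray(target.spacing)
    upper = np.asarray(target.shape) - 1

    def objective(p: np.ndarray) -> float:
        T = _params_to_transform(p, init, center)
        idx = (T.apply(points) - origin) / spacing
        inside = np.all((idx >= 0) & (idx <= upper), axis=1)
        if inside.mean() < 1.0 - opts.max_out_fraction:
            return 1.0  # worst possible (-score); discourages drifting out
        sampled = ndimage.map_coordinates(
            coeff, idx[inside].T, order=order, prefilter=False, mode="constant"
        )
        return -_ncc(values[inside], sampled)

    res = optimize.minimize(
        objective,
        np.zeros(6),
        method="Powell",
        options={
            "xtol": opts.param_tol,
            "ftol": opts.score_tol,
            "maxiter": opts.max_iterations,
        },
    )
    transform = _params_to_transform(res.x, init, center)
    return RegistrationResult(
        transform=transform,
        score=-float(res.fun),
        iterations=max(1, int(res.get("nit", 1))),
        converged=bool(res.success),
    )


def clip_mesh_to_coverage(
    radius_mesh: SurfaceMesh, ulna_mesh: SurfaceMesh, coverage_mm: float
) -> Tuple[SurfaceMesh, SurfaceMesh]:
    """Clip both meshes to a simulated axial coverage.

    A bounding box of height ``coverage_mm`` is anchored at the distal
    (maximal-z) extent of the *radius*; the box's bottom plane clips both
    meshes: vertices below the plane are removed together with their incident
    faces (open boundary allowed).  Surviving vertex coordinates are
    untouched.
    """
    if coverage_mm <= 0:
        raise ValueError("coverage must be > 0")
    if len(radius_mesh) == 0:
        raise ValueError("radius mesh is empty")
    z_plane = float(radius_mesh.vertices[:, 0].max()) - coverage_mm
    clipped_radius = _clip_mesh(radius_mesh, z_plane)
    if len(clipped_radius) == 0 or len(clipped_radius.faces) == 0:
        raise ValueError("coverage too small: radius mesh emptied by clipping")
    return clipped_radius, _clip_mesh(ulna_mesh, z_plane)


def _clip_mesh(mesh: SurfaceMesh, z_plane: float) -> SurfaceMesh:
    keep = mesh.vertices[:, 0] >= z_plane
    if keep.all():
        return mesh
    new_index = -np.ones(len(mesh), dtype=np.int64)
    new_index[keep] = np.arange(int(keep.sum()))
    faces_kept = mesh.faces[keep[mesh.faces].all(axis=1)]
    return SurfaceMesh(
        vertices=mesh.vertices[keep],
        faces=new_index[faces_kept],
        normals=mesh.normals[keep],
    )
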