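"""End-to-end experiments: simulate → segment → register → errors → stats.

Each experiment sweeps one acquisition factor over its condition levels —
tube current–time product (mAs) for the SNR study, simulated axial coverage
(mm) for the Z-coverage study, angular velocity (°/s) for the motion study —
and measures, per condition, the apparent motion of the radius relative to
the ulna across all target frames.  Both bones are static relative to each
other in the simulation, so these apparent motions are pure methodological
error.

A single integer seed drives every random draw (noise fields, registration
initialization jitter); per-condition and per-frame seeds are derived
through `numpy.random.SeedSequence` spawning, so reruns are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import phantom as ph
from .kinematics import ErrorSample, ErrorSummary, error_sample, summarize
from .registration import (
    RegistrationOptions,
    clip_mesh_to_coverage,
    make_double_contour,
    register,
)
from .segmentation import LevelSetParams, SurfaceMesh, default_thresholds, segment_bone
from .stats import RegressionResult, StatResult, run_comparison_table, velocity_regression
from .transforms import RigidTransform, random_rigid_transform
from .volume import Volume

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "make_report"]

logger = logging.getLogger(__name__)

_DESIGN_LEVELS: Dict[str, List[float]] = {
    "snr": [30.0, 75.0, 120.0],
    "zcoverage": [40.0, 57.0, 80.0, 160.0],
    "motion": [1.0, 2.5, 5.0, 10.0, 15.0, 20.0, 30.0],
}
_DESIGN_FRAMES = {"snr": 33, "zcoverage": 9, "motion": 33}


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one experiment sweep.

    ``levels`` defaults to the study design: mAs {30, 75, 120}, coverage
    {40, 57, 80, 160} mm, angular velocity {1, 2.5, 5, 10, 15, 20, 30} °/s.
    ``frames`` defaults to 33 targets per condition (9 for Z-coverage).
    """

    experiment: str
    levels: Tuple[float, ...] = ()
    frames: Optional[int] = None
    grid_spacing: Tuple[float, float, float] = (1.2, 1.2, 1.2)
    scene: ph.SceneConfig = field(default_factory=ph.SceneConfig)
    sigma_ref: float = 25.0
    mas_ref: float = 120.0
    exposure_window_s: float = 0.25
    contour_offset_mm: Optional[float] = None  # default: in-plane spacing
    smooth_width_mm: Optional[float] = None  # reconstruction PSF; default 2 voxels
    init_jitter_mm: float = 2.0
    init_jitter_deg: float = 2.0
    registration: RegistrationOptions = field(default_factory=RegistrationOptions)
    level_set: LevelSetParams = field(default_factory=LevelSetParams)
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.experiment not in _DESIGN_LEVELS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        levels = tuple(float(v) for v in self.levels) or tuple(
            _DESIGN_LEVELS[self.experiment]
        )
        if list(levels) != sorted(levels) or len(levels) == 0:
            raise ValueError("condition levels must be nonempty and sorted")
        object.__setattr__(self, "levels", levels)
        if self.frames is None:
            object.__setattr__(self, "frames", _DESIGN_FRAMES[self.experiment])
        if self.frames < 1:
            raise ValueError("frames must be >= 1")


@dataclass(frozen=True)
class ConditionResult:
    label: str
    level: float
    samples: List[ErrorSample]
    translation: ErrorSummary
    rotation: ErrorSummary
    transforms: List[Tuple[RigidTransform, RigidTransform]]  # (radius, ulna)


@dataclass(frozen=True)
class ExperimentResult:
    config: ExperimentConfig
    conditions: List[ConditionResult]
    stats: List[StatResult]
    regressions: Optional[Dict[str, Dict[str, RegressionResult]]]
    manifest: Dict

    def samples_frame(self) -> pd.DataFrame:
        rows = []
        for cond in self.conditions:
            for s in cond.samples:
                ry, rx, rz = s.angles_deg
                rows.append(
                    dict(condition=cond.label, frame=s.frame,
                         t_mag_mm=s.translation_mm, r_mag_deg=s.rotation_deg,
                         ry=ry, rx=rx, rz=rz)
                )
        return pd.DataFrame(rows)

    def stats_frame(self) -> pd.DataFrame:
        rows = [
            dict(design=self.config.experiment, pair=f"{r.pair[0]}-{r.pair[1]}",
                 response=r.response or "", test=r.test, statistic=r.statistic,
                 p=r.p_value, significant=r.significant)
            for r in self.stats
        ]
        return pd.DataFrame(rows)


def _condition_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] % (2**31))


def _bone_seed_voxel(scene: ph.PhantomScene, bone: ph.BoneSpec, vol: Volume) -> Tuple[int, int, int]:
    """A voxel safely inside the bone's cortical shell at mid-shaft.

    Picks the side of the shaft facing away from the other bone so the seed
    cannot fall into the inter-bone gap.
    """
    a = np.asarray(bone.shaft_start, float)
    b = np.asarray(bone.shaft_end, float)
    mid = 0.5 * (a + b)
    other = scene.ulna if bone is scene.radius else scene.radius
    away = np.sign(a[1] - np.asarray(other.shaft_start)[1]) or -1.0
    mid[1] += away * (bone.shaft_semiaxes[0] - bone.cortical_thickness / 2.0)
    idx = np.round(vol.index_from_world(mid)[0]).astype(int)
    return tuple(int(i) for i in np.clip(idx, 0, np.asarray(vol.shape) - 1))


def _protocol_for(cfg: ExperimentConfig, level: float, seed: int) -> ph.AcquisitionProtocol:
    kw = dict(
        sigma_ref=cfg.sigma_ref, mas_ref=cfg.mas_ref, frames=cfg.frames,
        exposure_window=cfg.exposure_window_s, seed=seed,
    )
    if cfg.experiment == "snr":
        kw["mas"] = level
    elif cfg.experiment == "motion":
        kw["omega_deg_s"] = level
    else:
        kw["z_coverage_mm"] = level
    return ph.AcquisitionProtocol.for_experiment(cfg.experiment, **kw)


def _condition_label(experiment: str, level: float) -> str:
    unit = {"snr": "mAs", "zcoverage": "mm", "motion": "deg/s"}[experiment]
    return f"{level:g} {unit}"


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run one full experiment sweep and (optionally) write its outputs.

    Per condition: simulate source + targets, segment radius and ulna from
    the source, clip both meshes to the condition's coverage (Z-coverage
    design only), build double contours, register both bones to every
    target starting from the ground-truth pose perturbed by a bounded random
    jitter (the stand-in for manual pre-registration), and condense each
    frame to translation/rotation error magnitudes.  Matching the scanning
    design, the SNR experiment re-acquires and re-segments its source at
    every exposure level, while the motion and Z-coverage experiments share
    one source scan and one segmentation (and, for Z-coverage, one target
    series) across conditions.  Afterwards the adjacent-pair comparison
    table runs, plus the velocity regression for the motion design.

    A condition whose stage errors out is aborted and logged; the remaining
    conditions complete and the failure is recorded in the manifest.
    """
    scene = ph.build_default_scene(cfg.scene)
    sweep = None
    if cfg.experiment == "motion":
        # worst-case rotation reached during the sweep (plus half a window)
        sweep = max(cfg.levels) * cfg.exposure_window_s * (cfg.frames + 0.5)
    grid = ph.fit_grid(
        scene, cfg.grid_spacing,
        cover_rotation=(cfg.experiment == "motion"), sweep_deg=sweep,
    )
    delta = cfg.contour_offset_mm or float(cfg.grid_spacing[1])
    thresholds = default_thresholds(scene)
    conditions: List[ConditionResult] = []
    # The scanning design acquires one dedicated source scan for the motion
    # and Z-coverage experiments (conditions differ only in their targets or
    # in mesh clipping); only the SNR experiment re-acquires the source at
    # each exposure level.  Shared stages are therefore computed once.
    shared_meshes: Optional[Tuple[SurfaceMesh, SurfaceMesh]] = None
    shared_sim: Optional[ph.SimulatedExperiment] = None
    failures: Dict[str, str] = {}
    for j, level in enumerate(cfg.levels):
        label = _condition_label(cfg.experiment, level)
        cond_seed = _condition_seed(cfg.seed, 0 if cfg.experiment == "zcoverage" else j)
        t0 = time.perf_counter()
        try:
            protocol = _protocol_for(cfg, level, cond_seed)
            if cfg.experiment == "zcoverage" and shared_sim is not None:
                sim = shared_sim  # one source + one target series; clipping varies
            else:
                sim = ph.simulate_experiment(
                    scene, protocol, cfg.experiment, grid,
                    smooth_width=cfg.smooth_width_mm,
                )
            t_sim = time.perf_counter()
            if cfg.experiment == "snr" or shared_meshes is None:
                radius_mesh = segment_bone(
                    sim.source, _bone_seed_voxel(scene, scene.radius, sim.source),
                    thresholds, cfg.level_set,
                )
                ulna_mesh = segment_bone(
                    sim.source, _bone_seed_voxel(scene, scene.ulna, sim.source),
                    thresholds, cfg.level_set,
                )
                if cfg.experiment != "snr":
                    shared_meshes = (radius_mesh, ulna_mesh)
                    shared_sim = sim
            else:
                radius_mesh, ulna_mesh = shared_meshes
            source = (shared_sim or sim).source
            if cfg.experiment == "zcoverage":
                radius_mesh, ulna_mesh = clip_mesh_to_coverage(
                    radius_mesh, ulna_mesh, coverage_mm=level
                )
            t_seg = time.perf_counter()
            dc_radius = make_double_contour(radius_mesh, source, delta)
            dc_ulna = make_double_contour(ulna_mesh, source, delta)
            center = radius_mesh.centroid
            samples: List[ErrorSample] = []
            transforms: List[Tuple[RigidTransform, RigidTransform]] = []
            rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, j, 0xA11]))
            for i, target in enumerate(sim.targets.volumes):
                gt = sim.targets.poses[i]
                pair: List[RigidTransform] = []
                for dc in (dc_radius, dc_ulna):
                    jitter = random_rigid_transform(
                        rng, cfg.init_jitter_mm, cfg.init_jitter_deg, center=dc.centroid
                    )
                    init = gt @ jitter
                    res = register(dc, target, init, cfg.registration)
                    pair.append(res.transform)
                samples.append(error_sample(i, pair[0], pair[1], center=center))
                transforms.append((pair[0], pair[1]))
            t_reg = time.perf_counter()
            logger.info(
                "%s | seed %d | simulate %.1fs | segment+clip %.1fs | register %.1fs",
                label, cond_seed, t_sim - t0, t_seg - t_sim, t_reg - t_seg,
            )
        except Exception as exc:  # abort this condition, keep the others
            logger.error("condition %s aborted: %s", label, exc)
            failures[label] = f"{type(exc).__name__}: {exc}"
            continue
        conditions.append(
            ConditionResult(
                label=label,
                level=level,
                samples=samples,
                translation=summarize([s.translation_mm for s in samples], label),
                rotation=summarize([s.rotation_deg for s in samples], label),
                transforms=transforms,
            )
        )
    if not conditions:
        raise RuntimeError(f"every condition failed: {failures}")
    summary_map = {c.label: (c.translation, c.rotation) for c in conditions}
    stats = run_comparison_table(summary_map, cfg.experiment) if len(conditions) > 1 else []
    regressions = None
    if cfg.experiment == "motion" and len(conditions) >= 3:
        levels_done = [c.level for c in conditions]
        regressions = {
            "translation": velocity_regression(
                levels_done, [c.translation for c in conditions]
            ),
            "rotation": velocity_regression(
                levels_done, [c.rotation for c in conditions]
            ),
        }
    manifest = _manifest(cfg)
    if failures:
        manifest["failed_conditions"] = failures
    result = ExperimentResult(
        config=cfg,
        conditions=conditions,
        stats=stats,
        regressions=regressions,
        manifest=manifest,
    )
    if cfg.out_dir:
        _write_outputs(result, Path(cfg.out_dir))
    return result


def _manifest(cfg: ExperimentConfig) -> Dict:
    d = dataclasses.asdict(cfg)
    d["condition_seeds"] = [
        _condition_seed(cfg.seed, j) for j in range(len(cfg.levels))
    ]
    return d


def _write_outputs(result: ExperimentResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    samples_path = out / "samples.csv"
    result.samples_frame().to_csv(samples_path, index=False)
    stats_path = out / "stats.csv"
    result.stats_frame().to_csv(stats_path, index=False)
    tf_path = out / "transforms.json"
    tf_path.write_text(
        json.dumps(
            {
                c.label: [
                    {"radius": r.to_dict(), "ulna": u.to_dict()}
                    for r, u in c.transforms
                ]
                for c in result.conditions
            },
            indent=1,
        )
    )
    for p in (samples_path, stats_path, tf_path):
        files[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = dict(result.manifest)
    manifest["files"] = files
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    make_report(result, out)


def boxplot_stats(result: ExperimentResult, response: str) -> List[Dict]:
    """Matplotlib ``bxp`` stats dicts built directly from the ErrorSummaries."""
    boxes = []
    for cond in result.conditions:
        s: ErrorSummary = getattr(cond, response)
        boxes.append(
            dict(
                label=cond.label, med=s.median, q1=s.q1, q3=s.q3,
                whislo=s.whisker_low, whishi=s.whisker_high,
                fliers=list(s.outliers),
            )
        )
    return boxes


def make_report(result: ExperimentResult, out_dir: str | Path) -> List[Path]:
    """Paired translation/rotation box plots plus the statistics table.

    Box elements are drawn from the precomputed :class:`ErrorSummary` fields
    (matplotlib ``bxp``), so the figure shows exactly the summarized
    statistics.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not result.conditions:
        raise ValueError("no summarized conditions to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, attr, title, unit in (
        (axes[0], "translation", "Translational error", "mm"),
        (axes[1], "rotation", "Rotational error", "deg"),
    ):
        ax.bxp(boxplot_stats(result, attr), showfliers=True)
        ax.set_title(title)
        ax.set_ylabel(unit)
        ax.tick_params(axis="x", rotation=30)
    fig.suptitle(f"Registration error — {result.config.experiment} experiment")
    fig.tight_layout()
    paths = []
    for suffix in ("png", "svg"):
        p = out / f"boxplot_{result.config.experiment}.{suffix}"
        fig.savefig(p, dpi=120)
        paths.append(p)
    plt.close(fig)
    stats_path = out / "stats.csv"
    if not stats_path.exists():
        result.stats_frame().to_csv(stats_path, index=False)
    paths.append(stats_path)
    return paths
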