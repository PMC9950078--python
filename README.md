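# drujkin

Quantifying the **methodological error** of dynamic-CT (4D-CT) kinematic
analysis of the distal radio-ulnar joint (DRUJ), end to end and with no
external data.

## The problem

4D-CT motion analysis of the wrist registers segmented 3D bone models to
every frame of a time-resolved CT sequence and reads joint kinematics off
the recovered rigid transforms. Three imaging factors corrupt that chain:
low signal-to-noise ratio (tube current–time product, mAs), limited axial
(Z-) coverage of 4D-capable scanners, and motion artefacts that turn from
blur into duplicated-contour ghosting as the joint moves faster. When the
measured kinematic parameter is of the same order as the registration error,
conclusions about joint function become unreliable — so the error itself
must be measured.

The trick: scan (here: simulate) a radius and ulna that are *rigidly fixed
to each other* while the whole assembly rotates about the ulnar shaft. Any
apparent motion of the radius relative to the ulna after image analysis,

```
E = T_ulna⁻¹ ∘ T_radius            (identity, if analysis were perfect)
```

is pure methodological error. Per frame it is condensed to two scalars: the
norm of the relative translation (mm) and the norm ‖(θy, θx, θz)‖ of the
Tait-Bryan YXZ angle triple (degrees). Per condition, Tukey box-plot
statistics summarize the frames: the **median** is the accuracy, the
**spread** the precision. Conditions are compared with Shapiro–Wilk,
median-centred Ansari–Bradley / Welch (precision), Kruskal–Wallis / Mood's
median (accuracy), and an angular-velocity regression, all at α = 0.05.

Small angles matter: a rotational error of 1° at one end of an average male
radius (26.5 cm) displaces the other end by tan(1°)·265 mm ≈ **4.6 mm**.

## What's in the package

| module | contents |
|---|---|
| `drujkin.phantom` | analytic two-bone DRUJ scene, rasterization, quantum mottle (σ ∝ 1/√mAs), exposure-window motion blur/ghosting, experiment simulation with ground-truth poses |
| `drujkin.segmentation` | threshold-connected region growing, hole filling, Laplacian level set, marching cubes → surface meshes (PLY/STL) |
| `drujkin.registration` | double-contour grey-value sampling, NCC similarity, Powell rigid registration, coverage clipping of meshes |
| `drujkin.kinematics` | relative transforms, Tait-Bryan YXZ decomposition, error magnitudes, lever-arm conversion, box-plot summaries |
| `drujkin.stats` | the statistical decision tree and velocity regressions |
| `drujkin.experiments` | the three end-to-end sweeps (SNR / Z-coverage / motion), CSV + JSON + figure outputs |
| `drujkin.volume`, `drujkin.transforms` | NIfTI/MetaImage volumes, rigid transforms with explicit rotation centers |

Real volumes in NIfTI (`.nii.gz`) or MetaImage (`.mhd`) are accepted by
every stage downstream of the simulator.

## Worked example

A reduced SNR sweep from the command line (5 frames per exposure level to
keep it quick; the full design uses 33):

```bash
drujkin run --experiment snr --frames 5 --seed 7 --out out/snr_demo
```

prints the comparison table and per-condition medians:

```
design           pair    response           test  statistic        p  significant
   snr  30 mAs-75 mAs translation ansari-bradley  16.500000 0.606316        False
   snr  30 mAs-75 mAs translation kruskal-wallis   0.534545 0.464702        False
   snr  30 mAs-75 mAs    rotation ansari-bradley  15.500000 0.863611        False
   snr  30 mAs-75 mAs    rotation kruskal-wallis   0.098182 0.754023        False
   snr 75 mAs-120 mAs translation ansari-bradley  11.500000 0.229187        False
   snr 75 mAs-120 mAs translation kruskal-wallis   2.454545 0.117185        False
   snr 75 mAs-120 mAs    rotation ansari-bradley  11.500000 0.229187        False
   snr 75 mAs-120 mAs    rotation kruskal-wallis   0.272727 0.601508        False
30 mAs: median translation 0.1054 mm, median rotation 0.2180 deg
75 mAs: median translation 0.1003 mm, median rotation 0.3762 deg
120 mAs: median translation 0.0300 mm, median rotation 0.1046 deg
```

Reading it: registering the same static bones to 120 mAs frames leaves a
median apparent radius-vs-ulna displacement of 0.03 mm / 0.10°; quadrupling
the noise (30 mAs) roughly triples both error medians. With only 5 frames
per condition none of the pairwise tests reaches significance — the full
33-frame design is what the statistics are sized for. The output directory
receives `samples.csv`, `stats.csv`, `transforms.json`, `manifest.json` and
paired box-plot figures.

The same sweep from Python:

```python
from drujkin.experiments import ExperimentConfig, run_experiment

result = run_experiment(ExperimentConfig(experiment="motion", seed=7))
for cond in result.conditions:
    print(cond.label, cond.translation.median, cond.rotation.median)
print(result.regressions["rotation"]["accuracy"])   # slope vs deg/s
```

Other pipeline stages are exposed individually (`drujkin simulate`,
`drujkin segment`, `drujkin register`) and as library functions; see
`docs/methods.md` for the model, parameter defaults, and numerical choices.

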