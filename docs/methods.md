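# Methods

`drujkin` measures the *methodological* error of dynamic-CT joint motion
analysis: the apparent motion between two bones that are in truth rigidly
fixed to each other, introduced purely by imaging and image analysis. The
package simulates a distal radio-ulnar joint (DRUJ) phantom, degrades the
images in controlled ways, runs the standard segmentation → grey-value
registration → pose-decomposition chain, and compares the resulting error
distributions across scan conditions.

## Phantom model

The scene holds two simplified long bones in an agarose-like background:

* **shafts** — capped elliptic cylinders along the longitudinal (z) axis.
  Elliptic rather than circular cross-sections for two reasons: long-bone
  shafts are not circular, and a perfectly axisymmetric shaft makes rotation
  about the bone's own axis invisible to intensity-based registration, which
  would render rotational error ill-defined. Defaults: radius-like bone
  semi-axes 7.5 × 5.5 mm (cortical thickness 2.5 mm), ulna-like 6.0 × 4.5 mm
  (2.0 mm), shaft length 60 mm.
* **distal heads** — ellipsoids centred at the distal shaft end but offset
  4 mm laterally off the shaft axis (as the real distal radius is); semi-axes
  10 × 9 × 11 mm (radius), 8 × 7 × 7 mm (ulna).
* **intensity model** — background 50, medullary 300, cortical 1200 HU-like
  units, emulating 120 kVp contrast between gel/soft tissue, marrow and
  cortex. Segmentation separability requires cortical > medullary >
  background, which the scene validates.
* **geometry invariants** — the bones must not intersect; the heads are
  placed so the minimum surface distance equals the configured joint gap
  (default 2 mm), which a dense-sampling check verifies at construction.
* **rotation axis** — through the centre of the ulnar shaft along z. Under
  rotation the ulna barely moves while the radius sweeps the largest arc, so
  motion artefacts concentrate on the radius, as in forearm
  pronation/supination.

All coordinates are millimetres in `(z, y, x)` array order; axis 0 is
longitudinal; a volume's origin is the world position of the centre of voxel
`(0, 0, 0)`.

### Rasterization and the edge profile

Voxel values are the scene intensity at voxel centres with the cortical
boundary softened over a finite width. Two profiles exist:

* `smoothstep` (default for `rasterize`) ramps over exactly one voxel —
  pure partial-volume averaging. Values more than half a ramp width from the
  boundary are exact, which keeps simple voxel-level reasoning valid.
* `gauss` (used by the simulation pipeline) is a clamped-erf edge of width
  two voxels (σ = one voxel), emulating the band-limiting of a
  reconstruction kernel. The wider, smoother profile matters: a one-voxel
  edge is undersampled on its own grid, and the trilinear interpolation error
  it induces biases the registration optimum by up to ~1° / 0.2 mm. With the
  band-limited profile, noise-free pose recovery is accurate to
  < 0.1 mm / 0.1° (see below). Treat the profile/width pair as a scanner
  property: coarser grids model lower-resolution scanners with
  proportionally wider kernels.

### Degradations

* **Quantum mottle** — additive zero-mean Gaussian noise with
  σ(mAs) = σ_ref · √(mAs_ref / mAs), anchored at σ_ref = 25 HU-like units at
  120 mAs. Gaussian is a good approximation for mottle in reconstructed CT;
  only the direction of the SNR–mAs relation is physically prescribed, and
  the 1/√mAs law follows from photon counting statistics.
* **Motion** — each 4D frame integrates the rotating scene over the 0.25 s
  exposure window. Below a per-frame sweep of 2.5° the frame is the uniform
  average of 15 sub-poses spanning the window (smooth blur). Above it, the
  weight concentrates at the window endpoints (0.5/0.5), producing the
  duplicated-contour *ghost* seen at roughly ≥ 10°/s. The equal-weight
  two-contour ghost is an emulation choice; real reconstruction produces
  ghosts whose relative intensities vary. The recorded ground-truth pose of
  a frame is the pose at mid-exposure.
* **Limited Z-coverage** — never applied to the volumes. The segmented
  radius and ulna meshes are clipped by a single plane: an axial bounding
  box of the requested height is anchored at the distal end of the *radius*,
  and its bottom plane removes vertices (plus incident faces) from both
  meshes. Surviving vertex coordinates are untouched.

Seeding: one integer seed per experiment; per-frame and per-condition
generators are spawned via `numpy.random.SeedSequence`, so identical
configurations reproduce bit-identical volumes and CSV outputs.

## Segmentation

Threshold-connected region growing (6-connectivity) from a user seed picks
up the cortical shell — default lower threshold midway between background
and cortical values, which intersects a symmetric edge profile exactly at
the true surface. Binary hole filling (6-connected background) closes the
medullary cavity. A Laplacian level set (SimpleITK) then refines the
boundary toward zero-crossings of the image Laplacian — the inflection of
the cortical edge; with our inside-negative signed-distance initialisation
the filter's expansion direction must be reversed, otherwise the front walks
away from the edge. Defaults: 50 iterations, RMS tolerance 1e-3, curvature
and propagation weights 1.0. Divergence (empty front, or flooding > 90 % of
the grid) raises instead of returning junk.

Surfaces are extracted at the zero level by marching cubes with vertices on
grid edges by linear interpolation. We use the Lewiner variant (scikit-image
default): the classical 15-case table can leave holes at ambiguous faces,
which would violate the watertightness this pipeline expects of closed
bones. Outward vertex normals come from the level-set gradient.

On noise-free and 120 mAs phantoms the full chain lands within
0.13–0.2 voxels mean absolute distance of the analytic surface.

## Registration

A *double contour* brackets the cortical edge: each mesh vertex contributes
an outer point (vertex + δ·normal) and an inner point (vertex − δ·normal),
δ defaulting to one in-plane voxel. Reference grey values are trilinear
samples of the source at those points. A candidate rigid transform is scored
by the normalized cross-correlation (NCC) between the reference profile and
target values at the transformed points; NCC's invariance to positive affine
intensity maps absorbs exposure differences between scans. Points mapping
outside the target are excluded; if more than half leave the volume the
overlap is degenerate and registration refuses to start (the analogue of a
failed manual pre-registration, which is emulated by initialising at the
ground-truth pose perturbed by a bounded random offset, default ≤ 2 mm /
≤ 2°).

Optimization is Powell's derivative-free method over 6 parameters
(translations in mm, rotations in degrees about the contour centroid; the
1 mm ≡ 1° scaling makes the parameter space roughly isotropic for these
bone sizes). Two numerical choices matter:

* **score tolerance 1e-9** — the NCC surface is extremely shallow along
  rotation about a bone's long axis (~1e-5 score change per 0.1°); a looser
  tolerance stalls that mode around 1° of residual error long before the
  parameter tolerance binds.
* **cubic target interpolation during optimization** — with trilinear
  sampling on both sides, the interpolation errors of reference and target
  correlate whenever a candidate pose aligns the two grids, pulling the
  optimum toward grid-aligned poses ("grid snapping"). On slowly rotating
  sequences this manifested as error growing linearly with the scene's
  rotation angle and saturating at one voxel. Cubic B-spline sampling of the
  target (coefficients prefiltered once per registration) suppresses the
  effect; the reference stays trilinear, as the double contour defines it.

With these defaults, on a 0.6 mm grid, 20 random poses (translations ≤ 3 mm,
rotations ≤ 3°) are recovered with maximum error < 0.1 mm / 0.1° without
noise, and median error ≪ 0.5 mm / 0.5° under 120 mAs-level noise.

An optional `max_points` subsample (even stride over the point list)
accelerates the optimizer on large contours; the paper-scale sub-sampling
idea applied once more.

## Error decomposition

Each frame yields transforms for radius and ulna; the *relative* transform
T_ulna⁻¹ ∘ T_radius, expressed about the radius mesh centroid, is the
methodological error (with perfect registration it is the identity in every
frame, because the simulated radius never moves relative to the ulna). The
translation error is the Euclidean norm of the relative translation at that
centroid; the rotation error is the Euclidean norm of the Tait-Bryan YXZ
angle triple, decomposed intrinsically (R = Ry·Rx·Rz with θx ∈ [−90°, 90°];
the extrinsic reading is available behind a flag). Near gimbal lock
(|cos θx| < 1e-8) θz is set to zero, θy absorbs the yaw, and a degeneracy
flag is raised. The geodesic rotation angle is computed for diagnostics but
never used in statistics. The Euler-norm magnitude (not the geodesic angle)
is the error parameter, matching standard robotics usage for small errors.

Per-condition summaries follow the Tukey box-plot convention: median,
quartiles by linear interpolation between order statistics (the numpy
default — outlier counts can shift under other quantile conventions, hence
the explicit choice), whiskers at the most extreme samples within 1.5·IQR of
the box, everything beyond as outliers. *Accuracy* of a condition is its
median; *precision* is its spread (IQR in regressions).

## Statistics

All at α = 0.05, raw p-values, no multiplicity correction (pairwise
adjacent-level comparisons are reported as-is):

* Shapiro–Wilk normality per sample (Z-coverage samples, n = 9, are treated
  as non-parametric without testing, due to their size).
* Precision: Ansari–Bradley after median-centering both samples (the test
  misleads when medians differ) for SNR / Z-coverage; two-tailed Welch
  t-test on raw magnitudes for motion samples (applying Welch to raw
  magnitudes rather than centred deviations is a documented convention
  choice).
* Accuracy: Kruskal–Wallis when precision found equal spread, Mood's median
  test otherwise. Mood's: values equal to the grand median count in the
  "at or below" cell; chi-square without continuity correction.
* Motion trend: OLS of per-condition median (accuracy) and IQR (precision)
  on angular velocity, for translation and rotation separately.

Under the null (identical normal samples, n = 33) each test's empirical
type-I rate over 1000 seeds sits within a 3σ binomial band around 5 %.

## Experiment designs and problem sizes

Full designs follow the study layout: SNR at 30/75/120 mAs with 33 frames
per condition (source re-acquired at each exposure); Z-coverage with one
source and one series of 9 full-extent targets at 120 mAs, meshes clipped to
40/57/80/160 mm; motion with one source and 33-frame sequences at seven
angular velocities spanning 1–30 °/s (defaults 1, 2.5, 5, 10, 15, 20, 30 —
the design states the range and count, not each level). The motion and
Z-coverage experiments share a single segmentation per run, mirroring their
single-source scanning design.

The default test grid is 1.2 mm isotropic (the scene fits in roughly
65 × 40 × 30 voxels; a motion-covering grid is larger). The test suite uses
deliberately reduced problem sizes chosen to keep statistical headroom while
a full run stays in CPU-minutes: parameter recovery on a 0.6 mm grid;
directional-trend replicates with 7 frames per condition, SNR endpoints
(30 vs 120 mAs) on the 1.2 mm grid and a 1/15/30 °/s motion sweep on a
0.9 mm grid, 10 seeded replicates with a sign-test criterion (≥ 9/10).
Full-scale runs (`ExperimentConfig` defaults) behave the same way with
tighter medians; 512 × 512 in-plane grids are configuration options.

## What the generator does and does not emulate

Captured: cortical/soft-tissue contrast, photon-statistics noise scaling,
partial-volume and reconstruction-kernel softening, exposure-window motion
blur and its transition to ghosting, coverage truncation as mesh clipping,
operator pre-registration as bounded random initialisation, and the
fixed-relative-pose gold standard that defines methodological error.

Not captured: projection-domain physics (beam hardening, spiral/pitch
artefacts, scatter), anatomical shape detail (trabecular texture, styloid
processes, cartilage), intensity inhomogeneity, table/patient drift, and
asymmetric ghost weighting. Consequences: absolute error magnitudes on this
phantom are smaller than cadaver-scale values — the bones here are cleaner
and the degradations milder than reality — so passing tests demonstrate
correct *mechanics and directions* (error grows with noise and speed,
shrinks with coverage), not clinical error budgets. In particular the
equal-weight ghost splits rotation errors strongly but produces a weaker
translation response than an asymmetric ghost would.

## Known limitations

* The ellipsoid and elliptic-cylinder signed distances use a first-order
  bound (exact on principal axes); adequate under boundary softening, but
  not a true Euclidean SDF far off-axis.
* Marching cubes requires the bone to be interior to the grid; surfaces
  touching the volume boundary would be left open. `fit_grid` adds margin to
  prevent this.
* The Laplacian level-set parameterisation (iterations, weights) is a
  pragmatic default; the underlying filter family is standard but its exact
  tuning in clinical tools is unknown.
* Registration is local: the capture range is roughly the basin around the
  initialisation; starts beyond ~5 mm / 5° may lock onto the wrong optimum
  or fail the overlap check, by design.
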