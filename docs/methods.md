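# Methods

`endopose` estimates and tracks the 6D pose — image-plane position
(tx, ty), a scale factor standing in for camera distance, and three
rotations (rx, ry, rz in degrees) — of a surgical target in monocular
endoscopic RGB video, and composites a 3D model of the target over the
frames. Because no deposited surgical videos or patient models exist for
this problem, the package carries a synthetic scene simulator that
renders labeled training data and evaluation sequences with exact ground
truth; every trainable and calibratable component is exercised end to
end on simulated scenes.

## Scene model and conventions

The simulator is a pure software rasterizer: pinhole camera at the
origin looking down −Z (world +Y up), image x rightward and y downward
with pixel centers at integer coordinates, z-buffered barycentric
triangle fill, Gouraud-interpolated Lambertian shading, and a procedural
sinusoidal texture evaluated per pixel from interpolated model-space
coordinates, so texture is rigidly attached to the surface and
consecutive-frame optical flow on the target is physically meaningful.
Rotations are intrinsic, applied about the model's own axes in X→Y→Z
order. Scale maps to distance along the optical axis: the target center
sits at depth `ref_distance / scale`, so projected linear size is
proportional to scale and silhouette area to scale².

Two lighting terms matter. A directional light with seeded jitter
(direction and intensity, ±15% by default) emulates variable
illumination. On top of it, an inverse-square *headlight* falloff
(normalized at the reference distance, clipped at 4×) models the light
source that endoscopes carry co-axially with the camera: surfaces closer
to the scope are visibly brighter. This term matters for monocular
depth-related cues — tilting the catheter tip toward the camera
brightens it smoothly and monotonically, exactly where the geometric
foreshortening cue (∝ cos of the tilt) has zero derivative.

Targets are watertight triangle meshes centered on their centroid:

* **organ** — an icosphere scaled to semi-axes (1.0, 0.85, 0.75) with a
  seeded low-order radial perturbation (`bumpiness` 0.15), a kidney-like
  rounded shape;
* **catheter** — a cylinder (radius 0.20, length 2.2 model units) along
  its model Z axis with a balloon tip (radius 0.38) at one end, a
  Foley-style geometry. The tip preserves the spin symmetry about the
  long axis (rz remains irrelevant) but breaks the ± ambiguity of
  out-of-plane tilt: a plain cylinder's silhouette length goes as
  cos(rx), which cannot distinguish +rx from −rx. A mounting rotation
  lays the long axis horizontally in the image, so that model-Y rotation
  is the in-plane tilt readable from the silhouette, model-X rotation
  tilts the tip toward/away from the camera, and model-Z is the
  invisible spin.

Rod-shaped instruments (0–2 per frame) enter from outside the frame at a
depth in front of the target and may occlude it; a proposal is redrawn
(up to 20 times, then dropped) whenever cumulative occlusion would
exceed 40% of the silhouette, matching the assumption that usable frames
keep the target well framed. The background is a seeded low-frequency
tissue-toned field; mild Gaussian sensor noise (σ = 0.008) is added per
frame. Identical (mesh, pose, config, seed) produce bit-identical
frames, masks and manifests.

A *domain-shift* variant (`SceneConfig.shifted()`): stronger lighting
jitter (0.4), Blinn–Phong specular highlights (0.35) and mild
mask-boundary label noise (2% of boundary pixels) emulate the harder
statistics of real intraoperative frames for fine-tuning experiments.

What the simulator does **not** model: tissue deformation, smoke, blood,
specular wetness (outside the shift variant), photometric calibration,
rolling shutter, or patient-specific anatomy. Passing tests therefore
demonstrate the pipeline's internal consistency and its behavior under
controlled nuisance variation, not clinical segmentation or rotation
accuracy on real video.

## Segmentation

A three-class (background / tool / target) encoder-decoder with skip
connections: two residual-block encoder stages (width w, 2w), a 4w
bottleneck, nearest-upsampling decoder stages with concatenated skips,
and a 1×1 classification head; pixel-wise cross-entropy, Adam. The desk
profile (96×96 inputs, w = 8) trains on one CPU in minutes; width and
depth are configuration, not architecture changes. Checkpoint selection
is by best validation mean IoU.

IoU is reported per class and as their mean. Headline numbers pool the
test set (summed intersections over summed unions, stated in the report
header); per-image scores are kept alongside. A class absent from both
prediction and truth is *undefined* for that image and excluded from
means rather than scored 0 — scoring it 0 would penalize frames that
legitimately contain no tool.

## Localization from the mask

The largest 8-connected target component (ties broken by earliest
row-major pixel) is summarized by its moment-equivalent ellipse: center
= centroid, axis lengths = 4·√(eigenvalues of the second-central-moment
matrix), orientation θ = ½·atan2(2μ11, μ20−μ02) in (−90°, 90°], with y
negated so θ grows counter-clockwise on screen. This is the standard
moments ellipse (identical to `skimage.regionprops`, cross-checked in
tests) and is robust to ragged mask boundaries. Isotropic regions report
θ = 0 by tie-break; regions under 5 px are rejected; collinear regions
get the minor axis floored at 1 px with a warning.

Position is the ellipse center. Scale uses the square-root area law
`scale = ref_scale·√(area/ref_area)` against a reference ellipse
registered once at a known scale — projected area goes with the square
of linear size, and linear size with inverse distance. For elongated
rigid targets (elongation ≥ 1.2, otherwise "axis-ambiguous") the
in-plane rotation is `sign·θ + offset` with a per-target calibration
fixed once from a registered frame; for the built-in catheter profile
the identity calibration is exact by construction.

## Rotation classification

Rotation estimation is a per-axis classification problem: each axis that
varies (per the target's rotation-range profile) is discretized into
half-open bins of width 1° by default — e.g. 50 classes for the catheter
X range [−40°, 10°) — and a prediction decodes to the bin center of the
argmax class (ties to the lower index). Heads share a convolutional
backbone and each consist of dense → ReLU → batch-norm → dropout (0.5) →
dense-N → softmax. The loss is the sum of per-axis cross-entropies.

Two profiles exist. The full-size profile follows the published family:
a 50-layer residual backbone with 4096-unit heads, batch 32, Adam at
1e-5, ~15 epochs. The desk profile — what this package trains and
evaluates — is a from-scratch three-stage plain convolutional backbone
(widths 12/24/48, 2× max-pool each stage) with 256-unit heads on 64×64
inputs, batch 32, Adam at 1e-3 with ×0.2 step decay at 60% and 85% of
the epochs, 30 epochs. Three training-side choices matter for the
desk-scale accuracy and are deliberate:

* **Photometric augmentation** — per-image random gain (±15%) and offset
  (±0.06) during training, so the net keys on geometry and relative
  shading gradients rather than absolute intensity (lighting is a
  nuisance). Per-image *standardization* at inference was rejected: with
  a headlight, absolute brightness carries genuine depth information.
* **Ordinal label smoothing** — the target distribution is a Gaussian
  over bins centered on the true angle (σ = 1 bin width) instead of
  one-hot. Neighboring bins represent neighboring angles; plain one-hot
  treats a 1° miss and a 30° miss identically, while the smoothed target
  teaches the ordinal structure and empirically removes the rare
  gross-confusion errors. σ → 0 recovers one-hot exactly.
* **Best-validation checkpointing** by mean ±5° accuracy across heads.

Fine-tuning continues from a checkpoint at 0.1× learning rate on
additional data (the simulator's domain-shift variant standing in for
annotated real frames); zero epochs is the identity.

## Optical-flow rotation tracking

Dense flow between consecutive frames (iterative Lucas–Kanade, radius 5;
the contract — median du within [0.8, 1.2] for a 1 px shift of a
textured image — is normative, not the algorithm) is restricted to
target pixels present in both frames' masks and decomposed by a
least-squares affine fit about the silhouette-ellipse center:
d(p) = A(p−c) + t. The antisymmetric part of A is the in-plane rotation
rate (curl, rad/frame), the trace is the looming rate, and t minus the
measured ellipse-center displacement is the *texture slip* — surface
texture sliding across a quasi-static silhouette, the signature of
out-of-plane rotation. Increments are
δrz = −degrees(curl) (image y points down), δry = ky·slip_x,
δrx = kx·slip_y, with components under a dead band (0.05 px slip)
zeroed so static scenes accumulate nothing.

Two numerical choices:

* the affine fit uses mask pixels eroded 7 px (flow window radius plus
  margin) from the silhouette boundary, backing off automatically if too
  few pixels remain. Boundary windows mix static background with target
  motion and were measured to shrink the fitted curl by ~28%; erosion
  reduces the residual bias to ~5%.
* kx, ky (degrees per pixel of slip) are calibrated once from simulated
  single-axis sequences of known rate, as the mean of rate/slip over
  frames above the dead band. On held-out sequences the calibrated
  increments are within a few percent of truth.

Per-frame increments are accumulated from the registered initial
rotation — always on consecutive frames, never on wider frame pairs —
and evaluation samples every 10th frame at ±5° and ±10° tolerance
bands. This decomposition is one concrete, deterministic realization of
the premise that flow magnitude indicates rotation angle and flow
direction the axis; it is documented as this package's interpretation.

## Pipeline modes

* **rigid-instrument**: per frame, X from the classifier, Y from the
  silhouette ellipse (held with a flag when the elongation gate fails),
  Z fixed at 0 by symmetry.
* **organ-auto**: the classifier registers the first well-framed frame;
  optical flow tracks thereafter.
* **organ-manual**: a supplied pose (CLI flag / one-line init) registers
  the first frame; optical flow tracks thereafter.

Every frame yields a pose-log record with a source tag per field
(`network`, `mask`, `flow`, `fixed`, `manual-init`, `held`); a frame
without a detectable target emits the raw frame and a flagged record,
and tracking resumes at the next detection. The overlay rasterizes the
mesh at the logged pose with the same camera model (fixed frontal light,
no texture, configurable alpha; alpha-blending is the default
compositing since no other convention is established). Real-time
throughput is reported, not guaranteed.

## Problem sizes and reproduction

The bundled reproduction script (`scripts/acceptance.py`) re-runs two
benchmarks from scratch at the package's chosen desk-scale sizes:
segmentation on 500 simulated organ scenes at 96×96 (70/15/15 split,
batch 4, lr 1e-4, up to 50 epochs, width-8 encoder), and rotation on a
catheter dataset of 4700 scenes (70/15/15; the ≈4000 train+val frames
drive training) with an independently seeded 3000-frame held-out test
set at 64×64. Under these conditions the segmenter reaches a pooled test
mean IoU around 0.96 and the rotation classifier ±5° accuracy around
0.999; both runs take roughly eight minutes each on one CPU core.

## Known limitations

* All accuracies are on simulated scenes; nothing here validates
  clinical performance (the motivating domain's real-image accuracy is
  known to drop sharply and is out of scope).
* The flow heuristic assumes a mostly rigid, mostly in-frame target;
  full occlusion requires re-registration (only detection gaps are
  flagged).
* Scale is relative to a registered reference frame, not metric depth;
  camera intrinsics are the simulator's, uncalibrated against any real
  scope.
* The silhouette centroid is biased away from the projected model origin
  for asymmetric targets (≈3 px for the balloon-tip catheter at default
  framing); registration anchors the model to the silhouette center, so
  the bias is consistent across frames.
* Rotation-range profiles bound what the classifier can express;
  trajectories are clamped at the range edges with a warning.
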