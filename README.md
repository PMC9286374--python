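# endopose

Monocular 6D pose registration and tracking of a surgical target in
endoscopic RGB video — and a synthetic scene simulator that makes the
whole pipeline trainable and testable without any external data.

## The problem

Augmented-reality guidance in robot-assisted laparoscopy overlays a
patient's preoperative 3D model on the live endoscopic view. That
requires the target's 6D pose — image position, apparent scale
(distance), and three rotations — recovered in real time from a single
RGB stream, with no extra sensors. `endopose` implements a
registration-and-tracking pipeline for this setting:

1. **Semantic segmentation** (encoder-decoder with skip connections)
   labels every pixel background / tool / target.
2. **Ellipse localization** summarizes the target mask by its
   moment-equivalent ellipse: the center gives the image position, the
   area gives the scale factor through a square-root law
   `s = s_ref·√(A/A_ref)`, and for elongated rigid instruments the
   major-axis angle gives the in-plane rotation.
3. **Discretized rotation classification**: each predicted axis is
   binned into 1° classes over its anatomical range (e.g. X ∈ [−40°,
   10°) → 50 classes for a catheter) and a shared-backbone CNN with one
   softmax head per axis predicts the bin; the decoded angle is the
   argmax bin center.
4. **Masked optical-flow tracking**: dense flow restricted to target
   pixels is decomposed by a least-squares affine fit d(p) = A(p−c)+t;
   the curl of A gives the in-plane rotation increment
   (δrz = −deg(ω)), and the translation residual after subtracting the
   ellipse-center motion — texture *slip* — gives the out-of-plane
   increments δrx = kx·slip_y, δry = ky·slip_x with constants
   calibrated on single-axis sequences. Increments accumulate from a
   registered initial pose.
5. **Overlay**: the mesh is rasterized at the estimated pose and
   alpha-blended over the frame; every frame's pose record tags the
   source of each field (network / mask / flow / fixed / manual-init).

Three modes mirror the clinical case studies: `rigid-instrument`
(classifier X + mask Y + fixed Z, every frame), `organ-auto` (classifier
registers the first frame, flow tracks), and `organ-manual` (supplied
initial pose, flow tracks).

Since surgical videos and patient models cannot be redistributed, the
package ships a deterministic software rasterizer (pinhole camera,
z-buffer, Lambertian shading with an endoscope-headlight 1/d² falloff,
surface-attached procedural texture, occluding instrument rods) that
renders labeled datasets and smooth sequences with exact ground truth.
See `docs/methods.md` for the scene model, network profiles and
numerical choices.

## Worked example: calibrate and track a rotating organ

```bash
endopose --seed 3 simulate --sequence --n 12 --rates 0.5,0,0 --size 96 --out seq_x
endopose --seed 4 simulate --sequence --n 12 --rates 0,0.5,0 --size 96 --out seq_y
endopose --seed 5 simulate --sequence --n 40 --rates 0,0,0.5 --size 96 --out seq_z
endopose calibrate-flow --x-sequence seq_x --y-sequence seq_y \
         --x-rate 0.5 --y-rate 0.5 --out calib.json
endopose track --sequence seq_z --calibration calib.json --out traj.csv
```

The calibration step prints the recovered slip-to-degrees constants:

```
kx=2.8715 ky=2.6601 -> calib.json
```

meaning one pixel of vertical (resp. horizontal) texture slip per frame
corresponds to ≈2.87° of X (resp. ≈2.66° of Y) rotation at this framing.
`track` accumulates flow increments over the 40-frame sequence rotating
at 0.5°/frame about Z and scores them at the 10-frame sample points:

```
axis  tol  accuracy
   x  5.0       1.0
   x 10.0       1.0
   y  5.0       1.0
   y 10.0       1.0
   z  5.0       1.0
   z 10.0       1.0
```

All sampled frames are within ±5° on every axis. The trajectory CSV
holds the per-frame estimates against ground truth; drift stays under
≈2% of the accumulated rotation:

```
 frame    rz_est  rz_true
     0  0.000000      0.0
    10  4.877721      5.0
    20  9.810129     10.0
    30 14.701534     15.0
    39 19.159786     19.5
```

Training works the same way from a simulated manifest:

```bash
endopose --seed 0 simulate --n 500 --target organ --ranges kidney --size 96 --out organ_ds
endopose --seed 0 train-seg --manifest organ_ds/manifest.csv --out seg.npz
endopose eval-seg --model seg.npz --manifest organ_ds/manifest.csv --report iou.csv
```

## Layout

```
src/endopose/
  scene_sim/       simulator: meshes, poses, rasterizer, datasets, sequences
  nn/              minimal numpy conv-net engine (layers, Adam)
  segmentation.py  encoder-decoder training, prediction, IoU reports
  localization.py  connected components, moment ellipse, position/scale/Y
  rotation_net.py  angle binning, multi-head classifier, tolerance accuracy
  flow_rotation.py dense flow, affine decomposition, calibration, tracking
  pipeline.py      the three modes, overlay, pose logs, evaluation
  profiles.py      canonical desk-scale scene/mesh profiles
  experiments.py   the two benchmark experiments
  cli.py           `endopose` command-line interface
```
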