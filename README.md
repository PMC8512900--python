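# backmark

Real-time anatomical landmark detection on back-surface point clouds
from a Time-of-Flight (ToF) depth camera.

Quantitative posture assessment — screening for kyphotic, lordotic or
scoliotic deviations, or monitoring a physiotherapy exercise — relies on
trunk surface metrics computed from the positions of a small set of
anatomical landmarks on the subject's back.  Marking those landmarks by
hand is slow and rater-dependent.  `backmark` implements an automatic,
training-free detector for ten of them on organized depth frames
(144 × 176 pixels, SR4000-class sensor) of a standing subject seen from
behind:

| symbol | landmark |
|---|---|
| AL, AR | left/right axilla (armpit fold top) |
| SL, SR | left/right shoulder |
| WL, WR | left/right waist indentation |
| C7-T1 | cervicothoracic junction (vertebra prominens region) |
| TK | thoracic kyphosis apex |
| LL | lumbar lordosis apex |
| S1 | sacral base |

The package is aimed at researchers in movement science and
biomedical-engineering groups building posture-assessment systems; it
contains the full processing chain, the validation statistics used to
compare a detector against expert raters, and a synthetic back-surface
generator with exact ground truth for testing every stage without
recorded data.

## Method

Camera coordinates: `x` frontal axis (left→right), `y` longitudinal
(bottom→top), `z` distance from the camera; all internal units are
meters.

**Preprocessing.** Ten successive frames are averaged per processed
cloud (depth-noise σ drops ≈ √10); the scene is cut at z ≤ 2 m; points
with fewer than 20 neighbors within 5 cm are discarded.  A one-time
region-of-interest calibration splits the cloud left/right of its
centroid, takes the 10 cm band above each side's lowest point, separates
the subject's lower limb from the device frame's post with DBSCAN
(ε = 0.03 m), and keeps the x interval between the posts' inner faces.
Subsequent clouds are cropped to that interval and denoised again
(3 cm / 10 neighbors), yielding the subject silhouette.

**Detection.** A 4 cm horizontal band at the silhouette centroid is
clustered with DBSCAN; the largest cluster is the torso, and its lateral
extremes are the trunk/arm boundary points.  On each side, a plane
`z = ax + by + c` is fitted to the lateral fragment; points lying behind
it by ≥ 1 cm form the axillary-fold object, whose highest point is the
axilla.  The shoulder is the highest point in a narrow belt at the
axilla's x; C7-T1 is the cloud point nearest (in xy) the shoulder-line
midpoint.  Points within ±2.5 cm of the C7-T1 x and below it form the
spine band, fitted with a degree-5 polynomial z(y); the local minimum
with the greatest y is TK, the local maximum below it is LL, and the
lowest inflection is S1, each mapped back to the cloud by nearest
neighbor in a 2 cm slab.  The waist points are the minimal-half-width
silhouette edges between S1 and the axillae (1 cm bins, 3-bin
smoothing).

**Validation.** Consensus positions are expert averages in the frontal
plane; signed per-axis errors ΔL = L − L0 are reported in mm; the
method's errors are cleaned per landmark by the interquartile rule
(flagging values above Q3 + 1.5·IQR) applied in the principal-component
space of the error distribution; rater agreement is summarized by
pairwise average distances, and tested with the Friedman rank test with
Kendall's W as effect size (W = χ² / (n(k−1))).

## Worked example

```python
import numpy as np
from backmark import (BackModelParams, BackSurface, render_frames,
                      preprocess_frames, detect_landmarks)

params = BackModelParams()                      # average study subject
surface = BackSurface(params, tilt_phase=0.0)   # neutral pelvic pose
frames, truth = render_frames(surface, n=10, noise_sigma=0.004, seed=1)

cloud, roi = preprocess_frames(frames)          # average, denoise, segment
landmarks = detect_landmarks(cloud)

print(f"ROI x in [{roi.x_min:.3f}, {roi.x_max:.3f}] m, "
      f"{len(cloud)} silhouette points")
for name, pos in landmarks.present().items():
    err = np.hypot(*(pos[:2] - truth.landmarks.position(name)[:2])) * 1000
    print(f"{name:>4}: x={pos[0]:+.3f} y={pos[1]:+.3f} z={pos[2]:.3f} m "
          f"(error vs truth {err:4.1f} mm)")
```

Output:

```
ROI x in [-0.422, 0.422] m, 3468 silhouette points
  AL: x=-0.175 y=-0.136 z=1.784 m (error vs truth 10.6 mm)
  AR: x=+0.153 y=-0.138 z=1.804 m (error vs truth 12.8 mm)
  SL: x=-0.167 y=-0.074 z=1.782 m (error vs truth  3.1 mm)
  SR: x=+0.150 y=-0.073 z=1.774 m (error vs truth 15.0 mm)
  WL: x=-0.121 y=-0.355 z=1.830 m (error vs truth 13.5 mm)
  WR: x=+0.112 y=-0.321 z=1.822 m (error vs truth 47.9 mm)
C7T1: x=-0.012 y=-0.073 z=1.764 m (error vs truth 12.2 mm)
  TK: x=+0.004 y=-0.134 z=1.752 m (error vs truth 12.5 mm)
  LL: x=-0.004 y=-0.343 z=1.809 m (error vs truth  4.1 mm)
  S1: x=+0.004 y=-0.450 z=1.766 m (error vs truth 10.1 mm)
```

The ROI sits 1 cm inside the device posts (placed at x = ±0.45 m,
radius 2 cm).  Errors are frontal-plane distances to the generator's
continuous-surface ground truth; the waist points are the hardest
landmarks (a flat width trough plus the sensor's ≈8 mm lateral pixel
pitch), matching their behaviour in expert comparisons.  Single-cloud
detection takes well under 0.1 s; the rendered simulation dominates the
example's runtime.

A command-line interface wraps the same stages:

```bash
backmark simulate --seed 1 --out session/          # synthetic session
backmark preprocess --frames session/ --out subject.ply
backmark detect --cloud subject.ply --out landmarks.json
backmark validate --annotations annotations.json --out report/
backmark run --seed 1 --subjects 5 --out study/    # end to end vs truth
```

`DepthLimiter`, `RadiusOutlierFilter`, `RoiCalibrator`,
`SubjectSegmenter` and `LandmarkDetector` are scikit-learn style
estimators operating on `(n, 3)` arrays, so preprocessing stages compose
with `sklearn.pipeline.Pipeline`.

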