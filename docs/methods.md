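# Methods

This note records how `backmark`'s processing chain, synthetic data
generator and validation statistics are defined: the assumptions each
stage makes, the values of every tunable parameter and where a value
was a genuinely open choice, the numerical conventions, and what the
synthetic experiments do and do not demonstrate about real recordings.

## Coordinate and unit conventions

Camera coordinates throughout: `x` frontal axis (left to right of the
image, i.e. the subject's right to left seen from behind), `y`
longitudinal axis (up), `z` sagittal axis (distance from the camera).
All geometry is stored in meters; reports convert to millimeters at the
edge.  The sensor is an SR4000-class ToF camera producing organized
144 × 176 frames at 30 Hz, mounted 1.5 m above the floor and viewing
the subject's back at roughly 1.6–1.9 m, so the vertical field covers
approximately the 1–2 m height band of a standing adult.

## Preprocessing

* **Temporal averaging** — `n_average = 10` frames, per-pixel
  arithmetic mean.  A pixel invalid in any constituent frame is invalid
  in the average (strict mask intersection); averaging over per-pixel
  subsets would mix different noise levels across the grid.  Ten frames
  balance noise (σ/√10) against time resolution (3 Hz effective), and
  the `mean_shift_curve` diagnostic reproduces the flattening mean
  point displacement that motivates that operating point.
* **Depth limit** — `depth_max = 2.0` m, boundary inclusive.  The
  boundary semantics are unobservable in practice (a measure-zero set);
  inclusivity was fixed once for determinism.
* **Neighborhood outlier criteria** — acquisition stage: a point
  survives when at least 20 *other* points lie within 5 cm; subject
  stage (after the ROI crop): 10 within 3 cm.  The query point is never
  counted as its own neighbor; counting it would shift the threshold by
  exactly one.  Implemented with a k-d tree (`scipy.spatial.cKDTree`).
* **ROI calibration** — run once per session.  The cloud is split at
  the centroid's x; per side, the bottom band (`roi_bottom_band =
  0.10` m above the side's lowest point) contains part of a lower limb
  and part of the device frame.  DBSCAN (ε = 0.03 m, `min_points =
  10`) separates them.  The limb is the cluster whose x centroid lies
  nearest the whole-cloud centroid; the *device* is the **outermost**
  cluster.  Taking the outermost (rather than "the other") cluster
  matters when a third object — typically the subject's hanging
  arm/hand — appears between limb and post: the device frame surrounds
  the subject, so the outermost cluster is the post, and anything
  inside it belongs to the subject.  The ROI bound is the device
  cluster's inner x face moved 1 cm further inward (`roi_margin`); the
  margin keeps grazing post returns out of the silhouette.
* **DBSCAN `min_points`** — 10 everywhere.  At SR4000 pixel pitch
  (≈8 mm at 1.8 m) a genuine surface patch has well over 10 points in a
  3 cm ball, while one-pixel-wide chains of grazing returns along
  silhouette edges have at most ~8 and are rejected as noise — a
  property the axilla detector relies on.
* ε = 0.03 is treated as meters; every other length in the chain is
  metric and a 3 cm density scale matches the sensor's point spacing.
* ROI calibration operates on the averaged cloud (the same input the
  rest of the chain sees); calibrating on raw frames would only add
  noise to a one-time estimate.

## Landmark detection

Dependency order: trunk/arm boundary → axillae → shoulders → C7-T1 →
spine profile → TK/LL/S1 → waist.  A failed prerequisite propagates a
recorded failure; detection never raises on odd anatomy and always
returns a total landmark set with per-landmark failure reasons.

* **Trunk/arm boundary** — a 4 cm horizontal band
  (`centroid_band_halfwidth = 0.02`) at the cloud's mean height,
  clustered with DBSCAN; the largest cluster is the torso, and its
  extreme lateral points are the auxiliary boundary points.
* **Axilla** — per side, the fragment beyond the auxiliary point is
  fitted with a least-squares plane `z = ax + by + c` (the plane
  predicts depth from frontal position; with the back facing the
  camera this is the only sensible regression direction).  Points
  *behind* the plane by at least `under_plane_threshold = 0.01` m are
  kept — the armpit fold recess is the dominant structure deeper than
  the arm/flank plane — clustered with DBSCAN, and the largest
  cluster's highest point is the axilla.  The 1 cm threshold is about
  3× the post-averaging noise and well below the ≥4 cm fold depth, so
  the margin on both sides is comfortable.
* **Shoulder** — highest point with |x − x(axilla)| ≤ 1 cm
  (`shoulder_belt_halfwidth`); ties broken toward the axilla x, then
  toward the camera.  The belt half-width matches the sensor's lateral
  pixel pitch: a wider belt systematically rides up the trapezius
  slope.
* **C7-T1** — cloud point nearest, in xy only, to the shoulder-line
  midpoint; ties by lowest point index.
* **Spine profile** — band |x − x(C7-T1)| ≤ 2.5 cm and y ≤ y(C7-T1)
  (`spine_band_halfwidth = 0.025`; about three pixel columns, enough
  points for a stable fit while staying near the midsagittal line; the
  band is fixed rather than following a curved spine line — on the
  frontal-plane-symmetric bodies considered here the midline is
  straight).  A degree-5 polynomial z(y) is fitted by least squares
  in numpy's scaled-domain basis (`Polynomial.fit`), which keeps the
  Vandermonde system well-conditioned over a ~0.5 m domain; raw
  power-basis coefficients are exposed via conversion.  Degree 5 is
  the default: 4 is the minimum able to carry two extrema plus an
  inflection below them, and one extra degree absorbs the sacral
  curvature without inviting edge oscillation.
* **TK / LL / S1** — critical points of the fitted polynomial from the
  companion-matrix eigenvalues of its derivative; roots closer than
  1e-9 are treated as coincident; only roots inside the fit domain
  count.  With z increasing away from the camera and the back toward
  it, the kyphotic apex is a z *minimum* and the lordotic apex a
  z *maximum*: TK is the minimum with the greatest y, LL the maximum
  below it, S1 the inflection (root of the second derivative) with the
  smallest y.  Each height is mapped to the cloud by restricting to a
  ±2 cm slab (`surface_slab_halfwidth`), taking the slab's x-extent
  midpoint as the lateral target, and returning the xy-nearest point.
* **Waist (WL/WR)** — no published procedure exists for these points,
  so this stage is this package's own design and is flagged as such in
  the logs.  Within y ∈ [y(S1), y(S1) + 0.6·(y(axilla) − y(S1))],
  restricted laterally to the torso x range (+1 cm) so hanging arms
  cannot masquerade as the silhouette edge, points are binned in 1 cm
  height bins; a bin is usable when at least 5 points support its edge
  estimate.  Per side, the extreme lateral |x| per bin forms a width
  profile, smoothed with a 3-bin moving average.  Because the ~8 mm
  lateral quantization flattens the trough into a staircase plateau,
  the waist bin is the *central* bin of the near-minimal plateau
  (within 2 mm of the minimum) rather than the bare argmin, which
  would bias toward the plateau's lower edge.  If the smoothed profile
  has less than 2 mm of relief the waist is reported as
  `waist_indistinct` rather than guessed.
* All argmax/argmin ties are broken deterministically (stated per
  step), so detection is bit-reproducible for a fixed input order.

## Synthetic back surfaces

The generator provides the study conditions under which the pipeline is
tested: a standing subject inside a device frame, pelvic tilt at
1 cycle/s, sensor noise, speckle outliers, and exact ground truth.

**Body model.**  A stylized parametric *relief*, not an anthropometric
mesh: every detection stage consumes only local geometry (folds,
extrema, silhouette widths), so a surface that reproduces those local
features suffices, and the repository stays free of mesh assets.
Horizontal cross-sections are shallow quartic reliefs
`z = z_mid(y) + 0.02·(|x|/w(y))⁴` — the silhouette edge recedes only
2 cm.  A full-depth elliptical torso would devote most of its depth
range to surface nearly parallel to the rays, which a ToF camera
barely samples; the shallow relief reproduces what the camera actually
sees of a back while keeping grazing-return artifacts at the
single-pixel level.  The half-width `w(y)` is a monotone (PCHIP)
interpolant through body stations at fixed fractions of stature
(lower-limb block 0.40, hip 0.56, waist ≈0.65, chest 0.81, neck base
0.845, crown of the modeled patch 0.88), so the waist knot is exactly
the width minimum.  The sagittal midline z(y) is a clamped C² cubic
spline through sacrum end, sacral-base knot (0.62), lordosis apex
(≈0.66, +3 cm), kyphosis apex (≈0.76, −2.5 cm) and neck, continued
*linearly* below the hip knot (zero curvature, so the lowest
inflection of the profile is guaranteed to be the sacral one).
Pelvic tilt shears the sub-lumbar midline about the lordosis knot by
`tilt_amplitude·sin(phase)` (default amplitude 6°), phase advancing at
1 cycle/s in sessions.  Arms are capsules (radius 4.5 cm, length
30 cm) pivoted just outside the torso near the axilla and abducted
outward by ≈22°; the posterior axillary fold is an explicit groove
(8 cm deep, 1.2 cm lateral scale) carved along the arm–torso seam,
ramping to full depth over 1 cm so that the fold attains its full
depth exactly at the ground-truth axilla.  The device frame
contributes two vertical posts at x = ±0.45 m (radius 2 cm).
An optional low-frequency sinusoidal perturbation
(`clothing_amplitude`, default off) emulates clothing folds around the
waist.

**Priors.**  Subjects are drawn from truncated normals.  Shoulder
width (38.4 ± 2.7 cm) and stature (174.2 cm) follow the reported
young-adult cohort anthropometry.  The hip prior is the reported
28.5 ± 1.9 cm *bi-cristal breadth* inflated by ~25% to 35.6 cm,
because the rendered quantity is the soft-tissue silhouette width at
the trochanter, not the skeletal breadth; the sampled waist half-width
is clamped strictly inside both shoulder and hip so the waist
indentation always exists.  Apex stations are expressed as fractions
of body height (the anatomically standard convention) with small
inter-subject jitter.

**Ground truth** is defined on the continuous surface, before
rendering: TK/LL are the extrema and S1 the lowest inflection of the
constructed midline, located by dense scan (1e-4 m grid); the waist is
the argmin of the width interpolant with edge point (±w, y, z); the
axilla is the full-depth onset of the fold groove; the shoulder is the
topmost surface point at the axilla's x (solved on the width and
capsule equations); C7-T1 is the midline point at the mean shoulder
height — in this stylized body the neck base is, by construction, at
shoulder-top height.

**Rendering.**  Pinhole ray-cast onto the 144 × 176 grid (FOV
43.6° × 34.6°): along each pixel ray the residual `g(z) = surface(uz,
vz) − z` changes sign at the first hit, found by a 4 mm coarse march
plus 30 bisection steps (residual < 1e-9 m).  Rays that bracket a
depth *discontinuity* (arm/torso occlusion seams) have no root; they
are dropped, mirroring the flying-pixel suppression of real ToF
pipelines.  Gaussian depth noise (default σ = 4 mm per raw frame, an
SR4000-class figure) and speckle outliers (default 1% of pixels,
displaced 0.1–0.5 m along their ray) perturb the depth; x and y move
with it, as depth errors of a ToF camera do.  Per-pixel labels
{subject, device, speckle} make segmentation precision/recall exactly
computable.  Within an averaging window the pose is frozen and the ten
frames are independent noise realizations of one ray-cast: this
isolates noise averaging from motion blur and keeps a 20-body study in
tens of seconds; sessions expose per-frame tilt phases and ground
truth for motion analyses.

**What passing does and does not show.**  The generator reproduces the
geometry and first-order noise of the acquisition, so recovery results
demonstrate the pipeline's logic, its parameter consistency, and its
noise robustness.  It does not model clothing in the default
conditions, soft-tissue deformation, asymmetric posture, ToF multipath
or amplitude-dependent noise, or inter-rater ambiguity; real-data
errors are dominated by exactly those factors, so synthetic recovery
numbers are a lower bound on real discrepancies, not a forecast.

## Validation statistics

* Consensus L0 = component-wise mean of the expert indications, xy
  only (indications are compared in the frontal plane; depth is stored
  but unused).
* Signed errors ΔL = (Δx, Δy) in mm; per-landmark means and sample
  SDs (n−1).  The published tables print signed values; the same
  convention is kept.
* Outlier removal: per landmark, the method's ΔL set is centered and
  projected on the eigenvectors of its 2 × 2 covariance (descending
  eigenvalue; sign fixed so each axis's largest-magnitude loading is
  positive); independently per component, values above Q3 + 1.5·IQR
  are flagged and the union removed.  The rule is deliberately
  one-sided, as specified for the source procedure; quartiles use the
  linear-interpolation convention (numpy default) — outlier *counts*
  depend on this choice, so it is fixed here.
* Pairwise average distance: mean over clouds of the xy Euclidean
  distance between two raters' indications, mm; the method-vs-all
  column is the mean of the three method-vs-expert values, and group
  summaries average that column over the axilla, shoulder and waist
  pairs.
* Friedman test: one test per landmark over k = 6 related groups (the
  three expert-pair distances and three method-expert distances), with
  blocks the clouds where all four raters marked the landmark.  This
  grouping is chosen because the published analysis reports a single
  W per landmark.  Mid-ranks for ties, the standard tie correction,
  p from χ²(k−1), Kendall's W = χ²/(n(k−1)); effect labels: < 0.1
  negligibly small, < 0.3 small, < 0.5 moderate, else large (the first
  two thresholds follow the published usage; the rest complete the
  conventional scale).

The study's own numerical tables depend on expert annotations that are
not distributable, so they are not reproduced numerically; the
aggregation code is instead exercised on the published per-pair
distance values (see `scripts/acceptance.py`), and the statistical
machinery is verified against `scipy.stats.friedmanchisquare` and
closed forms.

## Problem sizes and numerical conventions

* Recovery studies use 20 sampled bodies, one averaged window (10
  noise realizations) each — enough for stable per-landmark medians
  while a study completes in well under two minutes on one CPU.
* Dense-scan oracles use 1e-4 m grids on construction-side truth and
  ~1e5-point scans in tests; finer grids push the discrete second
  difference into floating-point round-off.
* Polynomial root finding: companion-matrix eigenvalues; imaginary
  parts below 1e-9 count as real; duplicate roots within 1e-9
  collapse.
* Quartiles: linear interpolation; sample SDs: n−1; all reported
  distances in mm at the precision of the tables they feed.

## Known limitations

* The estimator shape is training-free: `LandmarkDetector.fit`
  validates parameters only.  `predict` accepts one cloud or a
  sequence of clouds; a cloud is an `(n, 3)` array, not a feature
  matrix, which is unconventional for scikit-learn but keeps the
  stages composable in its pipelines.
* The waist procedure is this package's own; its errors are the
  largest of the ten landmarks, consistent with waist points being the
  hardest to place for human raters as well.
* Detection assumes a roughly frontal, laterally symmetric pose; the
  fixed spine band does not follow a laterally deviated spine, and
  strongly asymmetric arm postures can defeat the centroid-band
  torso/arm separation.
* No temporal tracking: each averaged cloud is processed
  independently.
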