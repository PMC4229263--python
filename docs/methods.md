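# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind facemocap, in the order of the measurement chain.

## Camera model and rig

Cameras are ideal pinholes: a world point `X` (mm) maps to pixels through
`x ~ K [R | t] X` with a single focal length (square pixels) and no lens
distortion. The default rig places six cameras in a symmetric "L" — a
horizontal arm at offsets (−600, −400, −200) mm and a vertical arm at
(+200, +400, +600) mm — in the plane 800 mm in front of the subject, all
aimed at the capture-volume centre. Defaults: 1360×1024 px sensor, focal
length 2400 px. These values are design choices of the simulator, set so
that the default observation noise of σ = 0.5 px produces reconstruction
errors of roughly 0.2 mm at the capture volume — the error scale of a
bench-validated commercial system — while keeping every marker of the face
volume inside at least three camera frusta. Real lenses add
distance-dependent bias through distortion; that physics is deliberately
not modeled, so the package makes no claim about absolute hardware
accuracy, only about the geometry/statistics chain.

## Synthetic scenes

All randomness flows from one top-level seed, split deterministically per
stage (`config.split_seed`); identical configuration + seed reproduces any
dataset byte for byte.

* **Wand sweep.** The calibration wand is a T-rod with three collinear
  markers at 100/150 mm spacings (the physical spacings are known to the
  operator but unpublished; these are configurable defaults). Each of the
  3000 frames (protocol minimum) draws a uniform random rigid pose inside
  a ±80 mm cube around the volume centre — the randomized orientations
  provide the non-coplanar spread the DLT solve needs.
* **Rod sessions.** Static mode holds one pose for 5 s (500 frames);
  dynamic mode moves the rod along smooth seeded sinusoids (±120 mm,
  ±25°) for 60 s, imitating hand-waving.
* **Face sessions.** The rest face is a synthetic 24-marker template
  (21 landmarks + 3 helmet markers) with exact left/right mirror symmetry;
  no published coordinates exist, so the template is an editable data file
  with anatomically plausible values. The published protocol names the 10
  expressions but not their amplitudes; per-landmark peak displacements
  (2–20 mm, largest for jaw drop) are design choices stored next to the
  registry. Each scheduled expression follows a raised-cosine
  onset(0.5 s)–hold(1 s)–offset(0.5 s) profile, so the configured peak is
  attained exactly during the hold. Head motion is smooth seeded
  sinusoidal rotation (±3°) and translation (±5 mm) near 0.25 Hz;
  helmet markers ride rigidly with the head and never deform.
* **Noise.** I.i.d. Gaussian pixel noise (default σ = 0.5 px) on every
  observation, plus an optional dropout rate standing in for detection
  failures. Visibility is frustum-based only; occlusion by the face is not
  modeled.

The helmet-marker triangle spans ~80 mm × ~55 mm. A tighter cluster would
be mechanically plausible too, but pixel noise on three nearly coincident
markers turns into orientation jitter that multiplies by the ~150 mm lever
arm to the lower face; the chosen spread keeps helmet-frame jitter below
the reconstruction noise floor.

## Calibration

Each camera is solved independently by the DLT from (3-D wand point, 2-D
observation) pairs, using the wand's surveyed positions from the session
manifest. Points are Hartley-normalized (centroid to origin, mean distance
√2 in the image, √3 in space) before the homogeneous least-squares solve;
the result is scaled so `‖P[2,:3]‖ = 1` and sign-fixed for positive
depths. Degenerate inputs (fewer than 6 points, near-coplanar spread)
raise a calibration error with a diagnostic. The systemic error is the RMS
over frames of (reconstructed wand spacing − manufactured spacing), using
at most 5000 frames (seeded subsample beyond that); the pass gate is
0.3 mm. A sweep shorter than 3000 frames warns but does not fail. Full
self-calibration (recovering camera poses from the wand alone, as the
commercial software does) is out of scope; the module's contract — wand
in, projections + gate out — is preserved.

## Triangulation, labeling, gaps

A marker seen by m ≥ 2 cameras is the smallest-singular-vector solution of
the 2m×4 homogeneous system; the reported residual is the RMS reprojection
error. Linear DLT without iterative refinement is the default: at this
noise scale the refinement changes positions by far less than the noise
floor (the equivalence is verified against a Levenberg–Marquardt oracle in
the tests). Two cameras suffice mathematically; the protocol's "at least
three cameras" rule is a QC flag, not a hard failure, so degraded sessions
remain analyzable. Frame-cloud batches sharing a visibility pattern are
triangulated in one stacked SVD for speed.

Labeling matches the first frame to a template layout by mutual nearest
neighbours (every template marker must claim a distinct point) and tracks
subsequent frames by nearest-neighbour gating with a maximum marker speed
of 500 mm/s (5 mm between frames at 100 Hz — generous for facial motion).
Unmatched frames become gaps; tracks re-acquire when the marker reappears
inside the gate. Gaps of at most 10 frames (0.1 s) are bridged by a cubic
spline through the present frames; edge gaps are never extrapolated.

## Reference frames

The helmet frame takes the marker centroid as origin; the third axis is
the marker-plane normal with its sign fixed toward the face at session
start and tracked for continuity thereafter; the first axis points from
the centroid toward marker 1, orthogonalized against the normal. The
published description fixes only "an origin and a plane"; centroid origin
and this axis completion are declared choices (marker-1 origin is a
one-line change). Landmark trajectories re-expressed per frame in this
frame are head-motion-free.

The anatomical frame is built once from the rest pose (mean over the
pre-expression rest window) in helmet coordinates and held fixed — the
helmet, not the face, provides dynamic stability, because no facial point
is static during expression. Y is the unit normal of the plane through
both tragi and the nasal midline point, oriented upward; X is the
sagittal-plane normal from right to left tragus (projected into the
horizontal plane); Z = X × Y points forward. The origin is the
intersection of the three planes, which places the coronal plane through
the left tragus and the sagittal plane through the nasal point. The "nasal
centre" is ambiguous between the columella root (I) and the nasal-dorsum
junction (K); I is the default (midline, and the natural reading of the
plane description), K is configurable.

## Kinematics

Positions are smoothed with a Savitzky–Golay filter (window 11 samples =
0.11 s, order 3) before differentiation; this preserves expression peak
amplitudes markedly better than a moving average of the same width.
Velocity and acceleration are second-order central differences at the
fixed 100 Hz rate, one-sided at the sequence ends. Per expression window,
the summary reports max deviation from rest, max |v|, max |a|, and the
moving direction as the unit displacement vector at peak deviation,
expressed on the signed anatomical axes. The 20 static parameters follow
the test-retest table: distances via Euclidean norm, angles at the middle
letter of the label, and "direction" interpreted as the X and Z components
of the unit vector from the first to the second landmark (the published
table never defines "direction"; this reading is declared openly).

## Accuracy statistics

At least 10 frames are sampled uniformly without replacement. Both the
signed mean error and the mean absolute error are reported (the protocol's
"average error" is ambiguous between them). The one-sample two-sided
t-test uses `t = (x̄ − ref)/(s/√n)`, df = n − 1. A constant series equal
to the reference reports t = 0, p = 1 (perfect agreement); a constant
biased series leaves t and p undefined rather than fabricated. Published
absolute hardware errors (0.19 mm, 0.29°, the 60–90 cm distance sweep)
depend on unmodeled lens physics and are never asserted; the test suite
validates the machinery through exactness at zero noise, monotonicity in
noise, and order-of-magnitude bands instead.

## Reliability

ICC(1,1) — one-way random effects, single measures — is computed from the
literal ANOVA mean squares. This form was selected because its F-based
interval arithmetic reproduces the published 95% bounds from the published
point ICCs at n = 19, k = 2 (verified in the acceptance tests); two-way
forms do not. Confidence bounds accept the point estimate alone, so
printed ICCs can be re-intervalled without raw data. Missing cells are
never imputed; subjects missing in either session are excluded pairwise
per parameter. Zero-variance tables yield NaN with a flag. The
variance-components cohort generator (between-subject SD 5 mm,
within-session SD 0.5 mm, n = 19, k = 2 by default, population
ICC = σ_b²/(σ_b²+σ_w²) ≈ 0.990) provides closed-form recovery targets.

## What the synthetic data does and does not show

Passing tests demonstrate that the geometry and statistics chain is
self-consistent: exact at zero noise, degrading monotonically and at the
expected scale with pixel noise, invariant to rigid motion, and
reproducing the published interval arithmetic. They do not demonstrate
hardware accuracy (no lens distortion, motion blur, marker-detection or
occlusion modeling), nor physiological realism of the expression
amplitudes, nor the published volunteer-cohort ICC values themselves,
which depend on real between-subject variability.

## Problem sizes

Default analysis sizes are chosen to match the protocol where stated:
3000-frame wand sweeps, 500-frame static and 6000-frame dynamic rod
sessions, ~2600-frame full expression sessions, 19-subject two-session
cohorts. Property tests that sweep noise levels use shorter sweeps
(800 frames) and sessions, which leaves their conclusions unchanged.
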