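# facemocap

Marker-based 3-D dynamic quantitative analysis of facial motion.

Objective assessment of facial-nerve function (e.g. grading facial palsy or
tracking recovery after surgery) needs quantitative, repeatable measurements
of how facial landmarks move — not a clinician's visual impression. This
package implements the complete measurement chain of a six-camera optical
motion-capture system for the face, for researchers who want to study,
validate, or extend such a system without the hardware:

* **Synthetic capture rig** — six pinhole cameras in a symmetric "L"
  (two perpendicular arms of three) at an 800 mm working distance, imaging
  at 100 frames/s. The simulated scenes are the ones the physical protocol
  uses: a calibration wand (three collinear markers at known spacings), a
  linear accuracy rod (176.84 mm between end markers), an L-shaped rod
  (90° corner), and a face bearing 21 reflective landmarks plus a rigid
  3-marker reference helmet, performing 10 standardized expressions under
  free head motion, with Gaussian pixel noise on every observation.
* **Calibration** — per-camera 3×4 projections `P = K[R|t]` estimated by
  the direct linear transform (DLT) with Hartley normalization from the
  wand sweep, gated by the *systemic error*: the RMS discrepancy between
  reconstructed and manufactured wand spacings must stay below 0.3 mm.
* **Reconstruction** — homogeneous linear triangulation of each marker
  from ≥ 2 cameras (markers seen by < 3 cameras carry a QC flag),
  template-based labeling, nearest-neighbour tracking, cubic gap filling.
* **Reference frames** — a head-fixed frame from the three helmet markers
  (centroid origin, marker-plane normal) removes rigid head motion; an
  anatomical frame built at rest (horizontal plane through both tragus
  points and the nasal midline point, sagittal plane through the nose,
  coronal plane through the left tragus) gives signed axes: X left "+",
  Y up "+", Z forward "+".
* **Kinematics** — per landmark and expression: maximal deviation from
  rest, maximal speed and acceleration (Savitzky–Golay smoothing, central
  differences), moving direction; plus the 20 static rest-pose parameters
  (8 distances, 4 angles, 8 direction components).
* **Accuracy validation** — the rod protocol: ≥ 10 randomly sampled frames
  measured against the manufactured reference, one-sample two-sided t-test
  `t = (x̄ − ref)/(s/√n)`, df = n − 1.
* **Reliability** — test-retest agreement via the one-way random-effects
  single-measures intraclass correlation coefficient

  `ICC(1,1) = (MSB − MSW) / (MSB + (k−1)·MSW)`

  with F-based 95% confidence bounds: `F = (1+(k−1)·ICC)/(1−ICC)`,
  lower bound from `F / F₀.₉₇₅(n−1, n(k−1))`, upper from
  `F · F₀.₉₇₅(n(k−1), n−1)`, each mapped back via `(F*−1)/(F*+k−1)`.

## Worked example

```python
from facemocap import (RunConfig, run_calibration, run_rod_protocol,
                       linear_rod, NoiseSpec)

cfg = RunConfig(seed=42)                       # one seed drives everything
rig, calibration, _ = run_calibration(cfg)     # 3000-frame wand sweep + DLT
print(calibration.systemic_error_mm)           # 0.2614 -> PASS (< 0.3 mm)

report = run_rod_protocol(rig, calibration, linear_rod(), "dynamic",
                          noise=NoiseSpec(cfg.sigma_px),
                          seed=cfg.stage_seed("rod_dynamic"))
print(report.mean, report.mean_abs_error)      # 176.9555  0.1473  (mm)
print(report.t_statistic, report.p_value)      # 1.57  0.152
```

The systemic error (0.26 mm) says the calibrated cameras reproduce the
wand geometry to a quarter millimetre at the default 0.5 px observation
noise. The rod report then measures a moving 176.84 mm rod through the full
chain: the mean of 10 randomly sampled frames is 176.96 mm, a mean absolute
error of 0.15 mm, and the t-test (p = 0.152 > 0.05) finds no significant
difference from the manufactured length. With noise set to zero the whole
chain is exact to ~1e-12 mm.

The `examples/` scripts walk through each capability (calibration, rod
accuracy, expression kinematics, ICC reliability) and print annotated
output; the `facemocap` CLI wraps the same library calls
(`facemocap demo` runs the entire chain end to end).

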