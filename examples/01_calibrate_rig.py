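"""Calibrate the six-camera rig from a simulated wand sweep.

A T-shaped wand with three collinear markers (100 mm and 150 mm spacings)
is swept through the capture volume for 3000 frames; each camera's 3x4
projection is then estimated by the direct linear transform, and the
systemic error — RMS discrepancy between reconstructed and manufactured
wand spacings — is checked against the 0.3 mm pass gate.
"""

from facemocap import NoiseSpec, calibrate_dlt, default_rig, simulate_wand_sweep, t_rod

rig = default_rig()
wand = t_rod()

sweep = simulate_wand_sweep(rig, wand, n_frames=3000, noise=NoiseSpec(0.5), seed=42)
result = calibrate_dlt(sweep, wand, seed=42)

print(f"cameras calibrated : {len(result.projections)}")
print(f"wand frames used   : {result.frames_used}")
print(f"systemic error     : {result.systemic_error_mm:.4f} mm")
print(f"gate (< {result.threshold_mm} mm)    : {'PASS' if result.passed else 'FAIL'}")
# The systemic error is the honest summary of calibration quality: with the
# default 0.5 px observation noise it sits around 0.25 mm, inside the gate.
# Rerun with NoiseSpec(0.0) and it collapses to ~1e-12 mm (an exact solve).
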