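"""Measure facial expression kinematics in anatomical coordinates.

A synthetic volunteer wearing the 3-marker reference helmet performs the
10 standardized expressions while the head moves freely. The chain
reconstructs all 24 markers, removes head motion via the helmet frame,
builds the anatomical frame (horizontal plane through the tragi and the
nasal point), and reports peak deviation / speed / acceleration and the
moving direction per active landmark.
"""

from facemocap import (
    HeadMotionSpec,
    NoiseSpec,
    RunConfig,
    analyze_session,
    load_expressions,
    load_face_template,
    run_calibration,
    simulate_expression_session,
)

cfg = RunConfig(seed=42)
rig, calibration, _ = run_calibration(cfg)

session = simulate_expression_session(
    load_face_template(), rig, load_expressions(),
    head_motion=HeadMotionSpec(cfg.head_rotation_deg, cfg.head_translation_mm),
    noise=NoiseSpec(cfg.sigma_px), seed=cfg.stage_seed("expressions"),
)
result = analyze_session(session, calibration, cfg)

print("static rest-pose measures (first rows):")
print(result["static_measures"].head(6).to_string(index=False))

print("\npeak kinematics of the brow lift (expression 1):")
brow = result["expression_summaries"].query("expression_index == 1")
print(brow[["landmark", "max_deviation_mm", "max_speed_mm_s", "direction_y"]]
      .to_string(index=False))
# direction_y near +1 confirms the brow markers move upward ("+" on the Y
# axis); max_deviation_mm recovers the simulated 7-8 mm lift amplitudes
# despite the rigid head motion that was removed by the helmet frame.
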