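"""High-level chains tying simulation, calibration, reconstruction and analysis.

These are the entry points the command-line interface and the example
scripts call; each stage remains individually usable from its own module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibrate import CalibrationResult, calibrate_dlt
from .camera import RigLayout, default_rig
from .config import RunConfig
from .frames import anatomical_frame, to_anatomical, to_helmet
from .kinematics import SmoothingSpec, expression_summary, static_measures
from .registries import (
    HELMET_MARKERS,
    ExpressionRegistry,
    load_expressions,
    load_face_template,
    load_landmarks,
)
from .reconstruct import fill_gaps, reconstruct_dataset
from .simulate import (
    CaptureDataset,
    ExpressionEvent,
    HeadMotionSpec,
    NoiseSpec,
    simulate_expression_session,
    simulate_wand_sweep,
    t_rod,
)

__all__ = ["build_rig", "run_calibration", "analyze_session", "session_schedule"]


def build_rig(config: RunConfig) -> RigLayout:
    return default_rig(config.working_distance_mm, config.focal_px)


def run_calibration(
    config: RunConfig, rig: RigLayout | None = None
) -> tuple[RigLayout, CalibrationResult, CaptureDataset]:
    """Wand sweep + DLT calibration at the configured noise level."""
    rig = rig or build_rig(config)
    wand = t_rod(config.wand_spacings_mm)
    sweep = simulate_wand_sweep(
        rig, wand, config.wand_frames,
        NoiseSpec(config.sigma_px, config.dropout_rate),
        seed=config.stage_seed("wand"),
    )
    calib = calibrate_dlt(sweep, wand, config.calibration_gate_mm,
                          seed=config.stage_seed("sampling"))
    return rig, calib, sweep


def session_schedule(dataset: CaptureDataset) -> list[ExpressionEvent]:
    """Recover the expression schedule echoed in a session manifest."""
    return [ExpressionEvent(**ev) for ev in dataset.manifest.get("schedule", [])]


def analyze_session(
    dataset: CaptureDataset,
    calibration: CalibrationResult,
    config: RunConfig,
    registry: ExpressionRegistry | None = None,
) -> dict:
    """Reconstruct an expression session and compute all kinematic outputs.

    Returns a dict with the anatomical-frame trajectories, the 20-parameter
    static measure table, and per-expression peak-kinematics summaries
    (tidy DataFrame, one row per landmark and expression).
    """
    registry = registry or load_expressions()
    schedule = session_schedule(dataset)
    trajs_world = reconstruct_dataset(dataset, calibration)
    trajs_world = {c: fill_gaps(t) for c, t in trajs_world.items()}
    trajs_helmet = to_helmet(trajs_world)
    rest_end = min((ev.start_s for ev in schedule), default=1.0)
    rest_window = (0.0, max(rest_end - 0.1, 0.1))
    rest_sl = slice(0, max(int(rest_window[1] * dataset.clock.frequency_hz), 1))
    rest = {
        c: t.positions[rest_sl][~t.gap_mask[rest_sl]].mean(axis=0)
        for c, t in trajs_helmet.items()
        if c not in HELMET_MARKERS and not t.gap_mask[rest_sl].all()
    }
    frame = anatomical_frame(rest, config.nasal_landmark)
    trajs_anat = to_anatomical(
        {c: t for c, t in trajs_helmet.items() if c not in HELMET_MARKERS}, frame
    )
    rest_anat = {c: frame.to_local(p)[0] for c, p in rest.items()}
    static = static_measures(rest_anat)

    smoothing = SmoothingSpec(config.smoothing_window, config.smoothing_polyorder)
    rows = []
    for ev in schedule:
        summaries = expression_summary(
            trajs_anat,
            ev.expression_index,
            (ev.start_s, ev.end_s),
            rest_window,
            landmarks=sorted(registry[ev.expression_index].active_landmarks),
            smoothing=smoothing,
        )
        rows.extend(s.as_dict() for s in summaries)
    dynamic = pd.DataFrame(rows)
    return {
        "trajectories_anatomical": trajs_anat,
        "anatomical_frame": frame,
        "rest_positions": rest_anat,
        "static_measures": static,
        "expression_summaries": dynamic,
    }
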