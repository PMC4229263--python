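"""Synthetic capture sessions: the virtual stand-in for the physical rig.

This module emulates what the hardware produces — per-camera 2-D marker
observations at 100 frames per second — for three kinds of scenes:

* a calibration wand (T-rod, three collinear markers at known spacings)
  swept through the capture volume,
* accuracy phantoms (a two-marker linear rod of known length and an L-rod
  with a right angle), static on a table or waved through the volume,
* a face bearing the 21 observational landmarks plus 3 rigid helmet
  markers, performing scheduled standardized expressions while the head
  moves freely.

Ground-truth 3-D positions are retained alongside the observations so the
downstream calibration / reconstruction / kinematics chain can be validated
by parameter recovery. All randomness (poses, head motion, pixel noise)
derives from a single seed; identical configuration and seed give identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .camera import CameraModel, RigLayout, project
from .registries import HELMET_MARKERS, ExpressionRegistry, FaceTemplate
from .trajectories import CaptureClock, Trajectory3D

__all__ = [
    "NoiseSpec",
    "RodPhantom",
    "linear_rod",
    "t_rod",
    "l_rod",
    "HeadMotionSpec",
    "ExpressionEvent",
    "CaptureDataset",
    "simulate_wand_sweep",
    "simulate_rod_session",
    "simulate_expression_session",
    "default_schedule",
]

LINEAR_ROD_LENGTH_MM = 176.84  # manufactured end-to-end reference length
L_ROD_ANGLE_DEG = 90.0         # manufactured corner angle


@dataclass(frozen=True)
class NoiseSpec:
    """Additive i.i.d. Gaussian pixel noise on every 2-D observation."""

    sigma_px: float = 0.5
    dropout_rate: float = 0.0   # chance an otherwise-visible observation is lost

    def __post_init__(self):
        if self.sigma_px < 0:
            raise ValueError("sigma_px must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class RodPhantom:
    """A rigid calibration/accuracy phantom with markers at known local coordinates."""

    kind: str                       # linear | T | L
    marker_ids: tuple[str, ...]
    local_mm: np.ndarray            # (n_markers, 3)
    reference_value: float          # mm for linear, degrees for L, mm max spacing for T

    def __post_init__(self):
        object.__setattr__(self, "local_mm", np.asarray(self.local_mm, dtype=float))


def linear_rod(length_mm: float = LINEAR_ROD_LENGTH_MM) -> RodPhantom:
    """Two-marker linear rod; end-to-end distance is the accuracy reference."""
    return RodPhantom(
        "linear", ("rodA", "rodB"),
        np.array([[0.0, 0.0, 0.0], [length_mm, 0.0, 0.0]]),
        length_mm,
    )


def t_rod(spacings_mm: tuple[float, float] = (100.0, 150.0)) -> RodPhantom:
    """Calibration wand: three collinear markers at the configured spacings."""
    s1, s2 = spacings_mm
    return RodPhantom(
        "T", ("wand1", "wand2", "wand3"),
        np.array([[0.0, 0.0, 0.0], [s1, 0.0, 0.0], [s1 + s2, 0.0, 0.0]]),
        s1 + s2,
    )


def l_rod(arms_mm: tuple[float, float] = (150.0, 100.0), angle_deg: float = L_ROD_ANGLE_DEG) -> RodPhantom:
    """L-shaped rod: corner marker plus one marker at each arm end."""
    a1, a2 = arms_mm
    th = np.radians(angle_deg)
    return RodPhantom(
        "L", ("armA", "corner", "armB"),
        np.array([[a1, 0.0, 0.0], [0.0, 0.0, 0.0], [a2 * np.cos(th), a2 * np.sin(th), 0.0]]),
        angle_deg,
    )


@dataclass(frozen=True)
class HeadMotionSpec:
    """Smooth rigid head motion: sinusoidal rotation + translation with seeded phases."""

    rotation_amplitude_deg: float = 3.0
    translation_amplitude_mm: float = 5.0
    frequency_hz: float = 0.25

    def poses(self, times: np.ndarray, rng: np.random.Generator):
        """Per-frame (R, t): rotations (n,3,3) and translations (n,3)."""
        n = len(times)
        if self.rotation_amplitude_deg == 0 and self.translation_amplitude_mm == 0:
            return np.broadcast_to(np.eye(3), (n, 3, 3)).copy(), np.zeros((n, 3))
        phases = rng.uniform(0, 2 * np.pi, size=6)
        freqs = self.frequency_hz * rng.uniform(0.7, 1.3, size=6)
        ang = np.radians(self.rotation_amplitude_deg) * np.sin(
            2 * np.pi * freqs[:3, None] * times[None, :] + phases[:3, None]
        )  # (3, n) roll/pitch/yaw
        trans = self.translation_amplitude_mm * np.sin(
            2 * np.pi * freqs[3:, None] * times[None, :] + phases[3:, None]
        ).T
        return _euler_xyz(ang[0], ang[1], ang[2]), trans


def _euler_xyz(rx, ry, rz) -> np.ndarray:
    """Batch rotation matrices R = Rz @ Ry @ Rx for angle arrays (n,)."""
    cx, sx, cy, sy, cz, sz = np.cos(rx), np.sin(rx), np.cos(ry), np.sin(ry), np.cos(rz), np.sin(rz)
    n = len(np.atleast_1d(cx))
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = cz * cy
    R[:, 0, 1] = cz * sy * sx - sz * cx
    R[:, 0, 2] = cz * sy * cx + sz * sx
    R[:, 1, 0] = sz * cy
    R[:, 1, 1] = sz * sy * sx + cz * cx
    R[:, 1, 2] = sz * sy * cx - cz * sx
    R[:, 2, 0] = -sy
    R[:, 2, 1] = cy * sx
    R[:, 2, 2] = cy * cx
    return R


@dataclass(frozen=True)
class ExpressionEvent:
    """One scheduled expression with a raised-cosine onset-hold-offset profile."""

    expression_index: int
    start_s: float
    onset_s: float = 0.5
    hold_s: float = 1.0
    offset_s: float = 0.5

    @property
    def end_s(self) -> float:
        return self.start_s + self.onset_s + self.hold_s + self.offset_s

    def activation(self, times: np.ndarray) -> np.ndarray:
        """Profile in [0, 1]: raised-cosine ramps around a full-amplitude hold."""
        t = np.asarray(times, dtype=float) - self.start_s
        act = np.zeros_like(t)
        up = (t >= 0) & (t < self.onset_s)
        act[up] = 0.5 * (1 - np.cos(np.pi * t[up] / self.onset_s))
        hold = (t >= self.onset_s) & (t < self.onset_s + self.hold_s)
        act[hold] = 1.0
        down = (t >= self.onset_s + self.hold_s) & (t < self.onset_s + self.hold_s + self.offset_s)
        td = t[down] - self.onset_s - self.hold_s
        act[down] = 0.5 * (1 + np.cos(np.pi * td / self.offset_s))
        return act


def default_schedule(registry: ExpressionRegistry, rest_s: float = 1.0, gap_s: float = 0.5) -> list[ExpressionEvent]:
    """All registered expressions in order, separated by rest gaps, after an
    initial rest window used as the kinematic baseline."""
    events, t = [], rest_s
    for idx in registry.indices:
        ev = ExpressionEvent(idx, t)
        events.append(ev)
        t = ev.end_s + gap_s
    return events


@dataclass
class CaptureDataset:
    """One simulated capture: observations + ground truth + provenance.

    ``observations``: frame, camera_id, marker_id, u_px, v_px
    ``truth``:        frame, marker_id, x_mm, y_mm, z_mm
    """

    observations: pd.DataFrame
    truth: pd.DataFrame
    clock: CaptureClock
    manifest: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return int(self.truth["frame"].max()) + 1 if len(self.truth) else 0

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.truth["marker_id"]))

    def camera_counts(self) -> pd.DataFrame:
        """Observing-camera count per (frame, marker); the hardware protocol
        expects every marker to be seen by at least three cameras."""
        c = (
            self.observations.groupby(["frame", "marker_id"], sort=True, observed=True)
            .size()
            .rename("n_cameras")
            .reset_index()
        )
        full = pd.MultiIndex.from_product(
            [range(self.n_frames), self.marker_ids], names=["frame", "marker_id"]
        ).to_frame(index=False)
        out = full.merge(c, on=["frame", "marker_id"], how="left").fillna({"n_cameras": 0})
        out["n_cameras"] = out["n_cameras"].astype(int)
        out["qc_under_three"] = out["n_cameras"] < 3
        return out

    def visibility_ok(self) -> bool:
        return not bool(self.camera_counts()["qc_under_three"].any())

    def truth_trajectory(self, marker_id: str) -> Trajectory3D:
        sub = self.truth[self.truth["marker_id"] == marker_id].sort_values("frame")
        pos = np.full((self.n_frames, 3), np.nan)
        pos[sub["frame"].to_numpy()] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy()
        return Trajectory3D(marker_id, pos, self.clock)


def _observe(
    rig: RigLayout,
    truth_xyz: np.ndarray,          # (n_frames, n_markers, 3)
    marker_ids: tuple[str, ...],
    clock: CaptureClock,
    noise: NoiseSpec,
    rng: np.random.Generator,
    manifest: dict,
) -> CaptureDataset:
    """Project ground truth through every camera, add noise, apply visibility."""
    n_frames, n_markers, _ = truth_xyz.shape
    flat = truth_xyz.reshape(-1, 3)
    frames = np.repeat(np.arange(n_frames), n_markers)
    mk = np.tile(np.asarray(marker_ids, dtype=object), n_frames)

    obs_parts = []
    for cam in rig.cameras:
        uv = project(cam, flat, strict=False)
        visible = np.all(np.isfinite(uv), axis=1) & cam.in_image(uv)
        if noise.sigma_px > 0:
            uv = uv + rng.normal(0.0, noise.sigma_px, size=uv.shape)
        if noise.dropout_rate > 0:
            visible &= rng.random(len(uv)) >= noise.dropout_rate
        obs_parts.append(
            pd.DataFrame(
                {
                    "frame": frames[visible],
                    "camera_id": cam.camera_id,
                    "marker_id": mk[visible],
                    "u_px": uv[visible, 0],
                    "v_px": uv[visible, 1],
                }
            )
        )
    observations = (
        pd.concat(obs_parts, ignore_index=True)
        .sort_values(["frame", "camera_id", "marker_id"], kind="stable")
        .reset_index(drop=True)
    )
    truth = pd.DataFrame(
        {
            "frame": frames,
            "marker_id": mk,
            "x_mm": flat[:, 0],
            "y_mm": flat[:, 1],
            "z_mm": flat[:, 2],
        }
    )
    return CaptureDataset(observations, truth, clock, manifest)


def _random_pose(rng: np.random.Generator, span_mm: float):
    ang = rng.uniform(-np.pi, np.pi, size=3)
    R = _euler_xyz(*(a[None] for a in ang))[0]
    t = rng.uniform(-span_mm, span_mm, size=3)
    return R, t


def simulate_wand_sweep(
    rig: RigLayout,
    wand: RodPhantom | None = None,
    n_frames: int = 3000,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    span_mm: float = 80.0,
) -> CaptureDataset:
    """Sweep the calibration wand through the working volume.

    Each frame places the wand at a random rigid pose inside a cube of
    half-side ``span_mm`` around the volume centre, imitating the horizontal
    and vertical sweeps of a hand-held wand; the randomized orientations
    give the non-coplanar point spread the calibration solve needs. The
    hardware protocol calls for at least 3000 frames per camera.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    wand = wand if wand is not None else t_rod()
    rng = np.random.default_rng(seed)
    clock = CaptureClock()
    centre = rig.volume_center
    xyz = np.empty((n_frames, len(wand.marker_ids), 3))
    for i in range(n_frames):
        R, t = _random_pose(rng, span_mm)
        # keep the whole wand inside the volume: centre it on its midpoint
        local = wand.local_mm - wand.local_mm.mean(axis=0)
        xyz[i] = local @ R.T + centre + t
    manifest = {
        "session": "wand_sweep",
        "wand_kind": wand.kind,
        "n_frames": n_frames,
        "sigma_px": noise.sigma_px,
        "seed": seed,
        "span_mm": span_mm,
    }
    return _observe(rig, xyz, wand.marker_ids, clock, noise, rng, manifest)


def simulate_rod_session(
    rig: RigLayout,
    rod: RodPhantom,
    mode: str = "static",
    duration_s: float = 5.0,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
) -> CaptureDataset:
    """Accuracy-phantom session: rod on a table (static) or waved (dynamic).

    Static mode holds one centred pose for the whole session (about 5 s in
    the bench protocol); dynamic mode moves the rod smoothly through the
    volume for about a minute. Frame count is duration x 100 Hz.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if mode not in ("static", "dynamic"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    clock = CaptureClock()
    n_frames = int(round(duration_s * clock.frequency_hz))
    times = clock.times(n_frames)
    local = rod.local_mm - rod.local_mm.mean(axis=0)
    if mode == "static":
        R0 = _euler_xyz(np.array([0.15]), np.array([0.1]), np.array([0.05]))[0]
        xyz = np.broadcast_to(local @ R0.T + rig.volume_center, (n_frames, len(local), 3)).copy()
    else:
        motion = HeadMotionSpec(rotation_amplitude_deg=25.0, translation_amplitude_mm=120.0,
                                frequency_hz=0.2)
        Rs, ts = motion.poses(times, rng)
        xyz = np.einsum("nij,mj->nmi", Rs, local) + (rig.volume_center + ts)[:, None, :]
    manifest = {
        "session": "rod",
        "rod_kind": rod.kind,
        "mode": mode,
        "duration_s": duration_s,
        "reference_value": rod.reference_value,
        "sigma_px": noise.sigma_px,
        "seed": seed,
    }
    return _observe(rig, xyz, rod.marker_ids, clock, noise, rng, manifest)


def simulate_expression_session(
    face: FaceTemplate,
    rig: RigLayout,
    registry: ExpressionRegistry,
    schedule: list[ExpressionEvent] | None = None,
    head_motion: HeadMotionSpec = HeadMotionSpec(),
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    amplitude_scale: float = 1.0,
) -> CaptureDataset:
    """A full facial measuring session.

    Landmarks follow rigid head motion composed with the scheduled
    expression displacement fields (raised-cosine onset-hold-offset); the
    three helmet markers follow head motion only, as they ride rigidly on
    the skull. Returns observations plus ground-truth trajectories.
    """
    schedule = schedule if schedule is not None else default_schedule(registry)
    for ev in schedule:
        if ev.expression_index not in registry.indices:
            raise KeyError(f"schedule references unregistered expression {ev.expression_index}")
    rng = np.random.default_rng(seed)
    clock = CaptureClock()
    duration = max((ev.end_s for ev in schedule), default=1.0) + 0.5
    n_frames = int(round(duration * clock.frequency_hz))
    times = clock.times(n_frames)

    marker_ids = tuple(face.positions)
    rest = face.array(marker_ids)                      # (m, 3) head frame
    disp = np.zeros((n_frames, len(marker_ids), 3))
    idx_of = {m: i for i, m in enumerate(marker_ids)}
    for ev in schedule:
        act = ev.activation(times)
        for lm, vec in registry[ev.expression_index].displacements.items():
            if lm in idx_of:  # helmet markers never deform
                disp[:, idx_of[lm], :] += act[:, None] * (amplitude_scale * vec)
    head_pts = rest[None, :, :] + disp                 # head-fixed coordinates
    Rs, ts = head_motion.poses(times, rng)
    xyz = np.einsum("nij,nmj->nmi", Rs, head_pts) + ts[:, None, :] + rig.volume_center

    manifest = {
        "session": "expressions",
        "n_frames": n_frames,
        "schedule": [
            {"expression_index": ev.expression_index, "start_s": ev.start_s,
             "onset_s": ev.onset_s, "hold_s": ev.hold_s, "offset_s": ev.offset_s}
            for ev in schedule
        ],
        "head_rotation_deg": head_motion.rotation_amplitude_deg,
        "head_translation_mm": head_motion.translation_amplitude_mm,
        "sigma_px": noise.sigma_px,
        "seed": seed,
        "amplitude_scale": amplitude_scale,
    }
    return _observe(rig, xyz, marker_ids, clock, noise, rng, manifest)
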