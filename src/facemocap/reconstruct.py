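"""Triangulation of 2-D observations into labeled 3-D trajectories.

A marker observed by two or more calibrated cameras is located by
homogeneous linear least squares (the DLT point solve): each camera
contributes two rows u (p3 . X) - p1 . X = 0, v (p3 . X) - p2 . X = 0 and
the point is the smallest-singular-vector solution. Two cameras suffice
mathematically; markers seen by fewer than three carry a soft QC flag,
since the capture protocol is designed so every marker is seen by at least
three cameras.

Unlabeled per-frame point clouds are attached to marker labels by matching
against a template layout in the first frame (mutual nearest neighbours)
and by nearest-neighbour gating frame to frame, with a maximum plausible
marker speed setting the gate width. Short gaps can be bridged by cubic
interpolation; gaps at the sequence edge are never extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .trajectories import CaptureClock, Trajectory3D

__all__ = [
    "FrameCloud",
    "triangulate",
    "triangulate_table",
    "reconstruct_dataset",
    "label_and_track",
    "fill_gaps",
    "LabelingError",
]

V_MAX_MM_S = 500.0     # gating speed for frame-to-frame tracking


class LabelingError(RuntimeError):
    """Ambiguous or impossible marker-label assignment."""


@dataclass
class FrameCloud:
    """Unlabeled triangulated points of one frame."""

    frame: int
    points: np.ndarray          # (n, 3) mm
    n_cameras: np.ndarray       # (n,) observing-camera count per point

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.n_cameras = np.asarray(self.n_cameras, dtype=int).reshape(-1)

    @property
    def qc_under_three(self) -> np.ndarray:
        return self.n_cameras < 3


def triangulate(
    observations: dict[str, np.ndarray],
    projections: dict[str, np.ndarray],
) -> tuple[np.ndarray, float]:
    """Triangulate one marker from per-camera pixel observations.

    Returns the 3-D point (mm) and the RMS reprojection residual (px).
    Raises ValueError with fewer than two observing cameras.
    """
    cams = [c for c in observations if c in projections]
    if len(cams) < 2:
        raise ValueError(f"need >= 2 observing cameras, got {len(cams)}")
    A = np.empty((2 * len(cams), 4))
    for i, c in enumerate(cams):
        P = projections[c]
        u, v = observations[c]
        A[2 * i] = u * P[2] - P[0]
        A[2 * i + 1] = v * P[2] - P[1]
    _, _, Vt = np.linalg.svd(A)
    Xh = Vt[-1]
    if abs(Xh[3]) < 1e-15:
        raise ValueError("triangulation degenerate: point at infinity")
    X = Xh[:3] / Xh[3]
    res = []
    for c in cams:
        P = projections[c]
        xh = P @ np.append(X, 1.0)
        res.append(xh[:2] / xh[2] - observations[c])
    residual = float(np.sqrt(np.mean(np.square(np.concatenate(res)))))
    return X, residual


def triangulate_table(observations: pd.DataFrame, projections: dict[str, np.ndarray]) -> pd.DataFrame:
    """Vectorized triangulation of an observations table.

    ``observations`` has columns (frame, camera_id, marker_id, u_px, v_px);
    returns one row per (frame, marker_id) with >= 2 observing cameras:
    (frame, marker_id, x_mm, y_mm, z_mm, n_cameras, residual_px). Rows are
    batched by visibility pattern so each batch is one stacked SVD.
    """
    cam_ids = [c for c in sorted(projections)]
    Ps = np.stack([projections[c] for c in cam_ids])            # (C, 3, 4)
    wide_u = observations.pivot_table(index=["frame", "marker_id"], columns="camera_id",
                                      values="u_px", aggfunc="first")
    wide_v = observations.pivot_table(index=["frame", "marker_id"], columns="camera_id",
                                      values="v_px", aggfunc="first")
    wide_u = wide_u.reindex(columns=cam_ids)
    wide_v = wide_v.reindex(columns=cam_ids)
    U = wide_u.to_numpy()
    V = wide_v.to_numpy()
    seen = np.isfinite(U)                                        # (N, C)
    n_cams = seen.sum(axis=1)

    out_x = np.full(len(U), np.nan)
    out_y = np.full(len(U), np.nan)
    out_z = np.full(len(U), np.nan)
    out_res = np.full(len(U), np.nan)
    # batch rows sharing a visibility pattern: one (N, 2m, 4) SVD per pattern
    patterns: dict[bytes, list[int]] = {}
    for i, row in enumerate(seen):
        if n_cams[i] >= 2:
            patterns.setdefault(row.tobytes(), []).append(i)
    for key, idx in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        sel = np.asarray(idx)
        cams = np.where(mask)[0]
        m = len(cams)
        u = U[np.ix_(sel, cams)]                                # (N, m)
        v = V[np.ix_(sel, cams)]
        P = Ps[cams]                                            # (m, 3, 4)
        A = np.empty((len(sel), 2 * m, 4))
        A[:, 0::2, :] = u[:, :, None] * P[None, :, 2, :] - P[None, :, 0, :]
        A[:, 1::2, :] = v[:, :, None] * P[None, :, 2, :] - P[None, :, 1, :]
        _, _, Vt = np.linalg.svd(A)
        Xh = Vt[:, -1, :]                                       # (N, 4)
        w = Xh[:, 3]
        w = np.where(np.abs(w) < 1e-15, np.nan, w)
        X = Xh[:, :3] / w[:, None]
        out_x[sel], out_y[sel], out_z[sel] = X[:, 0], X[:, 1], X[:, 2]
        # reprojection residuals
        Xw = np.concatenate([X, np.ones((len(sel), 1))], axis=1)
        proj = np.einsum("mij,nj->nmi", P, Xw)                  # (N, m, 3)
        uv = proj[:, :, :2] / proj[:, :, [2]]
        d = uv - np.stack([u, v], axis=2)
        out_res[sel] = np.sqrt(np.mean(d ** 2, axis=(1, 2)))

    idx_frame = wide_u.index.get_level_values("frame").to_numpy()
    idx_marker = wide_u.index.get_level_values("marker_id").to_numpy()
    ok = n_cams >= 2
    return pd.DataFrame(
        {
            "frame": idx_frame[ok],
            "marker_id": idx_marker[ok],
            "x_mm": out_x[ok],
            "y_mm": out_y[ok],
            "z_mm": out_z[ok],
            "n_cameras": n_cams[ok].astype(int),
            "residual_px": out_res[ok],
        }
    ).sort_values(["frame", "marker_id"], kind="stable").reset_index(drop=True)


def reconstruct_dataset(dataset, calibration) -> dict[str, Trajectory3D]:
    """Triangulate a labeled capture dataset into per-marker trajectories.

    Frames where a marker is seen by fewer than two cameras become gaps.
    """
    table = triangulate_table(dataset.observations, calibration.projections)
    n_frames = dataset.n_frames
    out: dict[str, Trajectory3D] = {}
    for mk in dataset.marker_ids:
        sub = table[table["marker_id"] == mk]
        pos = np.full((n_frames, 3), np.nan)
        ncam = np.zeros(n_frames, dtype=int)
        res = np.full(n_frames, np.nan)
        f = sub["frame"].to_numpy()
        pos[f] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy()
        ncam[f] = sub["n_cameras"].to_numpy()
        res[f] = sub["residual_px"].to_numpy()
        out[mk] = Trajectory3D(mk, pos, dataset.clock, None, ncam, res)
    return out


def _mutual_nearest(template: np.ndarray, points: np.ndarray) -> dict[int, int]:
    """Mutual-nearest-neighbour assignment template-row -> point-row."""
    d = np.linalg.norm(template[:, None, :] - points[None, :, :], axis=2)
    t_best = d.argmin(axis=1)
    p_best = d.argmin(axis=0)
    pairs = {ti: pi for ti, pi in enumerate(t_best) if p_best[pi] == ti}
    # a cloud point claimed by two template points would have broken mutuality,
    # but guard against duplicates anyway
    if len(set(pairs.values())) != len(pairs):
        raise LabelingError("ambiguous initial assignment: one point claimed twice")
    return pairs


def label_and_track(
    clouds: list[FrameCloud],
    template: dict[str, np.ndarray],
    clock: CaptureClock | None = None,
    v_max_mm_s: float = V_MAX_MM_S,
) -> dict[str, Trajectory3D]:
    """Attach marker labels to a sequence of unlabeled frame clouds.

    The first frame is matched to the expected template layout by mutual
    nearest neighbours (every template marker must find a distinct point);
    each later frame is matched to the previous labeled position with a
    nearest-neighbour gate of v_max / frame-rate. Unmatched frames become
    gaps and the track re-acquires when the marker reappears inside the gate.
    """
    clock = clock or CaptureClock()
    labels = list(template)
    tpl = np.stack([np.asarray(template[c], dtype=float) for c in labels])
    if len(clouds) == 0:
        raise LabelingError("no frames to label")
    first = clouds[0]
    if len(first.points) < len(labels):
        raise LabelingError(
            f"first frame has {len(first.points)} points but template expects {len(labels)}"
        )
    pairs = _mutual_nearest(tpl, first.points)
    if len(pairs) != len(labels):
        missing = [labels[i] for i in range(len(labels)) if i not in pairs]
        raise LabelingError(f"initial assignment failed for {missing}")

    n_frames = len(clouds)
    gate = v_max_mm_s / clock.frequency_hz
    pos = np.full((len(labels), n_frames, 3), np.nan)
    ncam = np.zeros((len(labels), n_frames), dtype=int)
    last = np.empty((len(labels), 3))
    for ti, pi in pairs.items():
        pos[ti, 0] = first.points[pi]
        ncam[ti, 0] = first.n_cameras[pi]
        last[ti] = first.points[pi]

    for fi in range(1, n_frames):
        cloud = clouds[fi]
        if len(cloud.points) == 0:
            continue
        d = np.linalg.norm(last[:, None, :] - cloud.points[None, :, :], axis=2)
        # greedy nearest within gate, each cloud point used once
        order = np.argsort(d, axis=None)
        taken_t: set[int] = set()
        taken_p: set[int] = set()
        for flat in order:
            ti, pi = divmod(int(flat), len(cloud.points))
            if d[ti, pi] > gate:
                break
            if ti in taken_t or pi in taken_p:
                continue
            taken_t.add(ti)
            taken_p.add(pi)
            pos[ti, fi] = cloud.points[pi]
            ncam[ti, fi] = cloud.n_cameras[pi]
            last[ti] = cloud.points[pi]
    return {
        lab: Trajectory3D(lab, pos[i], clock, None, ncam[i], None)
        for i, lab in enumerate(labels)
    }


def fill_gaps(trajectory: Trajectory3D, max_gap_frames: int = 10) -> Trajectory3D:
    """Bridge short interior gaps by cubic-spline interpolation.

    Gaps longer than ``max_gap_frames`` and gaps touching either end of the
    sequence are left flagged (interpolation only, never extrapolation).
    """
    out = trajectory.copy()
    gaps = out.gap_mask
    if not gaps.any():
        return out
    present = np.where(~gaps)[0]
    if len(present) < 2:
        return out
    spline = CubicSpline(present, out.positions[present], axis=0)
    # enumerate interior gap runs
    idx = np.where(gaps)[0]
    runs = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
    for run in runs:
        if len(run) == 0 or len(run) > max_gap_frames:
            continue
        if run[0] == 0 or run[-1] == len(gaps) - 1:
            continue  # edge gap: refuse to extrapolate
        out.positions[run] = spline(run)
        out.gap_mask[run] = False
    return out
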