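"""Camera calibration from wand sweeps via the direct linear transform.

Each camera's 3x4 projection is estimated (up to scale) from 3-D/2-D
correspondences between the wand's surveyed marker positions and its image
observations, with Hartley-style normalization for numerical conditioning.
After solving, a *systemic error* is computed the way a capture operator
checks a rig: the wand markers are triangulated back from the estimated
cameras and the root-mean-square discrepancy between reconstructed and
manufactured inter-marker distances is compared against a pass gate
(default 0.3 mm). The bench protocol also expects at least 3000 wand frames
per camera; fewer raises a warning, not a failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import CaptureDataset, RodPhantom

__all__ = [
    "CalibrationError",
    "CalibrationResult",
    "estimate_projection",
    "calibrate_dlt",
    "check_frame_budget",
    "FRAME_BUDGET",
    "SYSTEMIC_ERROR_GATE_MM",
]

FRAME_BUDGET = 3000                 # minimum wand frames per camera
SYSTEMIC_ERROR_GATE_MM = 0.3        # calibration pass gate
_SYSTEMIC_SAMPLE_CAP = 5000         # frames used for the error estimate


class CalibrationError(RuntimeError):
    """Too few or degenerate correspondences for a camera solve."""


@dataclass
class CalibrationResult:
    """Estimated projections plus the systemic-error gate outcome."""

    projections: dict[str, np.ndarray]      # camera_id -> 3x4 (scale-normalized)
    systemic_error_mm: float
    frames_used: int
    threshold_mm: float = SYSTEMIC_ERROR_GATE_MM
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.systemic_error_mm < self.threshold_mm

    @property
    def camera_ids(self) -> tuple[str, ...]:
        return tuple(self.projections)


def _normalize_2d(x: np.ndarray):
    c = x.mean(axis=0)
    d = np.mean(np.linalg.norm(x - c, axis=1))
    s = np.sqrt(2.0) / d if d > 0 else 1.0
    T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]])
    return (x - c) * s, T


def _normalize_3d(X: np.ndarray):
    c = X.mean(axis=0)
    d = np.mean(np.linalg.norm(X - c, axis=1))
    s = np.sqrt(3.0) / d if d > 0 else 1.0
    U = np.eye(4)
    U[:3, :3] *= s
    U[:3, 3] = -s * c
    return (X - c) * s, U


def estimate_projection(points3d: np.ndarray, points2d: np.ndarray) -> np.ndarray:
    """DLT solve of one camera's 3x4 projection from >= 6 correspondences.

    Points are Hartley-normalized before the homogeneous least-squares solve;
    the result is de-normalized and scaled so that ||P[2, :3]|| = 1 (which
    makes P @ [X, 1] produce true depth in its third coordinate).
    """
    X = np.asarray(points3d, dtype=float)
    x = np.asarray(points2d, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or x.shape != (len(X), 2):
        raise CalibrationError("correspondences must be (n,3) world and (n,2) image points")
    if len(X) < 6:
        raise CalibrationError(f"need >= 6 correspondences, got {len(X)}")
    # coplanar world points make the DLT rank-deficient
    sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    if sv[2] < 1e-6 * max(sv[0], 1.0):
        raise CalibrationError("world points are (near-)coplanar; sweep the wand through depth")

    Xn, U = _normalize_3d(X)
    xn, T = _normalize_2d(x)
    n = len(Xn)
    Xh = np.hstack([Xn, np.ones((n, 1))])
    A = np.zeros((2 * n, 12))
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -xn[:, [0]] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -xn[:, [1]] * Xh
    _, _, Vt = np.linalg.svd(A, full_matrices=False)
    Pn = Vt[-1].reshape(3, 4)
    P = np.linalg.inv(T) @ Pn @ U
    scale = np.linalg.norm(P[2, :3])
    P = P / scale
    # fix overall sign so reconstructed depths are positive
    Xc = np.hstack([X, np.ones((n, 1))]) @ P.T
    if np.median(Xc[:, 2]) < 0:
        P = -P
    return P


def calibrate_dlt(
    dataset: CaptureDataset,
    wand: RodPhantom,
    threshold_mm: float = SYSTEMIC_ERROR_GATE_MM,
    seed: int = 0,
) -> CalibrationResult:
    """Calibrate every camera of a wand-sweep dataset and gate the result.

    The wand's true 3-D positions come from the dataset's truth table (the
    surveyed wand geometry the operator enters before calibration); each
    camera is solved independently by DLT from its own observations.
    """
    from .reconstruct import triangulate_table  # local import: avoids a cycle

    warnings = list(check_frame_budget(dataset.n_frames)[1])
    truth = dataset.truth.set_index(["frame", "marker_id"])
    projections: dict[str, np.ndarray] = {}
    for cam_id, obs in dataset.observations.groupby("camera_id", sort=True):
        keys = list(zip(obs["frame"], obs["marker_id"]))
        X = truth.loc[keys][["x_mm", "y_mm", "z_mm"]].to_numpy()
        x = obs[["u_px", "v_px"]].to_numpy()
        try:
            projections[cam_id] = estimate_projection(X, x)
        except CalibrationError as e:
            raise CalibrationError(f"camera {cam_id}: {e}") from e
    if not projections:
        raise CalibrationError("dataset has no observations")

    # systemic error: wand inter-marker distances after reconstruction
    spacings = np.linalg.norm(np.diff(wand.local_mm, axis=0), axis=1)
    obs = dataset.observations
    if dataset.n_frames > _SYSTEMIC_SAMPLE_CAP:
        keep = np.sort(
            np.random.default_rng(seed).choice(
                np.arange(dataset.n_frames), _SYSTEMIC_SAMPLE_CAP, replace=False
            )
        )
        obs = obs[obs["frame"].isin(keep)]
    table = triangulate_table(obs, projections)
    wide = table.pivot_table(index="frame", columns="marker_id",
                             values=["x_mm", "y_mm", "z_mm"], aggfunc="first")
    devs = []
    ids = wand.marker_ids
    for i, d_ref in enumerate(spacings):
        a, b = ids[i], ids[i + 1]
        try:
            pa = wide.loc[:, [("x_mm", a), ("y_mm", a), ("z_mm", a)]].to_numpy()
            pb = wide.loc[:, [("x_mm", b), ("y_mm", b), ("z_mm", b)]].to_numpy()
        except KeyError:
            continue
        d = np.linalg.norm(pa - pb, axis=1)
        devs.append(d[np.isfinite(d)] - d_ref)
    if not devs or not len(np.concatenate(devs)):
        raise CalibrationError("no frame had enough observations to reconstruct the wand")
    systemic = float(np.sqrt(np.mean(np.square(np.concatenate(devs)))))
    return CalibrationResult(projections, systemic, dataset.n_frames, threshold_mm, warnings)


def check_frame_budget(n_frames: int) -> tuple[bool, list[str]]:
    """Soft gate on the wand-sweep length: below 3000 frames warn, never fail."""
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    if n_frames == 0:
        return False, ["empty wand sweep: no frames recorded"]
    if n_frames < FRAME_BUDGET:
        return False, [
            f"wand sweep has {n_frames} frames; the protocol calls for at least {FRAME_BUDGET}"
        ]
    return True, []
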