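"""CSV/JSON interchange with provenance headers.

CSV is the canonical interchange format (human-diffable); every file the
toolkit writes starts with comment lines embedding the configuration hash
and seed so any artifact can be traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import CalibrationResult
from .simulate import CaptureDataset
from .trajectories import CaptureClock, Trajectory3D

__all__ = [
    "config_hash",
    "write_csv",
    "read_csv",
    "write_dataset",
    "read_dataset",
    "write_calibration",
    "read_calibration",
    "write_trajectories",
    "read_trajectories",
]

_FLOAT_FMT = "%.9g"


def config_hash(manifest: dict) -> str:
    """Stable short hash of a configuration/manifest mapping."""
    blob = json.dumps(manifest, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance_lines(manifest: dict) -> str:
    seed = manifest.get("seed", "NA")
    return f"# facemocap config_hash={config_hash(manifest)} seed={seed}\n"


def write_csv(df: pd.DataFrame, path: str | Path, manifest: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(manifest))
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_dataset(dataset: CaptureDataset, directory: str | Path) -> Path:
    """Write a capture as observations.csv + truth.csv + manifest.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_csv(dataset.observations, d / "observations.csv", dataset.manifest)
    write_csv(dataset.truth, d / "truth.csv", dataset.manifest)
    meta = dict(dataset.manifest)
    meta["frequency_hz"] = dataset.clock.frequency_hz
    meta["config_hash"] = config_hash(dataset.manifest)
    (d / "manifest.json").write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return d


def read_dataset(directory: str | Path) -> CaptureDataset:
    d = Path(directory)
    meta = json.loads((d / "manifest.json").read_text())
    clock = CaptureClock(meta.pop("frequency_hz", 100.0))
    meta.pop("config_hash", None)
    return CaptureDataset(
        read_csv(d / "observations.csv"), read_csv(d / "truth.csv"), clock, meta
    )


def write_calibration(result: CalibrationResult, path: str | Path, manifest: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "projections": {c: P.tolist() for c, P in result.projections.items()},
        "systemic_error_mm": result.systemic_error_mm,
        "frames_used": result.frames_used,
        "threshold_mm": result.threshold_mm,
        "passed": result.passed,
        "warnings": result.warnings,
    }
    if manifest is not None:
        payload["config_hash"] = config_hash(manifest)
        payload["seed"] = manifest.get("seed")
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_calibration(path: str | Path) -> CalibrationResult:
    payload = json.loads(Path(path).read_text())
    return CalibrationResult(
        projections={c: np.asarray(P) for c, P in payload["projections"].items()},
        systemic_error_mm=payload["systemic_error_mm"],
        frames_used=payload["frames_used"],
        threshold_mm=payload["threshold_mm"],
        warnings=list(payload.get("warnings", [])),
    )


def write_trajectories(
    trajectories: dict[str, Trajectory3D], path: str | Path, manifest: dict
) -> Path:
    """Tidy trajectory CSV: frame, time_s, label, x/y/z, QC columns."""
    parts = []
    for label, traj in trajectories.items():
        n = traj.n_frames
        parts.append(
            pd.DataFrame(
                {
                    "frame": np.arange(n),
                    "time_s": traj.times,
                    "label": label,
                    "x_mm": traj.positions[:, 0],
                    "y_mm": traj.positions[:, 1],
                    "z_mm": traj.positions[:, 2],
                    "n_cameras": traj.n_cameras if traj.n_cameras is not None else 0,
                    "gap_flag": traj.gap_mask.astype(int),
                    "residual_px": traj.residual_px if traj.residual_px is not None else np.nan,
                }
            )
        )
    df = pd.concat(parts, ignore_index=True).sort_values(["frame", "label"], kind="stable")
    return write_csv(df, path, manifest)


def read_trajectories(path: str | Path, frequency_hz: float = 100.0) -> dict[str, Trajectory3D]:
    df = read_csv(path)
    clock = CaptureClock(frequency_hz)
    out = {}
    for label, g in df.groupby("label", sort=False):
        g = g.sort_values("frame")
        n = int(g["frame"].max()) + 1
        pos = np.full((n, 3), np.nan)
        ncam = np.zeros(n, dtype=int)
        res = np.full(n, np.nan)
        gap = np.ones(n, dtype=bool)
        f = g["frame"].to_numpy()
        pos[f] = g[["x_mm", "y_mm", "z_mm"]].to_numpy()
        ncam[f] = g["n_cameras"].to_numpy()
        res[f] = g["residual_px"].to_numpy()
        gap[f] = g["gap_flag"].to_numpy().astype(bool)
        out[str(label)] = Trajectory3D(str(label), pos, clock, gap, ncam, res)
    return out
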