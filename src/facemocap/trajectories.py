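"""Time-series containers: capture clock and labeled 3-D trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CaptureClock", "Trajectory3D"]


@dataclass(frozen=True)
class CaptureClock:
    """Fixed-rate capture clock; frame i occurs at time i / frequency."""

    frequency_hz: float = 100.0

    def __post_init__(self):
        if not self.frequency_hz > 0:
            raise ValueError("capture frequency must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.frequency_hz

    def times(self, n_frames: int) -> np.ndarray:
        return np.arange(n_frames) / self.frequency_hz


@dataclass
class Trajectory3D:
    """One marker's position per frame, with gaps flagged.

    ``positions`` is (n_frames, 3) in mm; frames where ``gap_mask`` is True
    hold NaN and are excluded from analysis unless filled. ``n_cameras``
    records how many cameras observed the marker in each frame (0 for gaps);
    frames seen by fewer than three cameras carry a soft QC flag.
    """

    label: str
    positions: np.ndarray
    clock: CaptureClock = field(default_factory=CaptureClock)
    gap_mask: np.ndarray | None = None
    n_cameras: np.ndarray | None = None
    residual_px: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_frames, 3)")
        n = len(self.positions)
        if self.gap_mask is None:
            self.gap_mask = ~np.all(np.isfinite(self.positions), axis=1)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape != (n,):
            raise ValueError("gap_mask length must match positions")
        if self.n_cameras is not None:
            self.n_cameras = np.asarray(self.n_cameras, dtype=int)
        if self.residual_px is not None:
            self.residual_px = np.asarray(self.residual_px, dtype=float)
        if np.any(~np.isfinite(self.positions[~self.gap_mask])):
            raise ValueError("non-finite position outside flagged gaps")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def times(self) -> np.ndarray:
        return self.clock.times(self.n_frames)

    @property
    def qc_low_camera_frames(self) -> np.ndarray:
        """Frames triangulated from fewer than 3 cameras (soft QC flag)."""
        if self.n_cameras is None:
            return np.zeros(self.n_frames, dtype=bool)
        return (~self.gap_mask) & (self.n_cameras < 3)

    def valid_positions(self) -> np.ndarray:
        return self.positions[~self.gap_mask]

    def copy(self) -> "Trajectory3D":
        return Trajectory3D(
            self.label,
            self.positions.copy(),
            self.clock,
            self.gap_mask.copy(),
            None if self.n_cameras is None else self.n_cameras.copy(),
            None if self.residual_px is None else self.residual_px.copy(),
        )
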