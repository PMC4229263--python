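"""Run configuration: a fully serializable description of a capture/analysis run.

A run is reproducible from its configuration and seed alone; all stage
seeds are split deterministically from the single top-level seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "split_seed"]

_STAGES = ("wand", "rod_static", "rod_dynamic", "expressions", "sampling", "reliability")


def split_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the top-level seed."""
    if stage not in _STAGES:
        raise KeyError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """Serializable configuration of the synthetic rig and analysis options."""

    seed: int = 0
    working_distance_mm: float = 800.0
    focal_px: float = 2400.0
    sigma_px: float = 0.5
    dropout_rate: float = 0.0
    wand_frames: int = 3000
    wand_spacings_mm: tuple[float, float] = (100.0, 150.0)
    linear_rod_length_mm: float = 176.84
    l_rod_angle_deg: float = 90.0
    smoothing_window: int = 11
    smoothing_polyorder: int = 3
    icc_alpha: float = 0.05
    nasal_landmark: str = "I"
    head_rotation_deg: float = 3.0
    head_translation_mm: float = 5.0
    calibration_gate_mm: float = 0.3

    def stage_seed(self, stage: str) -> int:
        return split_seed(self.seed, stage)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wand_spacings_mm"] = list(d["wand_spacings_mm"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "wand_spacings_mm" in raw:
            raw["wand_spacings_mm"] = tuple(raw["wand_spacings_mm"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return p
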