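"""Landmark and expression registries.

The toolkit tracks 21 facial observational points (uppercase codes on the
left half of the face, lowercase on the right, plus midline points I, J, K,
II, III) and 10 standardized facial expressions. Both registries ship as
plain-text CSV inside the package and can be overridden by user files of the
same schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Landmark",
    "LandmarkRegistry",
    "Expression",
    "ExpressionRegistry",
    "FaceTemplate",
    "HELMET_MARKERS",
    "load_landmarks",
    "load_expressions",
    "load_face_template",
]

HELMET_MARKERS = ("HM1", "HM2", "HM3")

_SIDES = {"left", "right", "midline"}
_EXPECTED_CODES = {
    "A", "a", "B", "b", "C", "c", "D", "d", "E", "e",
    "F", "f", "G", "g", "H", "h", "I", "J", "K", "II", "III",
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("facemocap").joinpath("data", name)))


@dataclass(frozen=True)
class Landmark:
    code: str          # case-sensitive: case encodes facial side
    description: str
    side: str          # left | right | midline

    def __post_init__(self):
        if self.side not in _SIDES:
            raise ValueError(f"unknown side {self.side!r} for landmark {self.code!r}")


@dataclass(frozen=True)
class LandmarkRegistry:
    """The 21 facial observational points."""

    entries: tuple[Landmark, ...]

    def __post_init__(self):
        codes = [lm.code for lm in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate landmark codes")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return any(lm.code == code for lm in self.entries)

    def __getitem__(self, code: str) -> Landmark:
        for lm in self.entries:
            if lm.code == code:
                return lm
        raise KeyError(code)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(lm.code for lm in self.entries)

    def mirror(self, code: str) -> str:
        """The contralateral homologue: swaps case for paired landmarks,
        identity for midline points (which use multi-char or midline codes)."""
        lm = self[code]
        if lm.side == "midline":
            return code
        return code.swapcase()


@dataclass(frozen=True)
class Expression:
    index: int
    name: str
    #: peak landmark displacements (mm) in the anatomical frame
    displacements: dict[str, np.ndarray] = field(compare=False)

    @property
    def active_landmarks(self) -> tuple[str, ...]:
        return tuple(self.displacements)

    @property
    def nominal_amplitude_mm(self) -> float:
        """Largest peak displacement magnitude over the active landmarks."""
        return max(float(np.linalg.norm(v)) for v in self.displacements.values())


@dataclass(frozen=True)
class ExpressionRegistry:
    """The 10 standardized facial movements of the measuring protocol."""

    entries: tuple[Expression, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, index: int) -> Expression:
        for e in self.entries:
            if e.index == index:
                return e
        raise KeyError(f"no expression with index {index}")

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(e.index for e in self.entries)


@dataclass(frozen=True)
class FaceTemplate:
    """Rest-pose marker positions in the head-fixed frame (mm).

    Contains the 21 facial landmarks plus the 3 rigid helmet markers.
    Left/right homologous landmarks are mirror images across the sagittal
    plane (X = 0); helmet markers ride rigidly with the head.
    """

    positions: dict[str, np.ndarray]

    def __post_init__(self):
        for code, p in self.positions.items():
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"bad template position for {code!r}")

    @property
    def landmark_codes(self) -> tuple[str, ...]:
        return tuple(c for c in self.positions if c not in HELMET_MARKERS)

    def array(self, codes) -> np.ndarray:
        return np.stack([self.positions[c] for c in codes])

    def check_mirror_symmetry(self, registry: LandmarkRegistry, tol: float = 1e-9) -> None:
        for lm in registry.entries:
            if lm.side != "left":
                continue
            p = self.positions[lm.code]
            q = self.positions[registry.mirror(lm.code)]
            if not np.allclose(p * np.array([-1.0, 1.0, 1.0]), q, atol=tol):
                raise ValueError(f"template not mirror-symmetric at {lm.code!r}")


def load_landmarks(path: str | Path | None = None) -> LandmarkRegistry:
    """Load the landmark registry (packaged default or a user override)."""
    df = pd.read_csv(path if path is not None else _data_path("landmarks.csv"), comment="#")
    reg = LandmarkRegistry(tuple(
        Landmark(str(r.code), str(r.description), str(r.side)) for r in df.itertuples()
    ))
    if path is None and set(reg.codes) != _EXPECTED_CODES:
        raise RuntimeError("packaged landmark registry is corrupted")
    return reg


def load_expressions(path: str | Path | None = None) -> ExpressionRegistry:
    """Load the expression registry with its per-landmark displacement field."""
    df = pd.read_csv(path if path is not None else _data_path("expressions.csv"), comment="#")
    entries = []
    for idx, grp in df.groupby("index", sort=True):
        disp = {
            str(r.landmark): np.array([r.dx_mm, r.dy_mm, r.dz_mm], dtype=float)
            for r in grp.itertuples()
        }
        entries.append(Expression(int(idx), str(grp["name"].iloc[0]), disp))
    return ExpressionRegistry(tuple(entries))


def load_face_template(path: str | Path | None = None) -> FaceTemplate:
    df = pd.read_csv(path if path is not None else _data_path("face_template.csv"), comment="#")
    return FaceTemplate({
        str(r.code): np.array([r.x_mm, r.y_mm, r.z_mm], dtype=float) for r in df.itertuples()
    })
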