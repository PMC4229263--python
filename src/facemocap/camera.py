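"""Pinhole camera models and the default six-camera capture rig.

Cameras are idealized pinholes (no lens distortion): a world point X (mm) is
mapped to pixels through x ~ K [R | t] X. The default rig arranges six
cameras in a symmetric "L" — one horizontal arm of three and one vertical
arm of three — all aimed at the capture-volume centre from a working
distance of 800 mm, so that every marker in the volume is seen by several
well-separated viewpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CameraModel", "RigLayout", "project", "look_at_rotation", "default_rig"]


class ProjectionError(ValueError):
    """Point at or behind the camera plane."""


@dataclass(frozen=True)
class CameraModel:
    """Intrinsics + pose of one pinhole camera.

    ``rotation`` maps world to camera axes, ``translation`` (mm) completes
    x_cam = R @ X + t. The camera looks along its +Z axis.
    """

    camera_id: str
    focal_px: float
    principal_px: np.ndarray          # (2,) cx, cy
    rotation: np.ndarray              # (3, 3) orthonormal, det +1
    translation: np.ndarray           # (3,) mm
    image_size_px: tuple[int, int] = (1360, 1024)

    def __post_init__(self):
        object.__setattr__(self, "principal_px", np.asarray(self.principal_px, dtype=float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if not self.focal_px > 0:
            raise ValueError("focal length must be positive")
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9) or not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be orthonormal with determinant +1")

    @property
    def intrinsics(self) -> np.ndarray:
        cx, cy = self.principal_px
        return np.array([[self.focal_px, 0.0, cx], [0.0, self.focal_px, cy], [0.0, 0.0, 1.0]])

    @property
    def projection_matrix(self) -> np.ndarray:
        """The 3x4 matrix K [R | t]."""
        return self.intrinsics @ np.hstack([self.rotation, self.translation[:, None]])

    @property
    def center(self) -> np.ndarray:
        """Camera centre in world coordinates (mm)."""
        return -self.rotation.T @ self.translation

    def in_image(self, uv: np.ndarray) -> np.ndarray:
        w, h = self.image_size_px
        uv = np.atleast_2d(uv)
        return (uv[:, 0] >= 0) & (uv[:, 0] <= w) & (uv[:, 1] >= 0) & (uv[:, 1] <= h)


def project(camera: CameraModel, points: np.ndarray, *, strict: bool = True) -> np.ndarray:
    """Pinhole projection of world points (mm) to pixel coordinates.

    ``points`` is (3,) or (n, 3); returns matching (2,) or (n, 2). With
    ``strict`` (default) a non-positive depth raises; otherwise such rows
    come back as NaN so callers can treat them as invisible.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cam_pts = pts @ camera.rotation.T + camera.translation
    depth = cam_pts[:, 2]
    bad = depth <= 0
    if strict and np.any(bad):
        raise ProjectionError("point at non-positive depth (behind the camera)")
    with np.errstate(divide="ignore", invalid="ignore"):
        uv = camera.focal_px * cam_pts[:, :2] / depth[:, None] + camera.principal_px
    uv[bad] = np.nan
    if np.asarray(points).ndim == 1:
        return uv[0]
    return uv


def look_at_rotation(center: np.ndarray, target: np.ndarray, up=(0.0, 1.0, 0.0)) -> np.ndarray:
    """World-to-camera rotation for a camera at ``center`` aimed at ``target``."""
    z = np.asarray(target, float) - np.asarray(center, float)
    z = z / np.linalg.norm(z)
    up = np.asarray(up, float)
    x = np.cross(up, z)
    nx = np.linalg.norm(x)
    if nx < 1e-12:  # looking straight along 'up'
        x = np.cross((1.0, 0.0, 0.0), z)
        nx = np.linalg.norm(x)
    x = x / nx
    y = np.cross(z, x)
    return np.stack([x, y, z])


@dataclass(frozen=True)
class RigLayout:
    """A multi-camera rig around a capture volume centred at ``volume_center``."""

    cameras: tuple[CameraModel, ...]
    volume_center: np.ndarray
    working_distance_mm: float = 800.0

    def __post_init__(self):
        object.__setattr__(self, "volume_center", np.asarray(self.volume_center, dtype=float))

    def __len__(self) -> int:
        return len(self.cameras)

    @property
    def camera_ids(self) -> tuple[str, ...]:
        return tuple(c.camera_id for c in self.cameras)


def default_rig(
    working_distance_mm: float = 800.0,
    focal_px: float = 2400.0,
    image_size_px: tuple[int, int] = (1360, 1024),
) -> RigLayout:
    """Six cameras in a symmetric "L", aimed at the origin.

    The horizontal arm holds three cameras offset left of centre, the
    vertical arm three cameras offset above centre, all in the plane
    z = ``working_distance_mm`` in front of the subject (+Z is the subject's
    "forward"). The two equal arms give both horizontal and vertical
    triangulation baselines.
    """
    arm = np.array([-600.0, -400.0, -200.0])
    offsets = [(dx, 0.0) for dx in arm] + [(0.0, -dy) for dy in arm]
    target = np.zeros(3)
    cams = []
    for i, (dx, dy) in enumerate(offsets, start=1):
        center = np.array([dx, dy, working_distance_mm])
        R = look_at_rotation(center, target)
        t = -R @ center
        cams.append(
            CameraModel(
                camera_id=f"cam{i}",
                focal_px=focal_px,
                principal_px=np.array(image_size_px, dtype=float) / 2.0,
                rotation=R,
                translation=t,
                image_size_px=image_size_px,
            )
        )
    return RigLayout(tuple(cams), volume_center=target, working_distance_mm=working_distance_mm)
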