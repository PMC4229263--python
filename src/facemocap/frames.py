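"""Head-fixed and anatomical reference frames.

No point on a moving face is static, so facial kinematics are expressed
relative to a rigid helmet carrying three reflective markers: the three
markers determine an origin (their centroid) and a plane, and the line
perpendicular to that plane through the origin completes a stable
head-fixed coordinate system. Expressing landmark trajectories in this
helmet frame removes rigid head motion.

Within the head-fixed frame, an anatomical frame is built once from the
rest pose: the horizontal plane runs through both tragus points and the
midline nasal point, the sagittal plane is perpendicular to it through the
nasal point, and the coronal plane is perpendicular to both through the
left tragus. Signs follow the measurement conventions: X is positive
toward the subject's left, Y positive upward, Z positive forward (toward
the cameras).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryError, as_vec3
from .registries import HELMET_MARKERS
from .trajectories import Trajectory3D

__all__ = [
    "HelmetFrame",
    "AnatomicalFrame",
    "helmet_frame",
    "to_helmet",
    "anatomical_frame",
    "to_anatomical",
    "NASAL_REFERENCE_LANDMARK",
]

#: midline nasal landmark anchoring the horizontal and sagittal planes;
#: the root of the columella nasi (I) is the midline "nasal centre" used by
#: default, configurable to the nasal-dorsum point K
NASAL_REFERENCE_LANDMARK = "I"


@dataclass(frozen=True)
class HelmetFrame:
    """Origin + right-handed orthonormal axes from the 3 helmet markers."""

    origin: np.ndarray
    axes: np.ndarray      # (3, 3), rows are the unit axes

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.axes.T

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.axes + self.origin


@dataclass(frozen=True)
class AnatomicalFrame:
    """Anatomically referenced frame: X left "+", Y up "+", Z forward "+"."""

    origin: np.ndarray
    axes: np.ndarray      # rows X, Y, Z

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.axes.T


def helmet_frame(m1, m2, m3, face_point=None, previous_normal=None) -> HelmetFrame:
    """Head-fixed frame from the three helmet markers.

    Origin is the marker centroid; the third axis is the unit normal of the
    marker plane, its sign fixed toward ``face_point`` when given (session
    start) or matched to ``previous_normal`` for frame-to-frame continuity;
    the first axis points from the centroid toward marker 1 (orthogonalized
    against the normal); the second completes a right-handed triad.
    """
    m1 = as_vec3(m1, "m1")
    m2 = as_vec3(m2, "m2")
    m3 = as_vec3(m3, "m3")
    origin = (m1 + m2 + m3) / 3.0
    n = np.cross(m2 - m1, m3 - m1)
    nn = np.linalg.norm(n)
    if 0.5 * nn < 1e-6:
        raise GeometryError("helmet markers are collinear")
    n = n / nn
    if face_point is not None and np.dot(as_vec3(face_point) - origin, n) < 0:
        n = -n
    elif previous_normal is not None and np.dot(previous_normal, n) < 0:
        n = -n
    a1 = m1 - origin
    a1 = a1 - np.dot(a1, n) * n
    a1 = a1 / np.linalg.norm(a1)
    a2 = np.cross(n, a1)
    return HelmetFrame(origin, np.stack([a1, a2, n]))


def to_helmet(
    trajectories: dict[str, Trajectory3D],
    face_point=None,
) -> dict[str, Trajectory3D]:
    """Re-express landmark trajectories in the per-frame helmet frame.

    The three helmet-marker trajectories must be present (codes HM1-HM3)
    and gap-free on analyzed frames; frames where any helmet marker is
    missing are excluded (become gaps) in every output trajectory.
    """
    missing = [m for m in HELMET_MARKERS if m not in trajectories]
    if missing:
        raise KeyError(f"helmet markers missing from trajectories: {missing}")
    hm = [trajectories[m] for m in HELMET_MARKERS]
    n_frames = hm[0].n_frames
    helmet_ok = ~(hm[0].gap_mask | hm[1].gap_mask | hm[2].gap_mask)

    if face_point is None:
        # default orientation hint: centroid of all non-helmet markers at
        # the first analyzable frame
        first = int(np.argmax(helmet_ok))
        pts = [
            t.positions[first]
            for c, t in trajectories.items()
            if c not in HELMET_MARKERS and not t.gap_mask[first]
        ]
        face_point = np.mean(pts, axis=0) if pts else None

    frames_list: list[HelmetFrame | None] = [None] * n_frames
    prev_normal = None
    for f in range(n_frames):
        if not helmet_ok[f]:
            continue
        fr = helmet_frame(
            hm[0].positions[f], hm[1].positions[f], hm[2].positions[f],
            face_point=face_point if prev_normal is None else None,
            previous_normal=prev_normal,
        )
        frames_list[f] = fr
        prev_normal = fr.axes[2]

    out: dict[str, Trajectory3D] = {}
    for code, traj in trajectories.items():
        pos = np.full_like(traj.positions, np.nan)
        for f in range(n_frames):
            fr = frames_list[f]
            if fr is not None and not traj.gap_mask[f]:
                pos[f] = fr.to_local(traj.positions[f])[0]
        out[code] = Trajectory3D(
            code, pos, traj.clock, None,
            traj.n_cameras, traj.residual_px,
        )
    return out


def anatomical_frame(
    rest_landmarks: dict[str, np.ndarray],
    nasal_landmark: str = NASAL_REFERENCE_LANDMARK,
) -> AnatomicalFrame:
    """Anatomical frame from rest-pose landmarks (helmet coordinates).

    Requires both tragus points (A left, a right) and the midline nasal
    landmark. Y is the unit normal of the horizontal plane through the
    three, oriented upward (away from the mouth, using the tragus-to-brow
    direction when brow landmarks are present, else +Y of the input frame);
    X is the sagittal-plane normal, oriented toward the subject's left
    (from right tragus to left tragus); Z = X x Y points forward. The
    origin lies at the intersection of the three planes, which places it on
    the coronal plane through the left tragus.
    """
    for code in ("A", "a", nasal_landmark):
        if code not in rest_landmarks:
            raise KeyError(f"anatomical frame needs landmark {code!r}")
    A = as_vec3(rest_landmarks["A"], "A")
    a = as_vec3(rest_landmarks["a"], "a")
    nasal = as_vec3(rest_landmarks[nasal_landmark], nasal_landmark)

    y = np.cross(nasal - A, a - A)
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise GeometryError("tragus points and nasal landmark are collinear")
    y = y / ny
    up_hint = None
    for brow in ("J", "B", "b"):
        if brow in rest_landmarks:
            up_hint = as_vec3(rest_landmarks[brow]) - (A + a) / 2.0
            break
    if up_hint is None:
        up_hint = np.array([0.0, 1.0, 0.0])
    if np.dot(y, up_hint) < 0:
        y = -y

    x = A - a                        # right tragus -> left tragus
    x = x - np.dot(x, y) * y         # force the sagittal normal into the horizontal plane
    x = x / np.linalg.norm(x)
    z = np.cross(x, y)
    # forward "+": toward the face front (the nasal point sits forward of the
    # inter-tragus axis)
    if np.dot(z, nasal - (A + a) / 2.0) < 0:
        raise GeometryError(
            "axis construction produced a backward-facing Z; check landmark sides"
        )
    axes = np.stack([x, y, z])
    # origin: on the sagittal plane through the nasal point, the horizontal
    # plane through the tragi, and the coronal plane through the left tragus
    origin = x * np.dot(x, nasal) + y * np.dot(y, A) + z * np.dot(z, A)
    return AnatomicalFrame(origin, axes)


def to_anatomical(
    trajectories: dict[str, Trajectory3D],
    frame: AnatomicalFrame,
) -> dict[str, Trajectory3D]:
    """Apply the fixed anatomical transform to helmet-frame trajectories."""
    out = {}
    for code, traj in trajectories.items():
        pos = np.full_like(traj.positions, np.nan)
        ok = ~traj.gap_mask
        pos[ok] = frame.to_local(traj.positions[ok])
        out[code] = Trajectory3D(code, pos, traj.clock, None, traj.n_cameras, traj.residual_px)
    return out
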