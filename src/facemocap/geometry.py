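"""Elementary 3-D geometry on millimetre coordinates.

All functions accept array-likes of shape (3,) (a single point) and return
plain floats / numpy arrays. Angles are reported in degrees, distances in
millimetres, matching the units used throughout the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "Plane",
    "as_vec3",
    "distance",
    "angle_at_vertex",
    "plane_from_points",
]

#: triangles with area below this (mm^2) are treated as degenerate
COLLINEARITY_AREA_TOL = 1e-6


class GeometryError(ValueError):
    """Degenerate or non-finite geometric input."""


def as_vec3(p, name: str = "point") -> np.ndarray:
    """Validate and convert a 3-vector; raises GeometryError on bad input."""
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"{name} must have shape (3,), got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError(f"{name} has non-finite components: {a!r}")
    return a


def distance(p, q) -> float:
    """Euclidean distance |p - q| in millimetres."""
    return float(np.linalg.norm(as_vec3(p, "p") - as_vec3(q, "q")))


def angle_at_vertex(a, v, b) -> float:
    """Angle in degrees subtended at vertex ``v`` by points ``a`` and ``b``.

    The vertex is the middle argument, mirroring the angle notation in which
    the middle letter names the vertex (e.g. the angle C-E-D is measured at E).
    Result lies in [0, 180].
    """
    a = as_vec3(a, "a")
    v = as_vec3(v, "v")
    b = as_vec3(b, "b")
    u1 = a - v
    u2 = b - v
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 == 0.0 or n2 == 0.0:
        raise GeometryError("degenerate angle: a ray endpoint coincides with the vertex")
    c = np.dot(u1, u2) / (n1 * n2)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class Plane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def signed_distance(self, p) -> float:
        """Signed point-to-plane distance (mm), positive along the normal."""
        return float(np.dot(as_vec3(p) - self.point, self.normal))


def plane_from_points(p1, p2, p3) -> Plane:
    """Plane through three non-collinear points.

    Raises GeometryError when the triangle area falls below
    ``COLLINEARITY_AREA_TOL`` (1e-6 mm^2).
    """
    p1 = as_vec3(p1, "p1")
    p2 = as_vec3(p2, "p2")
    p3 = as_vec3(p3, "p3")
    n = np.cross(p2 - p1, p3 - p1)
    area = 0.5 * np.linalg.norm(n)
    if area < COLLINEARITY_AREA_TOL:
        raise GeometryError(f"points are collinear within tolerance (area={area:g} mm^2)")
    return Plane(point=p1, normal=n / np.linalg.norm(n))
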