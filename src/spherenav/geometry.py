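"""Geodesic navigation primitives on the sphere and the plane.

All locations live on either the unit sphere (represented by unit
3-vectors) or the plane z = 0.  Lengths are expressed throughout in
*degree units*: on the reference sphere (``radius_scale = 1``) a length
of 1 unit is the arc subtended by 1 degree of great circle; on the plane
the same unit is used so that distances are directly comparable across
the two surfaces.  A sphere with ``radius_scale = s`` has all its arcs
stretched by ``s`` (an arc of ``d`` degree units spans ``d / s`` degrees
of central angle).

The sign convention for turns is: positive = rightward, i.e. clockwise
as seen from outside the sphere (or from +z above the plane).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Geometry",
    "PLANE",
    "SPHERE",
    "Pose",
    "GeometryError",
    "DegenerateBearingError",
    "surface_point",
    "validate_point",
    "geodesic_distance",
    "initial_bearing",
    "advance",
    "turn",
    "signed_turn_to",
    "angular_separation",
    "arc_to_units",
    "chance_position_error",
    "latlon_to_vector",
    "vector_to_latlon",
    "SPHERE_RADIUS_UNITS",
    "WALK_SPEED_DEG_PER_S",
]

#: Radius of the study sphere in virtual units.
SPHERE_RADIUS_UNITS = 12.5
#: Maximum translational walking speed, degrees of arc per second.
WALK_SPEED_DEG_PER_S = 20.0

_UNIT_TOL = 1e-12


class GeometryError(ValueError):
    """Invalid geometric input (non-unit spherical point, bad geometry)."""


class DegenerateBearingError(GeometryError):
    """Bearing undefined: coincident or antipodal points."""


@dataclass(frozen=True)
class Geometry:
    """Surface on which navigation takes place.

    Parameters
    ----------
    kind:
        ``"planar"`` or ``"spherical"``.
    radius_scale:
        Sphere radius as a multiple of the reference (study) sphere.
        Ignored for planar geometry.
    """

    kind: str
    radius_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("planar", "spherical"):
            raise GeometryError(f"unknown geometry kind {self.kind!r}")
        if not (self.radius_scale > 0):
            raise GeometryError("radius_scale must be positive")

    @property
    def is_spherical(self) -> bool:
        return self.kind == "spherical"


PLANE = Geometry("planar")
SPHERE = Geometry("spherical")


def surface_point(coords, g: Geometry) -> np.ndarray:
    """Coerce ``coords`` to a valid point for geometry ``g``.

    Spherical coordinates are normalised if within 1e-6 of unit norm,
    otherwise rejected; planar points must have z == 0.
    """
    p = np.asarray(coords, dtype=float)
    if p.shape != (3,):
        raise GeometryError("points are 3-vectors")
    if g.is_spherical:
        n = np.linalg.norm(p)
        if abs(n - 1.0) > 1e-6:
            raise GeometryError(f"spherical point has norm {n}, expected 1")
        return p / n
    if abs(p[2]) > 1e-9:
        raise GeometryError("planar points must lie in z = 0")
    return p


def validate_point(p: np.ndarray, g: Geometry) -> None:
    p = np.asarray(p, dtype=float)
    if g.is_spherical:
        if abs(np.linalg.norm(p) - 1.0) > 1e-9:
            raise GeometryError("spherical point is not on the unit sphere")
    elif abs(p[2]) > 1e-9:
        raise GeometryError("planar point off the z = 0 plane")


def _normal(p: np.ndarray, g: Geometry) -> np.ndarray:
    """Outward surface normal at p."""
    return p if g.is_spherical else np.array([0.0, 0.0, 1.0])


@dataclass
class Pose:
    """Position plus heading (unit tangent vector at the position)."""

    position: np.ndarray
    heading: np.ndarray
    geometry: Geometry = field(default=SPHERE)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        validate_point(self.position, self.geometry)
        n = np.linalg.norm(self.heading)
        if abs(n - 1.0) > 1e-9:
            raise GeometryError("heading must be a unit vector")
        if self.geometry.is_spherical:
            if abs(float(self.position @ self.heading)) > 1e-9:
                raise GeometryError("heading must be tangent to the sphere")
        elif abs(self.heading[2]) > 1e-9:
            raise GeometryError("planar heading must lie in the plane")

    def copy(self) -> "Pose":
        return Pose(self.position.copy(), self.heading.copy(), self.geometry)


def geodesic_distance(p, q, g: Geometry) -> float:
    """Shortest-path distance between p and q, in degree units.

    On the sphere this is ``radius_scale`` times the central angle in
    degrees; on the plane it is the Euclidean distance.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    validate_point(p, g)
    validate_point(q, g)
    if g.is_spherical:
        ang = math.atan2(np.linalg.norm(np.cross(p, q)), float(p @ q))
        return math.degrees(ang) * g.radius_scale
    return float(np.linalg.norm(p - q))


def initial_bearing(p, q, g: Geometry) -> np.ndarray:
    """Unit tangent at p pointing along the shortest geodesic to q.

    Raises :class:`DegenerateBearingError` for coincident points, or
    antipodal points on the sphere (shortest path not unique).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    validate_point(p, g)
    validate_point(q, g)
    if g.is_spherical:
        c = np.cross(p, q)
        if np.linalg.norm(c) < 1e-12:
            raise DegenerateBearingError("coincident or antipodal points")
        t = q - float(p @ q) * p
        return t / np.linalg.norm(t)
    d = q - p
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise DegenerateBearingError("coincident points")
    return d / n


def advance(pose: Pose, d: float, g: Geometry | None = None) -> Pose:
    """Move distance ``d`` (degree units) along the current geodesic.

    On the sphere the pose follows the great circle through its position
    and heading; the heading is parallel-transported and remains tangent
    to that great circle.
    """
    g = pose.geometry if g is None else g
    if d < 0:
        raise GeometryError("advance distance must be >= 0")
    p, h = pose.position, pose.heading
    if g.is_spherical:
        th = math.radians(d / g.radius_scale)
        new_p = p * math.cos(th) + h * math.sin(th)
        new_h = h * math.cos(th) - p * math.sin(th)
        new_p /= np.linalg.norm(new_p)
        new_h -= float(new_p @ new_h) * new_p
        new_h /= np.linalg.norm(new_h)
        return Pose(new_p, new_h, g)
    return Pose(p + d * h, h.copy(), g)


def turn(pose: Pose, angle: float) -> Pose:
    """Rotate the heading in the tangent plane; positive = rightward."""
    if not (-360.0 < angle < 360.0):
        raise GeometryError("turn angle must lie in (-360, 360)")
    g = pose.geometry
    n = _normal(pose.position, g)
    phi = -math.radians(angle)  # rightward = clockwise seen from outside
    h = pose.heading
    new_h = h * math.cos(phi) + np.cross(n, h) * math.sin(phi)
    new_h -= float(n @ new_h) * n if g.is_spherical else 0.0
    new_h /= np.linalg.norm(new_h)
    return Pose(pose.position.copy(), new_h, g)


def signed_turn_to(pose: Pose, bearing: np.ndarray) -> float:
    """Signed turn (degrees, positive rightward) from the pose's heading
    to the given tangent direction at the same point."""
    n = _normal(pose.position, pose.geometry)
    h, b = pose.heading, np.asarray(bearing, dtype=float)
    ccw = math.atan2(float(n @ np.cross(h, b)), float(h @ b))
    return -math.degrees(ccw)


def angular_separation(h1, h2) -> float:
    """Unsigned angle between two tangent vectors at one point, in [0, 180]."""
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    return math.degrees(
        math.atan2(np.linalg.norm(np.cross(h1, h2)), float(h1 @ h2))
    )


def arc_to_units(arc_deg: float, radius_units: float) -> float:
    """Convert an arc (degrees) to a length in virtual units."""
    if radius_units <= 0:
        raise GeometryError("radius_units must be positive")
    return arc_deg * math.pi / 180.0 * radius_units


def chance_position_error(g: Geometry) -> float:
    """Expected geodesic distance from a fixed point to a uniform random
    point on the sphere: the analytic value of ∫ θ sin(θ)/2 dθ = 90°
    (times ``radius_scale``).  Undefined on the unbounded plane."""
    if not g.is_spherical:
        raise GeometryError("chance level is defined only on the sphere")
    return 90.0 * g.radius_scale


def latlon_to_vector(lat_deg: float, lon_deg: float) -> np.ndarray:
    """Decimal-degree latitude/longitude to a unit 3-vector (lat 90 = +z)."""
    la, lo = math.radians(lat_deg), math.radians(lon_deg)
    return np.array(
        [math.cos(la) * math.cos(lo), math.cos(la) * math.sin(lo), math.sin(la)]
    )


def vector_to_latlon(v: np.ndarray) -> tuple[float, float]:
    """Unit 3-vector to (lat, lon) with lat in [-90, 90], lon in (-180, 180]."""
    v = np.asarray(v, dtype=float)
    lat = math.degrees(math.asin(max(-1.0, min(1.0, float(v[2])))))
    lon = math.degrees(math.atan2(float(v[1]), float(v[0])))
    if lon <= -180.0:
        lon += 360.0
    return lat, lon
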