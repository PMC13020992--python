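"""Ideal inbound responses for the triangle-completion task.

A trial consists of an outbound journey (leg 1, a mid-path turn, leg 2)
after which the navigator must turn and walk straight back to the
unmarked start.  The correct response depends on the geometry of the
surface: on a plane the interior angles of a triangle sum to 180°, on a
sphere they exceed it, so a planar path-integration system produces a
systematic overturn and overshoot when used on a sphere.

Conventions
-----------
``inner_angle`` is the triangle's interior angle at the response corner;
``pooled_turn`` = 180 − inner_angle is the unsigned response turn after
left/right mirror trials are pooled onto the 0–180° scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import (
    PLANE,
    SPHERE,
    Geometry,
    GeometryError,
    Pose,
    advance,
    angular_separation,
    geodesic_distance,
    initial_bearing,
    signed_turn_to,
    turn,
)

__all__ = [
    "TriangleShape",
    "InboundSolution",
    "TriangleTrial",
    "DegenerateShapeError",
    "canonical_start",
    "outbound_endpoint",
    "ideal_inbound",
    "execute_inbound",
    "closure_error",
    "pool_turn",
    "pool_symmetric",
    "radius_family",
]

_DEGENERATE_TOL = 1e-6


class DegenerateShapeError(GeometryError):
    """Outbound endpoint coincides with (or is antipodal to) the start."""


@dataclass(frozen=True)
class TriangleShape:
    """Outbound design: two legs joined by a signed mid-path turn.

    Lengths are in degree units; ``mid_turn`` is in signed degrees
    (positive = rightward).  Left/right mirror versions of a shape have
    mid turns of opposite sign and equal magnitude.
    """

    leg1: float
    mid_turn: float
    leg2: float
    shape_id: str = ""
    side: str = "right"

    def __post_init__(self) -> None:
        if self.leg1 <= 0 or self.leg2 <= 0:
            raise ValueError("legs must be positive")
        if not (0 < abs(self.mid_turn) < 180):
            raise ValueError("|mid_turn| must be in (0, 180)")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        expected_sign = 1.0 if self.side == "right" else -1.0
        if math.copysign(1.0, self.mid_turn) != expected_sign:
            raise ValueError("mid_turn sign must match side (right = +)")

    def mirrored(self) -> "TriangleShape":
        new_side = "left" if self.side == "right" else "right"
        return replace(self, mid_turn=-self.mid_turn, side=new_side)


@dataclass(frozen=True)
class InboundSolution:
    """Ideal response at the end of the outbound path, under a geometry."""

    inner_angle: float  # interior angle at the response corner, [0, 180]
    pooled_turn: float  # 180 - inner_angle, the pooled response turn
    distance: float     # return distance in degree units
    geometry: Geometry


@dataclass
class TriangleTrial:
    """One behavioral trial of the triangle-completion task."""

    participant: str
    environment: str  # "sphere" | "plane"
    shape_id: str
    side: str
    response_turn: float
    response_distance: float
    response_time: float | None = None


def canonical_start(g: Geometry) -> Pose:
    """Standard start pose: north pole heading along longitude 0 on the
    sphere; the origin heading +y on the plane."""
    if g.is_spherical:
        return Pose(np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]), g)
    return Pose(np.array([0.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]), g)


def outbound_endpoint(
    shape: TriangleShape, g: Geometry, start: Pose | None = None
) -> Pose:
    """Pose after walking leg 1, turning by ``mid_turn``, walking leg 2."""
    pose = canonical_start(g) if start is None else start
    pose = advance(pose, shape.leg1, g)
    pose = turn(pose, shape.mid_turn)
    return advance(pose, shape.leg2, g)


def ideal_inbound(shape: TriangleShape, g: Geometry) -> InboundSolution:
    """Ideal inbound turn and distance that close the triangle under g.

    The solution is constructed geometrically (vector rotations plus the
    exact bearing back to the start) rather than from per-case trigonometric
    formulas; ``closure_error`` provides the self-check that executing the
    solution returns to the start.
    """
    start = canonical_start(g)
    end = outbound_endpoint(shape, g, start)
    dist = geodesic_distance(end.position, start.position, g)
    if dist < _DEGENERATE_TOL:
        raise DegenerateShapeError("outbound endpoint coincides with start")
    if g.is_spherical and (180.0 * g.radius_scale - dist) < _DEGENERATE_TOL:
        raise DegenerateShapeError("outbound endpoint antipodal to start")
    bearing = initial_bearing(end.position, start.position, g)
    signed = signed_turn_to(end, bearing)
    pooled = abs(signed)
    if pooled > 180.0:
        pooled = 360.0 - pooled
    return InboundSolution(
        inner_angle=180.0 - pooled, pooled_turn=pooled, distance=dist, geometry=g
    )


def execute_inbound(
    shape: TriangleShape, sol: InboundSolution, g: Geometry
) -> Pose:
    """Execute the inbound response (turn toward the start, then walk the
    solution's distance) from the outbound endpoint."""
    end = outbound_endpoint(shape, g)
    bearing = initial_bearing(end.position, canonical_start(g).position, g)
    signed = signed_turn_to(end, bearing)
    # turn by the solution's magnitude in the direction that closes
    pose = turn(end, math.copysign(sol.pooled_turn, signed) if signed else sol.pooled_turn)
    return advance(pose, sol.distance, g)


def closure_error(shape: TriangleShape, g: Geometry) -> float:
    """Distance from the executed ideal inbound's endpoint to the start.

    This is the module's ground-truth check: an exact solution closes the
    triangle to numerical precision.
    """
    sol = ideal_inbound(shape, g)
    final = execute_inbound(shape, sol, g)
    return geodesic_distance(final.position, canonical_start(g).position, g)


def pool_turn(response_turn: float) -> float:
    """Map a signed turn to its unsigned equivalent in [0, 180]."""
    if not (-360.0 < response_turn < 360.0):
        raise ValueError("turn outside (-360, 360)")
    a = abs(response_turn) % 360.0
    return 360.0 - a if a > 180.0 else a


def pool_symmetric(trials: list[TriangleTrial]) -> list[TriangleTrial]:
    """Pool left/right mirror trials onto a common 0–180° turn scale.

    Response turns are replaced by their unsigned equivalents and the
    side label is collapsed, so mirror versions of a shape become one
    condition.  Idempotent.
    """
    pooled = []
    for t in trials:
        pooled.append(
            replace_trial(t, response_turn=pool_turn(t.response_turn), side="pooled")
        )
    return pooled


def replace_trial(t: TriangleTrial, **kw) -> TriangleTrial:
    d = dict(
        participant=t.participant,
        environment=t.environment,
        shape_id=t.shape_id,
        side=t.side,
        response_turn=t.response_turn,
        response_distance=t.response_distance,
        response_time=t.response_time,
    )
    d.update(kw)
    return TriangleTrial(**d)


def radius_family(
    shape: TriangleShape, scales: list[float]
) -> list[InboundSolution]:
    """Ideal spherical solutions across a family of sphere radii.

    As the radius grows the spherical solution converges to the planar
    one, providing a one-parameter bridge between the two geometry models.
    """
    sols = []
    for s in scales:
        if s <= 0:
            raise ValueError("radius scale must be positive")
        sols.append(ideal_inbound(shape, Geometry("spherical", s)))
    return sols
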