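"""Synthetic behavioral cohorts with the statistical structure the
analyses assume.

Two generators stand in for the study's raw data:

* :func:`gen_triangle_cohort` — triangle-completion responses generated
  from the same model family the mixed-model analysis fits: per
  participant a random intercept and a random slope on the ideal
  response of the responder's internal geometry, plus Gaussian trial
  noise.  Responses are generated directly on the pooled 0–180° turn
  scale.
* :func:`gen_object_location_cohort` — object-location trials whose
  initial headings come either from a true great-circle planner
  (``global_3d``) or from the multi-planar-map planner
  (``planar_atlas``), with wrapped-Normal heading jitter and
  multiplicative distance noise on execution.

Default parameter values (20 participants, 7 shapes × 4 repetitions,
noise calibrated so the per-participant R² against the true turn
predictor lands near 0.67) live in ``data/default_cohort.yaml``.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .atlas import (
    IcosahedralAtlas,
    default_detour_vertex,
    detour_face_chain,
    geodesic_face_chain,
    plan_and_execute,
    unfold_chain,
)
from .geometry import (
    PLANE,
    SPHERE,
    Geometry,
    Pose,
    advance,
    angular_separation,
    geodesic_distance,
    initial_bearing,
    vector_to_latlon,
)
from .triangle import TriangleShape, TriangleTrial, ideal_inbound

__all__ = [
    "CohortParams",
    "ObjectLocationParams",
    "DEFAULT_TARGET_VERTICES",
    "default_design",
    "default_cohort_params",
    "gen_triangle_cohort",
    "trials_to_frame",
    "gen_object_location_cohort",
]

#: The six landmarks used as recall targets (every other vertex).
DEFAULT_TARGET_VERTICES = (1, 3, 5, 7, 9, 11)


@dataclass(frozen=True)
class CohortParams:
    """Data-generating parameters of a triangle-completion cohort.

    ``responder_geometry`` sets the internal path-integration model a
    participant applies on the sphere: ``"planar"``, ``"spherical"`` or
    a mixture weight w ∈ [0, 1] on the planar predictor.  On the plane
    environment the ideal response is planar for every responder.
    """

    n_participants: int = 20
    responder_geometry: str = "planar"  # "planar" | "spherical"
    mixture_weight: float | None = None  # w on planar ideal, if mixing
    slope_mean: float = 1.0
    slope_sd: float = 0.15
    intercept_mean: float = 0.0
    intercept_sd: float = 10.0
    turn_noise_sd: float = 14.0
    distance_noise_sd: float = 31.0
    repetitions: int = 4  # per shape, split over left/right mirrors
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        for sd in (self.slope_sd, self.intercept_sd,
                   self.turn_noise_sd, self.distance_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.mixture_weight is not None and not (
            0.0 <= self.mixture_weight <= 1.0
        ):
            raise ValueError("mixture weight must be in [0, 1]")
        if self.responder_geometry not in ("planar", "spherical", "mixture"):
            raise ValueError("responder_geometry must be planar/spherical/mixture")
        if self.responder_geometry == "mixture" and self.mixture_weight is None:
            raise ValueError("mixture responder needs a mixture_weight")


@dataclass(frozen=True)
class ObjectLocationParams:
    """Execution-noise and condition parameters for object-location data."""

    n_participants: int = 20
    n_trials_per_condition: int = 12  # per environment
    heading_noise_sd: float = 10.0    # degrees, wrapped-Normal jitter
    distance_noise_rel: float = 0.20  # multiplicative distance misestimation sd
    placement_noise_sd: float = 10.0  # degrees, memory/placement error at stop
    p_suboptimal: float = 0.5         # long sphere trials, planar_atlas only
    short_range: tuple[float, float] = (40.0, 110.0)
    long_range: tuple[float, float] = (120.0, 175.0)
    seed: int = 0


def default_design() -> list[TriangleShape]:
    """The default 7-shape outbound design (right-turn versions).

    Shapes span a wide range of ideal inbound turns and distances so
    responses cannot follow a shape-insensitive stereotype; the exact
    parameters are configuration, replaceable via the design YAML.
    """
    cfg = yaml.safe_load(
        importlib.resources.files("spherenav.data")
        .joinpath("default_design.yaml")
        .read_text()
    )
    shapes = []
    for item in cfg["shapes"]:
        shapes.append(
            TriangleShape(
                leg1=float(item["leg1_deg"]),
                mid_turn=abs(float(item["mid_turn_deg"])),
                leg2=float(item["leg2_deg"]),
                shape_id=str(item["shape_id"]),
                side="right",
            )
        )
    return shapes


def default_cohort_params(**overrides) -> CohortParams:
    """Cohort parameters from the packaged defaults file."""
    cfg = yaml.safe_load(
        importlib.resources.files("spherenav.data")
        .joinpath("default_cohort.yaml")
        .read_text()
    )
    cfg.update(overrides)
    return CohortParams(**cfg)


def _ideal_pooled(shape: TriangleShape, env: str, params: CohortParams):
    """(turn, distance) ideal response of the responder on this trial."""
    if env == "plane":
        sol = ideal_inbound(shape, PLANE)
        return sol.pooled_turn, sol.distance
    if params.responder_geometry == "planar":
        sol = ideal_inbound(shape, PLANE)
        return sol.pooled_turn, sol.distance
    if params.responder_geometry == "spherical":
        sol = ideal_inbound(shape, SPHERE)
        return sol.pooled_turn, sol.distance
    w = params.mixture_weight
    p = ideal_inbound(shape, PLANE)
    s = ideal_inbound(shape, SPHERE)
    return (
        w * p.pooled_turn + (1 - w) * s.pooled_turn,
        w * p.distance + (1 - w) * s.distance,
    )


def gen_triangle_cohort(
    design: list[TriangleShape],
    params: CohortParams,
    environments: tuple[str, ...] = ("sphere", "plane"),
) -> list[TriangleTrial]:
    """Generate a triangle-completion cohort.

    response = α_i + β_i · ideal(responder geometry) + ε per trial, with
    α_i ~ N(intercept_mean, intercept_sd), β_i ~ N(slope_mean, slope_sd)
    drawn independently for the turn and distance responses, and
    ε ~ N(0, noise_sd).  Each shape appears ``repetitions`` times per
    environment, alternating its left/right mirror; responses are
    generated on the pooled 0–180° scale and tagged with the side.
    Fully reproducible from ``params.seed``.
    """
    if not design:
        raise ValueError("empty design")
    rng = np.random.default_rng(params.seed)
    trials: list[TriangleTrial] = []
    for i in range(params.n_participants):
        pid = f"P{i + 1:02d}"
        a_t = rng.normal(params.intercept_mean, params.intercept_sd)
        b_t = rng.normal(params.slope_mean, params.slope_sd)
        a_d = rng.normal(params.intercept_mean, params.intercept_sd)
        b_d = rng.normal(params.slope_mean, params.slope_sd)
        for env in environments:
            for shape in design:
                turn_ideal, dist_ideal = _ideal_pooled(shape, env, params)
                for rep in range(params.repetitions):
                    side = "right" if rep % 2 == 0 else "left"
                    turn = (
                        a_t + b_t * turn_ideal
                        + rng.normal(0.0, params.turn_noise_sd)
                    )
                    dist = (
                        a_d + b_d * dist_ideal
                        + rng.normal(0.0, params.distance_noise_sd)
                    )
                    trials.append(
                        TriangleTrial(
                            participant=pid,
                            environment=env,
                            shape_id=shape.shape_id,
                            side=side,
                            response_turn=float(turn),
                            response_distance=float(max(dist, 0.0)),
                        )
                    )
    return trials


def trials_to_frame(trials: list[TriangleTrial],
                    design: list[TriangleShape] | None = None) -> pd.DataFrame:
    """Triangle trials as the standard trial-table DataFrame."""
    df = pd.DataFrame(
        {
            "participant_id": [t.participant for t in trials],
            "environment": [t.environment for t in trials],
            "shape_id": [t.shape_id for t in trials],
            "side": [t.side for t in trials],
            "response_turn_deg": [t.response_turn for t in trials],
            "response_distance_deg": [t.response_distance for t in trials],
            "rt_s": [t.response_time for t in trials],
        }
    )
    if design is not None:
        geom = pd.DataFrame(
            {
                "shape_id": [s.shape_id for s in design if s.side == "right"],
                "leg1_deg": [s.leg1 for s in design if s.side == "right"],
                "mid_turn_deg": [s.mid_turn for s in design if s.side == "right"],
                "leg2_deg": [s.leg2 for s in design if s.side == "right"],
            }
        ).drop_duplicates("shape_id")
        df = df.merge(geom, on="shape_id", how="left")
    return df


# ------------------------------------------------------- object location

def _wrapped_turn(heading: np.ndarray, pos: np.ndarray,
                  jitter_deg: float) -> np.ndarray:
    """Rotate a tangent heading by a signed angle about the outward normal."""
    phi = -math.radians(jitter_deg)  # positive jitter = rightward
    h = (
        heading * math.cos(phi)
        + np.cross(pos, heading) * math.sin(phi)
    )
    h -= float(pos @ h) * pos
    return h / np.linalg.norm(h)


def _sphere_trial(
    atlas: IcosahedralAtlas,
    target_vertex: int,
    distance: float,
    azimuth: float,
    strategy: str,
    suboptimal: bool,
    heading_jitter: float,
    dist_factor: float,
    placement: tuple[float, float] = (0.0, 0.0),
) -> tuple[float, float, np.ndarray]:
    """One sphere trial; returns (direction_error, position_error, start)."""
    target = atlas.vertices[target_vertex]
    # place the start at the requested distance along the given azimuth
    north = np.array([0.0, 0.0, 1.0])
    ref = north if abs(float(target @ north)) < 0.99 else np.array([1.0, 0.0, 0.0])
    t0 = ref - float(target @ ref) * target
    t0 /= np.linalg.norm(t0)
    pose = Pose(target, t0, SPHERE)
    pose = Pose(*_rotate_heading(pose, azimuth), SPHERE)
    start = advance(pose, distance).position

    true_bearing = initial_bearing(start, target, SPHERE)
    if strategy == "global_3d":
        planned_heading, planned_dist = true_bearing, distance
    else:
        if suboptimal:
            dv = default_detour_vertex(atlas, start, target)
            chain = detour_face_chain(start, target, atlas, dv)
        else:
            chain = geodesic_face_chain(start, target, atlas)
        unf = unfold_chain(chain, start, target, atlas)
        d = unf.target_image - unf.start_image
        L = float(np.linalg.norm(d))
        if L < 1e-9:
            planned_heading, planned_dist = true_bearing, 0.0
        else:
            u = d / L
            p2 = unf.face_maps[0].to_sphere(unf.start_image + 1e-3 * u)
            planned_heading = initial_bearing(start, p2, SPHERE)
            planned_heading -= float(start @ planned_heading) * start
            planned_heading /= np.linalg.norm(planned_heading)
            planned_dist = L
    executed = _wrapped_turn(planned_heading, start, heading_jitter)
    walked = max(planned_dist * dist_factor, 0.0)
    end = advance(Pose(start, executed, SPHERE), walked)
    # memory/placement error: offset the indicated stop location
    mag, ang = placement
    if abs(mag) > 1e-12:
        off_heading = _wrapped_turn(end.heading, end.position, ang)
        arrival = advance(Pose(end.position, off_heading, SPHERE), abs(mag)).position
    else:
        arrival = end.position
    direction_error = angular_separation(executed, true_bearing)
    position_error = geodesic_distance(arrival, target, SPHERE)
    return direction_error, position_error, start


def _rotate_heading(pose: Pose, azimuth_deg: float):
    phi = -math.radians(azimuth_deg)
    h = (
        pose.heading * math.cos(phi)
        + np.cross(pose.position, pose.heading) * math.sin(phi)
    )
    h -= float(pose.position @ h) * pose.position
    return pose.position, h / np.linalg.norm(h)


def gen_object_location_cohort(
    atlas: IcosahedralAtlas,
    params: ObjectLocationParams,
    strategy: str = "planar_atlas",
    target_vertices: tuple[int, ...] = DEFAULT_TARGET_VERTICES,
) -> pd.DataFrame:
    """Generate object-location trials for both environments.

    Targets are drawn from the six designated landmark vertices.  On the
    sphere the ``planar_atlas`` strategy plans with the multi-planar-map
    planner (long trials take a suboptimal patch arrangement with
    probability ``p_suboptimal``); ``global_3d`` plans along the true
    great circle.  On the plane both strategies are exact up to
    execution noise, since planar maps carry no distortion there.
    Short/long labels follow the 110° start–target distance threshold.
    """
    if strategy not in ("planar_atlas", "global_3d"):
        raise ValueError("strategy must be 'planar_atlas' or 'global_3d'")
    rng = np.random.default_rng(params.seed)
    rows = []
    for i in range(params.n_participants):
        pid = f"P{i + 1:02d}"
        for env in ("sphere", "plane"):
            for cond in ("short", "long"):
                lo, hi = (
                    params.short_range if cond == "short" else params.long_range
                )
                for _ in range(params.n_trials_per_condition):
                    distance = float(rng.uniform(lo, hi))
                    azimuth = float(rng.uniform(0.0, 360.0))
                    tv = int(rng.choice(target_vertices))
                    jitter = float(rng.normal(0.0, params.heading_noise_sd))
                    dist_factor = float(
                        max(rng.normal(1.0, params.distance_noise_rel), 0.0)
                    )
                    px, py = rng.normal(0.0, params.placement_noise_sd, 2)
                    sub = bool(
                        strategy == "planar_atlas"
                        and env == "sphere"
                        and cond == "long"
                        and distance > 120.0
                        and rng.random() < params.p_suboptimal
                    )
                    if env == "sphere":
                        de, pe, start = _sphere_trial(
                            atlas, tv, distance, azimuth, strategy, sub,
                            jitter, dist_factor,
                            placement=(
                                float(np.hypot(px, py)),
                                float(np.degrees(np.arctan2(py, px))),
                            ),
                        )
                        lat, lon = vector_to_latlon(start)
                        tlat, tlon = vector_to_latlon(atlas.vertices[tv])
                    else:
                        # exact planar plan + the same execution noise
                        de = abs(jitter)
                        walked = distance * dist_factor
                        stop = np.array(
                            [
                                walked * math.cos(math.radians(jitter)) + px,
                                walked * math.sin(math.radians(jitter)) + py,
                            ]
                        )
                        pe = float(np.hypot(stop[0] - distance, stop[1]))
                        lat = lon = tlat = tlon = float("nan")
                    rows.append(
                        {
                            "participant_id": pid,
                            "environment": env,
                            "start_lat": lat,
                            "start_lon": lon,
                            "target_id": tv,
                            "target_lat": tlat,
                            "target_lon": tlon,
                            "distance_deg": distance,
                            "condition": cond,
                            "direction_error_deg": de,
                            "position_error_deg": pe,
                        }
                    )
    return pd.DataFrame(rows)
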