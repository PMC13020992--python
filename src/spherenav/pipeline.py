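"""End-to-end orchestration: generate → filter → fit → compare → report.

A single seeded configuration drives the whole synthetic study: the
triangle-completion cohort and its geometry-model comparison, the
object-location cohort and its distance × environment interaction test,
the multi-planar-map route-planning simulation, and the Bayes-factor
design analysis.  All randomness is derived from the one run seed, so a
config reproduces its report bundle byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .atlas import build_atlas, simulate_route_planning
from .geometry import vector_to_latlon
from .stats import (
    attach_ideal_predictors,
    bf_from_bic,
    compare_geometries,
    filter_outliers_position,
    filter_outliers_triangle,
    fit_geometry_lmm,
    interaction_ttest,
    bfda_power,
    radius_sweep_analysis,
    split_short_long,
)
from .synthetic import (
    CohortParams,
    ObjectLocationParams,
    default_cohort_params,
    default_design,
    gen_object_location_cohort,
    gen_triangle_cohort,
    trials_to_frame,
)
from .triangle import pool_turn

__all__ = ["RunConfig", "run_full_synthetic_study"]

log = logging.getLogger("spherenav")


@dataclass
class RunConfig:
    """Configuration of one full synthetic-study run."""

    seed: int = 0
    out_dir: str = "spherenav_run"
    responder_geometry: str = "planar"
    cohort_overrides: dict = field(default_factory=dict)
    n_starts: int = 500
    sim_min_distance: float = 120.0
    radius_scales: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0)
    run_radius_sweep: bool = True
    power_d: float = 1.9
    power_n: int = 20
    power_iterations: int = 1000
    power_threshold: float = 3.0


def _pool_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["response_turn_deg"] = out["response_turn_deg"].map(pool_turn)
    out["side"] = "pooled"
    return out


def run_full_synthetic_study(config: RunConfig) -> dict:
    """Run the full synthetic study and write the report bundle.

    Writes trial CSVs, the route-planning simulation CSV and a JSON
    report into ``config.out_dir``; returns the report dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    log.info("run seed=%d derived seeds=%s", config.seed, seeds)

    design = default_design()
    report: dict = {"config": {"seed": config.seed,
                               "responder_geometry": config.responder_geometry}}

    # ---- triangle-completion arm
    params = default_cohort_params(
        seed=seeds[0],
        responder_geometry=config.responder_geometry,
        **config.cohort_overrides,
    )
    trials = gen_triangle_cohort(design, params)
    tri = trials_to_frame(trials, design)
    io.write_csv(tri[io.TRIANGLE_COLUMNS], out / "triangle_trials.csv",
                 seed=params.seed)
    pooled = attach_ideal_predictors(_pool_frame(tri), design,
                                     scales=config.radius_scales)
    tri_report = {}
    for env in ("sphere", "plane"):
        env_trials = pooled[pooled.environment == env]
        kept, removed = filter_outliers_triangle(env_trials)
        block = {"n_trials": int(len(env_trials)),
                 "n_removed": int(len(removed))}
        for dv in ("turn", "distance"):
            cmp_res = compare_geometries(kept, dv)
            fit_c = fit_geometry_lmm(kept, "combined", dv)
            block[dv] = {
                "bf_planar_over_spherical": cmp_res.bf,
                "log_bf": cmp_res.log_bf,
                "winner": cmp_res.winner,
                "bf_planar_over_combined": bf_from_bic(
                    cmp_res.fits["planar"], fit_c
                ),
                "r2_planar_mean": cmp_res.per_participant_r2["planar"][1],
                "r2_planar_sd": cmp_res.per_participant_r2["planar"][2],
                "r2_spherical_mean": cmp_res.per_participant_r2["spherical"][1],
                "r2_spherical_sd": cmp_res.per_participant_r2["spherical"][2],
            }
        if config.run_radius_sweep and env == "sphere":
            table, best = radius_sweep_analysis(kept, config.radius_scales,
                                                dv="turn")
            block["radius_sweep"] = table.to_dict(orient="records")
            block["best_radius_per_participant"] = best.to_dict()
        tri_report[env] = block
    report["triangle"] = tri_report

    # ---- object-location arm
    atlas = build_atlas()
    ol_params = ObjectLocationParams(seed=seeds[1],
                                     n_participants=params.n_participants)
    ol = gen_object_location_cohort(atlas, ol_params, "planar_atlas")
    io.write_csv(ol[io.OBJECT_LOCATION_COLUMNS],
                 out / "object_location_trials.csv", seed=ol_params.seed)
    labeled = split_short_long(ol)
    kept_ol = filter_outliers_position(labeled)
    t_res = interaction_ttest(kept_ol)
    report["object_location"] = {
        "n_trials": int(len(ol)),
        "n_kept": int(len(kept_ol)),
        "interaction_bf10": t_res.bf10,
        "t_statistic": t_res.t_statistic,
        "df": t_res.df,
        "cohens_d": t_res.cohens_d,
        "mean_interaction_deg": t_res.mean_diff,
        "cell_means": {
            f"{env}_{cond}": float(v)
            for (env, cond), v in kept_ol.groupby(
                ["environment", "condition"]
            )["direction_error_deg"].mean().items()
        },
    }

    # ---- route-planning simulation arm
    sim_rows = []
    sim_summary = {}
    for k, arrangement in enumerate(("optimal", "suboptimal")):
        recs = simulate_route_planning(
            atlas, config.n_starts, arrangement,
            min_distance=config.sim_min_distance, seed=seeds[2 + k],
        )
        de = np.array([r.direction_error for r in recs])
        pe = np.array([r.position_error for r in recs])
        sim_summary[arrangement] = {
            "n": len(recs),
            "direction_error_max": float(de.max()),
            "direction_error_q95": float(np.percentile(de, 95)),
            "direction_error_mean": float(de.mean()),
            "position_error_max": float(pe.max()),
            "position_error_q95": float(np.percentile(pe, 95)),
            "position_error_mean": float(pe.mean()),
        }
        for r in recs:
            slat, slon = vector_to_latlon(r.start)
            tlat, tlon = vector_to_latlon(r.target)
            sim_rows.append(
                {
                    "start_lat": slat, "start_lon": slon,
                    "target_lat": tlat, "target_lon": tlon,
                    "distance_deg": r.start_target_distance,
                    "arrangement": r.arrangement,
                    "chain_length": r.chain_length,
                    "direction_error_deg": r.direction_error,
                    "position_error_deg": r.position_error,
                    "seed": r.seed,
                }
            )
    io.write_csv(pd.DataFrame(sim_rows)[io.SIMULATION_COLUMNS],
                 out / "route_planning_sim.csv", seed=config.seed)
    report["route_planning"] = sim_summary

    # ---- power arm
    hit, fp = bfda_power(
        config.power_d, config.power_n, config.power_iterations,
        config.power_threshold, seed=seeds[4],
    )
    report["power"] = {
        "d": config.power_d, "n": config.power_n,
        "iterations": config.power_iterations,
        "threshold": config.power_threshold,
        "hit_rate_pct": hit, "false_positive_rate_pct": fp,
    }

    io.write_json_report(report, out / "report.json")
    return report
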