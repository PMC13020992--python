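"""CSV and config I/O.

All CSVs are comma-separated UTF-8 with a header row and '.' decimals;
generated data files carry the generating seed in a leading comment
line (``# seed=<int>``) which readers skip.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .triangle import TriangleShape

__all__ = [
    "write_csv",
    "read_csv",
    "load_design_yaml",
    "write_json_report",
]

TRIANGLE_COLUMNS = [
    "participant_id", "environment", "shape_id", "side",
    "leg1_deg", "mid_turn_deg", "leg2_deg",
    "response_turn_deg", "response_distance_deg", "rt_s",
]

OBJECT_LOCATION_COLUMNS = [
    "participant_id", "environment", "start_lat", "start_lon",
    "target_id", "target_lat", "target_lon", "distance_deg",
    "condition", "direction_error_deg", "position_error_deg",
]

SIMULATION_COLUMNS = [
    "start_lat", "start_lon", "target_lat", "target_lon", "distance_deg",
    "arrangement", "chain_length", "direction_error_deg",
    "position_error_deg", "seed",
]


def write_csv(df: pd.DataFrame, path, seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_design_yaml(path) -> list[TriangleShape]:
    """Load a triangle design file (see ``data/default_design.yaml``)."""
    cfg = yaml.safe_load(Path(path).read_text())
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


def write_json_report(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))


def _coerce(x):
    try:
        return float(x)
    except (TypeError, ValueError):
        return str(x)
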