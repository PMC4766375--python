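"""Table and config I/O.

CSV schemas
-----------
cells.csv    : id, x_um, y_um, radius_um, is_microglia (0/1),
               is_proliferating (0/1), intensity (float, may be empty)
plaques.csv  : id, x_um, y_um, radius_um
ct.csv       : sample_id, group, gene, ct
panel.csv    : sample_id, group, analyte, concentration_pg_ml,
               below_lod (0/1), lod_pg_ml
trials.csv   : subject_id, trial_index, outcome (alternated/repeated/failed)

Intensity grids are plain CSV matrices (one row per image row); a
single-channel image file readable by Pillow is also accepted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .profiler import RadialProfile
from .simulate import SimulationConfig

__all__ = [
    "SchemaError",
    "read_cells",
    "read_plaques",
    "read_ct_table",
    "read_analyte_panel",
    "read_trials",
    "read_intensity_grid",
    "read_simulation_config",
    "profile_to_dict",
    "profiles_to_json",
]

CELL_COLUMNS = ("id", "x_um", "y_um", "radius_um", "is_microglia")
PLAQUE_COLUMNS = ("id", "x_um", "y_um", "radius_um")


class SchemaError(ValueError):
    pass


def _read_csv(path, required: Sequence[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table {path} missing columns: {missing}")
    return df


def read_cells(path) -> pd.DataFrame:
    df = _read_csv(path, CELL_COLUMNS, "cell")
    if (df["radius_um"] <= 0).any():
        raise SchemaError("cell radii must be > 0")
    return df


def read_plaques(path) -> pd.DataFrame:
    df = _read_csv(path, PLAQUE_COLUMNS, "plaque")
    if (df["radius_um"] <= 0).any():
        raise SchemaError("plaque radii must be > 0")
    return df


def read_ct_table(path) -> pd.DataFrame:
    return _read_csv(path, ("sample_id", "group", "gene", "ct"), "Ct")


def read_analyte_panel(path) -> pd.DataFrame:
    return _read_csv(
        path,
        ("sample_id", "group", "analyte", "concentration_pg_ml", "below_lod", "lod_pg_ml"),
        "analyte panel",
    )


def read_trials(path) -> pd.DataFrame:
    return _read_csv(path, ("subject_id", "trial_index", "outcome"), "trial")


def read_intensity_grid(path) -> np.ndarray:
    """Load an intensity grid from a CSV matrix or a single-channel image."""
    path = Path(path)
    if path.suffix.lower() in (".csv", ".txt"):
        return np.loadtxt(path, delimiter=",", ndmin=2)
    from PIL import Image

    with Image.open(path) as img:
        return np.asarray(img.convert("F"), dtype=float)


def read_simulation_config(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError(f"config {path} must be a mapping")
    return SimulationConfig(**data)


def profile_to_dict(profile: RadialProfile) -> dict:
    return {
        "plaque_id": profile.plaque_id,
        "plaque_radius_um": profile.plaque_radius_um,
        "step_um": profile.step_um,
        "cells_inside_plaque": profile.cells_inside_plaque,
        "stop_reason": profile.stop_reason,
        "annuli": [
            {
                "inner_r_um": a.inner_r_um,
                "outer_r_um": a.outer_r_um,
                "count": a.cell_count,
                "area_mm2": a.area_mm2,
                "density_per_mm2": a.density_per_mm2,
            }
            for a in profile.annuli
        ],
    }


def profiles_to_json(
    profiles: Sequence[RadialProfile], aggregate: pd.DataFrame | None = None
) -> str:
    payload: dict = {"profiles": [profile_to_dict(p) for p in profiles]}
    if aggregate is not None:
        payload["aggregate"] = aggregate.to_dict(orient="records")
    return json.dumps(payload, indent=2)
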