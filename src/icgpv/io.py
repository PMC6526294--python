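"""Readers and writers for the plate and participant CSV schemas.

CSV dialect is fixed: comma-separated, UTF-8, header required, dot decimal.
Units are carried in column names (uL, mg/L, seconds, g) and never inferred.

Plate schema (long; one row per read, triplicates share a label)::

    well,label,role,nominal_conc_mg_L,draw_time_s,absorbance

Participant metadata schema::

    id,weight_kg,height_cm[,age_y,bmi,body_fat_pct,syringe_pre_g,syringe_post_g]
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .calibration import VALID_ROLES, WellGroup
from .kinetics import TimedConcentration

PLATE_COLUMNS = ["well", "label", "role", "nominal_conc_mg_L", "draw_time_s", "absorbance"]
PARTICIPANT_REQUIRED = ["id", "weight_kg", "height_cm"]


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Load and validate a long-format plate export."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV {path} missing columns: {missing}")
    bad_roles = set(df["role"].unique()) - VALID_ROLES
    if bad_roles:
        raise ValueError(f"plate CSV {path} has unknown roles: {sorted(bad_roles)}")
    if not np.all(np.isfinite(df["absorbance"].to_numpy(dtype=float))):
        raise ValueError(f"plate CSV {path} has non-finite absorbances")
    return df[PLATE_COLUMNS]


def plate_groups(plate: pd.DataFrame) -> List[WellGroup]:
    """Collapse plate rows into replicate :class:`WellGroup` objects."""
    groups: list[WellGroup] = []
    for (role, label), sub in plate.groupby(["role", "label"], sort=False):
        nominal = sub["nominal_conc_mg_L"].iloc[0]
        draw = sub["draw_time_s"].iloc[0]
        groups.append(
            WellGroup(
                role=str(role),
                label=str(label),
                absorbances=tuple(float(a) for a in sub["absorbance"]),
                nominal_conc=None if pd.isna(nominal) else float(nominal),
                draw_time_s=None if pd.isna(draw) else float(draw),
            )
        )
    return groups


def read_participants_csv(path: str | Path) -> pd.DataFrame:
    """Load and validate participant metadata."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in PARTICIPANT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"participant CSV {path} missing columns: {missing}")
    if df["id"].duplicated().any():
        raise ValueError(f"participant CSV {path} has duplicate ids")
    if (df["weight_kg"] <= 0).any() or (df["height_cm"] <= 0).any():
        raise ValueError(f"participant CSV {path} has non-positive weight/height")
    return df


def read_timed_concentrations(path: str | Path) -> dict[str, List[TimedConcentration]]:
    """Read a `participant_id,draw_time_s,conc_mg_L` CSV into sample lists."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    need = ["participant_id", "draw_time_s", "conc_mg_L"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"concentration CSV {path} missing columns: {missing}")
    out: dict[str, List[TimedConcentration]] = {}
    for pid, sub in df.groupby("participant_id", sort=False):
        out[str(pid)] = [
            TimedConcentration(draw_time_s=float(t), conc=float(c))
            for t, c in zip(sub["draw_time_s"], sub["conc_mg_L"])
        ]
    return out


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=float) + "\n")


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
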