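"""Run configuration for the bench protocol.

All physical defaults mirror the two-hour bench workflow: a 2.5 mg/mL ICG
stock, a 0.25 mg/kg target dose, a five-level plasma-matrix standard series
(2.5-10 mg/L) within the Beer-Lambert linear range (<= 15 mg/L at 805 nm),
and timed draws between 2 and 5 minutes post-injection.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Tuple

import yaml
from pydantic import BaseModel, Field, model_validator

#: Final concentrations (mg/L, after 1:1 plasma mixing) used by default.
DEFAULT_STANDARD_SERIES: Tuple[float, ...] = (2.5, 3.75, 5.0, 7.5, 10.0)

#: The full six-level series of the bench tables, up to the linear cap.
FULL_STANDARD_SERIES: Tuple[float, ...] = (2.5, 3.75, 5.0, 7.5, 10.0, 15.0)

#: Nominal post-injection draw schedule, seconds from start of injection.
DEFAULT_DRAW_TIMES_S: Tuple[float, ...] = (120.0, 165.0, 210.0, 255.0, 300.0)


class RunConfig(BaseModel):
    """Validated configuration shared by the CLI and the model objects."""

    model_config = {"frozen": True}

    stock_conc_mg_ml: float = Field(2.5, gt=0, description="ICG stock, mg/mL")
    target_dose_per_kg: float = Field(0.25, gt=0, description="mg ICG per kg body weight")
    linear_cap_mg_l: float = Field(15.0, gt=0, description="upper bound of the linear range, mg/L")
    standard_series: Tuple[float, ...] = DEFAULT_STANDARD_SERIES
    fit_window_s: Tuple[float, float] = (120.0, 300.0)
    window_grace_s: float = Field(
        15.0,
        ge=0,
        description="tolerance around the fit window for recorded draw times",
    )
    density_g_ml: float = Field(1.0, gt=0, description="ICG solution density for weight->volume")
    bsa_formula: Literal["dubois", "mosteller"] = "dubois"
    cv_warn_pct: float = Field(15.0, gt=0, description="triplicate CV warning threshold, %")
    seed: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _check_physical(self) -> "RunConfig":
        if not self.standard_series:
            raise ValueError("standard_series must be non-empty")
        for c in self.standard_series:
            if not 0 <= c <= self.linear_cap_mg_l:
                raise ValueError(
                    f"standard concentration {c} mg/L outside [0, {self.linear_cap_mg_l}]"
                )
        lo, hi = self.fit_window_s
        if not 0 <= lo < hi:
            raise ValueError("fit_window_s must satisfy 0 <= lo < hi")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        """Stable SHA-256 over the canonical JSON serialisation."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()
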