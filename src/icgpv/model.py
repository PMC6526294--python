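"""Model/Results objects tying calibration, kinetics and PV together.

:class:`PlasmaVolumeModel` holds one participant's plate data and dose;
``fit()`` runs calibrate -> invert -> log-linear decay fit -> PV under both
back-extrapolation conventions and returns a :class:`PlasmaVolumeResults`
carrying the estimates, their standard errors, QC diagnostics and a
``summary()`` table.  :class:`CohortModel` does the same for a whole study
directory and adds cohort summaries and PV-vs-anthropometry associations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationCurve,
    WellGroup,
    average_wells,
    fit_calibration,
    invert_absorbance_checked,
)
from .cohort import (
    CohortSummary,
    ICGDose,
    ParticipantRecord,
    PVResult,
    build_pv_result,
    summarize_cohort,
)
from .config import RunConfig
from .exceptions import InsufficientDataError
from .io import plate_groups, read_participants_csv, read_plate_csv
from .kinetics import DecayFit, TimedConcentration, fit_decay

logger = logging.getLogger("icgpv")


@dataclass(frozen=True)
class GroupQC:
    role: str
    label: str
    n_reads: int
    mean_au: float
    cv_pct: float
    high_cv: bool


class PlasmaVolumeModel:
    """Indicator-dilution PV model for a single participant.

    Parameters
    ----------
    plate : DataFrame
        Long-format plate export (see :mod:`icgpv.io` for the schema).
    dose : float or ICGDose
        Injected ICG mass in mg, or the syringe-weighing record from which
        it is computed.
    participant : ParticipantRecord, optional
        Enables weight/BSA-normalised outputs.
    config : RunConfig, optional
    """

    def __init__(
        self,
        plate: pd.DataFrame,
        dose: float | ICGDose,
        participant: ParticipantRecord | None = None,
        config: RunConfig | None = None,
    ):
        self.plate = plate
        self.dose_mg = dose.dose_mg if isinstance(dose, ICGDose) else float(dose)
        if self.dose_mg <= 0:
            raise ValueError("dose must be positive")
        self.participant = participant
        self.config = config or RunConfig()

    @classmethod
    def from_files(
        cls,
        plate_csv: str | Path,
        dose: float | ICGDose,
        participant: ParticipantRecord | None = None,
        config: RunConfig | None = None,
    ) -> "PlasmaVolumeModel":
        return cls(read_plate_csv(plate_csv), dose, participant, config)

    def fit(self) -> "PlasmaVolumeResults":
        cfg = self.config
        groups = plate_groups(self.plate)
        qc: list[GroupQC] = []
        standards: list[tuple[float, float]] = []
        samples: list[WellGroup] = []
        warnings: list[str] = []
        for g in groups:
            mean, cv = average_wells(g)
            high = math.isfinite(cv) and cv > cfg.cv_warn_pct
            qc.append(GroupQC(g.role, g.label, len(g.absorbances), mean, cv, high))
            if high:
                warnings.append(f"group {g.label!r}: triplicate CV {cv:.1f}% > {cfg.cv_warn_pct}%")
            if g.role == "standard":
                if g.nominal_conc is None:
                    raise ValueError(f"standard group {g.label!r} lacks nominal_conc_mg_L")
                standards.append((g.nominal_conc, mean))
            elif g.role == "sample":
                if g.draw_time_s is None:
                    raise ValueError(f"sample group {g.label!r} lacks draw_time_s")
                samples.append(g)

        curve = fit_calibration(standards, linear_cap=cfg.linear_cap_mg_l)

        timed: list[TimedConcentration] = []
        exclusions: list[dict] = []
        # a draw recorded within a few seconds of the window edge is still an
        # elimination-phase draw; the grace keeps jittered edge draws in
        lo = cfg.fit_window_s[0] - cfg.window_grace_s
        hi = cfg.fit_window_s[1] + cfg.window_grace_s
        for g in samples:
            mean = next(q.mean_au for q in qc if q.role == "sample" and q.label == g.label)
            conc, above, clamped = invert_absorbance_checked(curve, mean)
            if above:
                exclusions.append(
                    {"label": g.label, "reason": "above-linear-range", "conc_mg_L": conc}
                )
                continue
            if clamped or conc <= 0:
                exclusions.append(
                    {"label": g.label, "reason": "nonpositive-concentration", "conc_mg_L": conc}
                )
                continue
            if not lo <= g.draw_time_s <= hi:
                exclusions.append(
                    {"label": g.label, "reason": "outside-fit-window", "draw_time_s": g.draw_time_s}
                )
                continue
            timed.append(TimedConcentration(draw_time_s=g.draw_time_s, conc=conc))
        for ex in exclusions:
            logger.warning("excluded sample %s: %s", ex["label"], ex["reason"])
        if len(timed) < 3:
            raise InsufficientDataError(
                f"only {len(timed)} usable timed samples after exclusions "
                f"({[e['reason'] for e in exclusions]})"
            )

        decay = fit_decay(timed)
        if not decay.physiologic:
            warnings.append("non-negative decay slope: nonphysiologic fit")
        rec = self.participant
        pv = build_pv_result(
            self.dose_mg,
            decay,
            weight_kg=rec.weight_kg if rec else None,
            height_cm=rec.height_cm if rec else None,
            bsa_formula=cfg.bsa_formula,
        )
        return PlasmaVolumeResults(
            model=self,
            calibration=curve,
            decay=decay,
            pv=pv,
            concentrations=tuple(timed),
            group_qc=tuple(qc),
            exclusions=tuple(exclusions),
            warnings=tuple(warnings),
        )


@dataclass(frozen=True)
class PlasmaVolumeResults:
    """Fitted PV estimates with uncertainties and QC diagnostics."""

    model: PlasmaVolumeModel
    calibration: CalibrationCurve
    decay: DecayFit
    pv: PVResult
    concentrations: Tuple[TimedConcentration, ...]
    group_qc: Tuple[GroupQC, ...]
    exclusions: Tuple[dict, ...]
    warnings: Tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "dose_mg": self.pv.dose_mg,
            "calibration": {
                "slope_au_per_mg_l": self.calibration.slope,
                "intercept_au": self.calibration.intercept,
                "r": self.calibration.r,
                "n_points": self.calibration.n_points,
                "valid_range_mg_l": list(self.calibration.valid_range),
            },
            "decay": {
                "slope_per_s": self.decay.slope_per_s,
                "ln_intercept": self.decay.ln_intercept,
                "r": self.decay.r,
                "n_points": self.decay.n_points,
                "k_per_min": self.decay.k_per_min,
                "c0_t0_mg_l": self.decay.c0_t0,
                "c_t60_mg_l": self.decay.c_t60,
                "half_life_min": self.decay.half_life_min,
                "pdr_pct_per_min": self.decay.pdr_pct_per_min,
                "window_s": list(self.decay.window_s) if self.decay.window_s else None,
            },
            "pv": {k: v for k, v in asdict(self.pv).items()},
            "group_cvs": {q.label: q.cv_pct for q in self.group_qc},
            "exclusions": list(self.exclusions),
            "warnings": list(self.warnings),
        }

    def summary(self) -> str:
        p = self.pv
        d = self.decay
        lines = [
            "Indicator-dilution plasma volume (ICG, 805 nm)",
            "=" * 54,
            f"Dose D                 {p.dose_mg:10.3f} mg",
            f"Calibration slope      {self.calibration.slope:10.5f} AU/(mg/L)   r = {self.calibration.r:.4f}",
            f"Decay fit (n={d.n_points})        k = {d.k_per_min:.4f} /min        r = {d.r:.4f}",
            f"C0 (t=0)               {d.c0_t0:10.4f} mg/L",
            f"C (t=1 min)            {d.c_t60:10.4f} mg/L",
            f"PV (t=0)               {p.pv_t0_ml:10.1f} mL"
            + (f"  (SE {p.pv_t0_se_ml:.1f})" if p.pv_t0_se_ml is not None else ""),
            f"PV (t=1 min)           {p.pv_t1_ml:10.1f} mL"
            + (f"  (SE {p.pv_t1_se_ml:.1f})" if p.pv_t1_se_ml is not None else ""),
            f"Half-life              {p.half_life_min:10.3f} min",
            f"PDR                    {p.pdr_pct_per_min:10.2f} %/min",
            f"Clearance (t=0)        {p.clearance_t0_ml_min:10.1f} mL/min",
        ]
        if p.pv_per_kg_ml is not None:
            lines.append(f"PV / weight            {p.pv_per_kg_ml:10.2f} mL/kg")
        if p.pv_per_bsa_ml_m2 is not None:
            lines.append(f"PV / BSA               {p.pv_per_bsa_ml_m2:10.1f} mL/m^2")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        for e in self.exclusions:
            lines.append(f"excluded: {e['label']} ({e['reason']})")
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------
    def plot_calibration(self, ax=None):
        """Standard curve: absorbance vs concentration with the OLS line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = [(q.label, q.mean_au) for q in self.group_qc if q.role == "standard"]
        concs = [g.nominal_conc for g in plate_groups(self.model.plate) if g.role == "standard"]
        means = [m for _, m in pts]
        ax.scatter(concs, means, color="k", zorder=3)
        xs = np.linspace(0, self.calibration.valid_range[1], 50)
        ax.plot(xs, self.calibration.slope * xs + self.calibration.intercept, "g-")
        ax.set_xlabel("ICG concentration (mg/L)")
        ax.set_ylabel("Absorbance at 805 nm (AU)")
        ax.set_title(f"Standard curve (r = {self.calibration.r:.3f})")
        return ax

    def plot_decay(self, ax=None):
        """ln-concentration vs time with the back-extrapolated line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = [c.draw_time_s for c in self.concentrations]
        y = [math.log(c.conc) for c in self.concentrations]
        ax.scatter(t, y, color="k", zorder=3)
        xs = np.linspace(0, max(t), 100)
        ax.plot(xs, self.decay.ln_intercept + self.decay.slope_per_s * xs, "g--")
        ax.scatter([0, 60], [self.decay.ln_intercept, math.log(self.decay.c_t60)], marker="x", color="r")
        ax.set_xlabel("Time since injection (s)")
        ax.set_ylabel("ln ICG concentration (mg/L)")
        ax.set_title(f"Decay curve (k = {self.decay.k_per_min:.3f}/min, r = {self.decay.r:.3f})")
        return ax


# ---------------------------------------------------------------------------
# Cohort level
# ---------------------------------------------------------------------------

COHORT_TABLE_COLUMNS = [
    "id", "age_y", "weight_kg", "height_cm", "bmi", "body_fat_pct",
    "dose_mg", "pv_t0_ml", "pv_t1_ml", "pv_per_kg_ml", "bsa_m2",
    "pv_per_bsa_ml_m2", "k_per_min", "half_life_min", "pdr_pct_per_min",
    "clearance_t0_ml_min", "calibration_r", "decay_r",
]


class CohortModel:
    """Fit the PV pipeline for every participant in a study.

    ``participants`` is the metadata table; ``plates`` maps participant id
    to that subject's plate DataFrame.  Doses come from the syringe-weight
    columns when present, otherwise from the planned 0.25 mg/kg dose.
    """

    def __init__(
        self,
        participants: pd.DataFrame,
        plates: Mapping[str, pd.DataFrame],
        config: RunConfig | None = None,
    ):
        self.participants = participants
        self.plates = dict(plates)
        self.config = config or RunConfig()
        ids = set(participants["id"])
        missing = ids - set(self.plates)
        extra = set(self.plates) - ids
        if missing or extra:
            raise ValueError(
                f"participant/plate id mismatch: missing plates {sorted(missing)}, "
                f"unmatched plates {sorted(extra)}"
            )

    @classmethod
    def from_study_dir(cls, study_dir: str | Path, config: RunConfig | None = None) -> "CohortModel":
        """Load a study directory (`participants.csv` + `plate_<id>.csv`)."""
        study_dir = Path(study_dir)
        participants = read_participants_csv(study_dir / "participants.csv")
        plates = {
            pid: read_plate_csv(study_dir / f"plate_{pid}.csv")
            for pid in participants["id"]
        }
        return cls(participants, plates, config)

    def _dose_for(self, row: pd.Series) -> float | ICGDose:
        cfg = self.config
        if "syringe_pre_g" in row.index and pd.notna(row.get("syringe_pre_g")):
            return ICGDose(
                syringe_weight_pre_g=float(row["syringe_pre_g"]),
                syringe_weight_post_g=float(row["syringe_post_g"]),
                stock_conc_mg_ml=cfg.stock_conc_mg_ml,
                density_g_ml=cfg.density_g_ml,
                target_dose_per_kg=cfg.target_dose_per_kg,
            )
        return cfg.target_dose_per_kg * float(row["weight_kg"])

    def fit(self) -> "CohortResults":
        per: dict[str, PlasmaVolumeResults] = {}
        records: dict[str, ParticipantRecord] = {}
        for _, row in self.participants.iterrows():
            pid = str(row["id"])
            rec = ParticipantRecord(
                id=pid,
                weight_kg=float(row["weight_kg"]),
                height_cm=float(row["height_cm"]),
                age_y=float(row["age_y"]) if "age_y" in row.index and pd.notna(row.get("age_y")) else None,
                body_fat_pct=float(row["body_fat_pct"])
                if "body_fat_pct" in row.index and pd.notna(row.get("body_fat_pct"))
                else None,
            )
            model = PlasmaVolumeModel(self.plates[pid], self._dose_for(row), rec, self.config)
            res = model.fit()
            logger.info(
                "participant %s: PV(t=0)=%.0f mL, k=%.3f/min, cal r=%.4f, decay r=%.4f, n=%d",
                pid, res.pv.pv_t0_ml, res.pv.k_per_min, res.calibration.r,
                res.decay.r, res.decay.n_points,
            )
            per[pid] = res
            records[pid] = rec
        summary = summarize_cohort([(records[pid], per[pid].pv) for pid in per])
        return CohortResults(model=self, results=per, records=records, summary_stats=summary)


@dataclass(frozen=True)
class CohortResults:
    model: CohortModel
    results: Dict[str, PlasmaVolumeResults]
    records: Dict[str, ParticipantRecord]
    summary_stats: CohortSummary

    def table(self) -> pd.DataFrame:
        """Per-participant results table (one row per subject)."""
        rows = []
        for pid, res in self.results.items():
            rec, p = self.records[pid], res.pv
            rows.append(
                {
                    "id": pid,
                    "age_y": rec.age_y,
                    "weight_kg": rec.weight_kg,
                    "height_cm": rec.height_cm,
                    "bmi": rec.bmi,
                    "body_fat_pct": rec.body_fat_pct,
                    "dose_mg": p.dose_mg,
                    "pv_t0_ml": p.pv_t0_ml,
                    "pv_t1_ml": p.pv_t1_ml,
                    "pv_per_kg_ml": p.pv_per_kg_ml,
                    "bsa_m2": p.bsa_m2,
                    "pv_per_bsa_ml_m2": p.pv_per_bsa_ml_m2,
                    "k_per_min": p.k_per_min,
                    "half_life_min": p.half_life_min,
                    "pdr_pct_per_min": p.pdr_pct_per_min,
                    "clearance_t0_ml_min": p.clearance_t0_ml_min,
                    "calibration_r": res.calibration.r,
                    "decay_r": res.decay.r,
                }
            )
        return pd.DataFrame(rows, columns=COHORT_TABLE_COLUMNS)

    def summary(self) -> str:
        s = self.summary_stats
        lines = [
            f"ICG dye-dilution cohort (n = {s.n})",
            "=" * 58,
            f"{'variable':<22}{'mean':>12}{'SD':>12}",
        ]
        for key in (
            "age_y", "weight_kg", "height_cm", "bmi", "bsa_m2",
            "pv_t0_ml", "pv_t1_ml", "pv_per_kg_ml", "pv_per_bsa_ml_m2",
            "k_per_min", "half_life_min", "pdr_pct_per_min", "clearance_t0_ml_min",
        ):
            lines.append(f"{key:<22}{s.means[key]:>12.3f}{s.sds[key]:>12.3f}")
        lines.append("")
        lines.append("PV(t=0) associations (Spearman / OLS slope [95% CI]):")
        for pred, a in s.associations.items():
            lines.append(
                f"  {pred:<12} r = {a.spearman_r:6.3f}  p = {a.spearman_p:6.4f} "
                f"({a.p_method}); slope = {a.ols_slope:.3f} "
                f"[{a.ols_ci95[0]:.3f}, {a.ols_ci95[1]:.3f}] mL per unit"
            )
        return "\n".join(lines)

    def to_report(self) -> dict:
        s = self.summary_stats
        return {
            "n": s.n,
            "means": s.means,
            "sds": s.sds,
            "associations": {
                pred: {
                    "spearman_r": a.spearman_r,
                    "spearman_p": a.spearman_p,
                    "p_method": a.p_method,
                    "ols_slope_ml_per_unit": a.ols_slope,
                    "ols_ci95": list(a.ols_ci95),
                }
                for pred, a in s.associations.items()
            },
        }
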