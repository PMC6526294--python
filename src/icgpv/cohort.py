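"""Dose computation, plasma volume, normalisation and cohort summaries.

PV follows the indicator-dilution principle: an injected tracer mass D (mg)
fully mixed in a plasma volume V gives concentration C = D/V, so V = D/C.
Both back-extrapolation conventions (t = 0 and t = 1 min) are always
reported side by side; they are linked exactly by PV_t1 = PV_t0 * e^k.
PV is additionally normalised by body weight and by Du Bois body surface
area, and cohort-level associations of PV with anthropometrics use Spearman
rank correlation (exact-permutation p-values at small n) plus an OLS slope
with a normal-theory 95% CI.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import InsufficientDataError
from .kinetics import DecayFit, clearance

#: Largest n for which the Spearman p-value is computed by exhaustive
#: enumeration of all n! pairings (9! = 362,880 is still cheap).
EXACT_PERM_MAX_N = 9


@dataclass(frozen=True)
class ParticipantRecord:
    """Anthropometrics and optional QC fields for one subject."""

    id: str
    weight_kg: float
    height_cm: float
    age_y: float | None = None
    bmi: float | None = None
    body_fat_pct: float | None = None
    sbp_mmhg: float | None = None
    dbp_mmhg: float | None = None

    def __post_init__(self) -> None:
        if self.weight_kg <= 0 or self.height_cm <= 0:
            raise ValueError("weight and height must be positive")
        derived = self.weight_kg / (self.height_cm / 100.0) ** 2
        if self.bmi is None:
            object.__setattr__(self, "bmi", derived)
        elif abs(self.bmi - derived) > 0.1:
            raise ValueError(
                f"participant {self.id}: BMI {self.bmi} inconsistent with "
                f"weight/height (derived {derived:.2f})"
            )


@dataclass(frozen=True)
class ICGDose:
    """Gravimetric determination of the injected ICG mass.

    The syringe is weighed full and again after the injection; the mass
    difference, divided by the solution density and multiplied by the stock
    concentration, is the exact dose delivered.
    """

    syringe_weight_pre_g: float
    syringe_weight_post_g: float
    stock_conc_mg_ml: float = 2.5
    density_g_ml: float = 1.0
    target_dose_per_kg: float = 0.25

    def __post_init__(self) -> None:
        if self.syringe_weight_pre_g <= self.syringe_weight_post_g:
            raise ValueError("pre-injection syringe weight must exceed post-injection")
        if self.stock_conc_mg_ml <= 0 or self.density_g_ml <= 0:
            raise ValueError("stock concentration and density must be positive")

    @property
    def dose_mg(self) -> float:
        injected_ml = (
            self.syringe_weight_pre_g - self.syringe_weight_post_g
        ) / self.density_g_ml
        return injected_ml * self.stock_conc_mg_ml


def compute_dose(dose: ICGDose) -> float:
    """Injected ICG mass in mg from the syringe weight difference."""
    return dose.dose_mg


def planned_injection_volume_ml(
    weight_kg: float, target_dose_per_kg: float = 0.25, stock_conc_mg_ml: float = 2.5
) -> float:
    """Syringe volume to draw: dose_per_kg * weight / stock concentration."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    return target_dose_per_kg * weight_kg / stock_conc_mg_ml


def dubois_bsa(weight_kg: float, height_cm: float) -> float:
    """Du Bois-Du Bois body surface area, m^2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def mosteller_bsa(weight_kg: float, height_cm: float) -> float:
    """Mosteller body surface area, m^2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return math.sqrt(weight_kg * height_cm / 3600.0)


_BSA_FORMULAS = {"dubois": dubois_bsa, "mosteller": mosteller_bsa}


def body_surface_area(weight_kg: float, height_cm: float, formula: str = "dubois") -> float:
    try:
        return _BSA_FORMULAS[formula](weight_kg, height_cm)
    except KeyError:
        raise ValueError(f"unknown BSA formula {formula!r}") from None


def compute_pv(dose_mg: float, c0: float) -> float:
    """Plasma volume in litres: D (mg) / C0 (mg/L)."""
    if dose_mg <= 0:
        raise ValueError(f"dose must be positive, got {dose_mg}")
    if c0 <= 0:
        raise ValueError(f"extrapolated concentration must be positive, got {c0}")
    return dose_mg / c0


@dataclass(frozen=True)
class PVResult:
    """Plasma volume under both conventions with normalised derivatives."""

    dose_mg: float
    k_per_min: float
    pv_t0_ml: float
    pv_t1_ml: float
    half_life_min: float
    pdr_pct_per_min: float
    clearance_t0_ml_min: float
    pv_per_kg_ml: float | None = None
    bsa_m2: float | None = None
    pv_per_bsa_ml_m2: float | None = None
    pv_t0_se_ml: float | None = None
    pv_t1_se_ml: float | None = None


def build_pv_result(
    dose_mg: float,
    fit: DecayFit,
    weight_kg: float | None = None,
    height_cm: float | None = None,
    bsa_formula: str = "dubois",
) -> PVResult:
    """Combine the dose and a decay fit into the full PV result.

    Normalised quantities are filled in when anthropometrics are supplied.
    Standard errors propagate the uncertainty of the back-extrapolated
    ln-concentration (delta method); dose uncertainty is negligible with
    gravimetric dosing and is not propagated.
    """
    pv_t0_l = compute_pv(dose_mg, fit.c0_t0)
    pv_t1_l = compute_pv(dose_mg, fit.c_t60)
    pv_t0_ml = 1000.0 * pv_t0_l
    pv_t1_ml = 1000.0 * pv_t1_l
    se0 = se1 = None
    if math.isfinite(fit.se_ln_intercept):
        se0 = pv_t0_ml * fit.se_ln_intercept
        se1 = pv_t1_ml * fit.se_ln_conc(60.0)
    per_kg = pv_t0_ml / weight_kg if weight_kg else None
    bsa = pv_bsa = None
    if weight_kg and height_cm:
        bsa = body_surface_area(weight_kg, height_cm, bsa_formula)
        pv_bsa = pv_t0_ml / bsa
    return PVResult(
        dose_mg=dose_mg,
        k_per_min=fit.k_per_min,
        pv_t0_ml=pv_t0_ml,
        pv_t1_ml=pv_t1_ml,
        half_life_min=fit.half_life_min,
        pdr_pct_per_min=fit.pdr_pct_per_min,
        clearance_t0_ml_min=clearance(fit.k_per_min, pv_t0_ml) if fit.physiologic else float("nan"),
        pv_per_kg_ml=per_kg,
        bsa_m2=bsa,
        pv_per_bsa_ml_m2=pv_bsa,
        pv_t0_se_ml=se0,
        pv_t1_se_ml=se1,
    )


# ---------------------------------------------------------------------------
# Cohort association statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationStats:
    """Spearman correlation and OLS slope of PV against one predictor."""

    predictor: str
    spearman_r: float
    spearman_p: float
    p_method: str  # "exact-permutation" or "asymptotic"
    ols_slope: float
    ols_ci95: Tuple[float, float]
    degenerate: bool = False


@dataclass(frozen=True)
class CohortSummary:
    n: int
    means: Dict[str, float]
    sds: Dict[str, float]
    associations: Dict[str, AssociationStats]


def spearman_exact(
    x: Sequence[float],
    y: Sequence[float],
    max_exact_n: int = EXACT_PERM_MAX_N,
    _perms: np.ndarray | None = None,
) -> Tuple[float, float, str]:
    """Spearman rank correlation with an exact-permutation two-sided p.

    Ties are mid-ranked.  For n <= ``max_exact_n`` the p-value is the exact
    fraction of all n! pairings whose |r| is at least the observed |r|;
    above that the usual t approximation (scipy) is used.  Returns
    (r, p, method).  Degenerate (constant) inputs give (nan, nan, ...).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise InsufficientDataError("need >=3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), "degenerate"
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.linalg.norm(rxc) * np.linalg.norm(ryc)
    r_obs = float(rxc @ ryc / denom)
    if n <= max_exact_n:
        perms = _perms if _perms is not None else enumerate_rank_permutations(ry)
        r_all = perms @ rxc / denom
        p = float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))
        return r_obs, p, "exact-permutation"
    p = float(stats.spearmanr(x, y).pvalue)
    return r_obs, p, "asymptotic"


def enumerate_rank_permutations(ranks: np.ndarray) -> np.ndarray:
    """All n! orderings of a rank vector, as an (n!, n) array.

    Centred on output so that a dot with a centred partner vector gives the
    permutation-null numerator directly.
    """
    perms = np.array(list(itertools.permutations(ranks)), dtype=float)
    return perms - perms.mean(axis=1, keepdims=True)


def _ols_slope_ci(x: np.ndarray, y: np.ndarray) -> Tuple[float, Tuple[float, float]]:
    res = sm.OLS(y, sm.add_constant(x)).fit()
    lo, hi = np.asarray(res.conf_int())[1]
    return float(res.params[1]), (float(lo), float(hi))


#: Predictors examined against PV(t=0), and their report units.
PV_PREDICTORS = ("height_cm", "weight_kg", "bmi", "bsa_m2")


def summarize_cohort(
    results: Sequence[Tuple[ParticipantRecord, PVResult]]
) -> CohortSummary:
    """Cohort means/SDs and PV-vs-anthropometry associations.

    Means and SDs (n-1 denominator) cover the anthropometrics and every PV
    quantity; associations relate PV(t=0, mL) to height, weight, BMI and
    BSA via Spearman rank correlation (exact-permutation p for n <= 9) and
    an OLS slope with normal-theory 95% CI.
    """
    if len(results) < 3:
        raise InsufficientDataError(f"cohort summary needs n>=3, got {len(results)}")
    rows: Dict[str, List[float]] = {}

    def put(key: str, value: float | None) -> None:
        rows.setdefault(key, []).append(float("nan") if value is None else float(value))

    for rec, pv in results:
        put("age_y", rec.age_y)
        put("weight_kg", rec.weight_kg)
        put("height_cm", rec.height_cm)
        put("bmi", rec.bmi)
        put("body_fat_pct", rec.body_fat_pct)
        put("bsa_m2", pv.bsa_m2 if pv.bsa_m2 is not None else None)
        put("pv_t0_ml", pv.pv_t0_ml)
        put("pv_t1_ml", pv.pv_t1_ml)
        put("pv_per_kg_ml", pv.pv_per_kg_ml)
        put("pv_per_bsa_ml_m2", pv.pv_per_bsa_ml_m2)
        put("k_per_min", pv.k_per_min)
        put("half_life_min", pv.half_life_min)
        put("pdr_pct_per_min", pv.pdr_pct_per_min)
        put("clearance_t0_ml_min", pv.clearance_t0_ml_min)

    arrays = {k: np.asarray(v) for k, v in rows.items()}
    means = {k: float(np.nanmean(v)) if not np.all(np.isnan(v)) else float("nan") for k, v in arrays.items()}
    sds = {
        k: float(np.nanstd(v, ddof=1)) if np.sum(~np.isnan(v)) > 1 else float("nan")
        for k, v in arrays.items()
    }

    pv0 = arrays["pv_t0_ml"]
    n = len(results)
    shared_perms = (
        enumerate_rank_permutations(stats.rankdata(pv0))
        if (n <= EXACT_PERM_MAX_N and np.ptp(pv0) > 0)
        else None
    )
    associations: Dict[str, AssociationStats] = {}
    for pred in PV_PREDICTORS:
        x = arrays[pred]
        if np.any(np.isnan(x)) or np.ptp(x) == 0 or np.ptp(pv0) == 0:
            associations[pred] = AssociationStats(
                predictor=pred,
                spearman_r=float("nan"),
                spearman_p=float("nan"),
                p_method="degenerate",
                ols_slope=float("nan"),
                ols_ci95=(float("nan"), float("nan")),
                degenerate=True,
            )
            continue
        r, p, method = spearman_exact(x, pv0, _perms=shared_perms)
        slope, ci = _ols_slope_ci(x, pv0)
        associations[pred] = AssociationStats(
            predictor=pred,
            spearman_r=r,
            spearman_p=p,
            p_method=method,
            ols_slope=slope,
            ols_ci95=ci,
        )
    return CohortSummary(n=n, means=means, sds=sds, associations=associations)
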