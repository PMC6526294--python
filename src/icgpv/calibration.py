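"""Standard-series planning and plasma-matrix calibration for ICG at 805 nm.

The bench protocol builds, for every participant, a fresh calibration curve
from known ICG spikes in that participant's own pre-injection plasma.  The
absorbance/concentration relation is linear (Beer-Lambert) up to about
15 mg/L, so the curve is an unweighted ordinary-least-squares line and the
plasma background is absorbed into its intercept: matrix-matched standards
make an explicit blank subtraction unnecessary, and the blank wells are kept
for QC only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import stats

from .exceptions import (
    InfeasibleDilutionError,
    InsufficientDataError,
    InvalidCurveError,
)

DEFAULT_LINEAR_CAP_MG_L = 15.0

VALID_ROLES = frozenset({"blank", "standard", "sample"})


@dataclass(frozen=True)
class DilutionStep:
    """One aqueous pre-dilution of the ICG stock (volumes in microlitres)."""

    target_conc: float  # mg/L
    stock_volume: float  # uL
    diluent_volume: float  # uL
    total_volume: float  # uL

    def __post_init__(self) -> None:
        if min(self.stock_volume, self.diluent_volume, self.total_volume) < 0:
            raise ValueError("dilution volumes must be non-negative")
        if not math.isclose(
            self.stock_volume + self.diluent_volume, self.total_volume, rel_tol=1e-9
        ):
            raise ValueError("stock + diluent volume must equal total volume")


@dataclass(frozen=True)
class PlasmaStandard:
    """An aqueous standard mixed 1:1 (by default) with blank plasma."""

    premix_conc: float  # mg/L
    standard_volume: float  # uL
    plasma_volume: float  # uL
    final_conc: float  # mg/L

    def __post_init__(self) -> None:
        if self.final_conc > self.premix_conc * (1 + 1e-12):
            raise ValueError("mixing with plasma cannot raise the concentration")


@dataclass(frozen=True)
class WellGroup:
    """Replicate absorbance reads sharing one role/label on the plate.

    ``nominal_conc`` (mg/L) is set for standards, ``draw_time_s`` for timed
    post-injection samples; blanks carry neither.
    """

    role: str
    label: str
    absorbances: Tuple[float, ...]
    nominal_conc: float | None = None
    draw_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"role must be one of {sorted(VALID_ROLES)}, got {self.role!r}")
        if len(self.absorbances) == 0:
            raise InsufficientDataError(f"well group {self.label!r} has no readings")
        for a in self.absorbances:
            if not math.isfinite(a):
                raise ValueError(f"non-finite absorbance in group {self.label!r}")
            if a < 0:
                raise ValueError(f"negative absorbance in group {self.label!r}")


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line absorbance = slope * conc + intercept, valid on [0, cap] mg/L."""

    slope: float  # AU per (mg/L)
    intercept: float  # AU
    r: float  # Pearson correlation of the fitted points
    n_points: int
    valid_range: Tuple[float, float] = (0.0, DEFAULT_LINEAR_CAP_MG_L)

    def predict(self, conc: float) -> float:
        """Absorbance expected at a given concentration (mg/L)."""
        return self.slope * conc + self.intercept


def plan_standard_dilutions(
    targets: Sequence[float], stock_conc: float, total_volume: float
) -> list[DilutionStep]:
    """Plan aqueous dilutions of the ICG stock to each target concentration.

    Parameters use bench units: ``targets`` and ``stock_conc`` in mg/L,
    ``total_volume`` in uL.  Mass balance (stock_volume * stock_conc =
    target * total_volume) is enforced exactly before volumes are rounded to
    the nearest 1 uL for pipetting.
    """
    if total_volume <= 0:
        raise ValueError("total_volume must be positive")
    if stock_conc <= 0:
        raise ValueError("stock_conc must be positive")
    steps = []
    for target in targets:
        if target < 0:
            raise ValueError(f"negative target concentration {target}")
        if target > stock_conc:
            raise InfeasibleDilutionError(
                f"target {target} mg/L exceeds stock concentration {stock_conc} mg/L"
            )
        stock_exact = target * total_volume / stock_conc
        # mass balance holds by construction; round for 1-uL pipetting
        stock_ul = round(stock_exact)
        steps.append(
            DilutionStep(
                target_conc=target,
                stock_volume=float(stock_ul),
                diluent_volume=float(total_volume - stock_ul),
                total_volume=float(total_volume),
            )
        )
    return steps


def mix_with_plasma(
    premix_conc: float, standard_volume: float, plasma_volume: float
) -> PlasmaStandard:
    """Mix an aqueous standard with blank plasma (which carries no ICG)."""
    if standard_volume < 0 or plasma_volume < 0:
        raise ValueError("volumes must be non-negative")
    total = standard_volume + plasma_volume
    if total == 0:
        raise ValueError("standard and plasma volumes cannot both be zero")
    final = premix_conc * standard_volume / total
    return PlasmaStandard(
        premix_conc=premix_conc,
        standard_volume=standard_volume,
        plasma_volume=plasma_volume,
        final_conc=final,
    )


def average_wells(group: WellGroup) -> tuple[float, float]:
    """Mean absorbance and CV% (SD with n-1 denominator) of a well group.

    The mean is what enters the curve; the CV is a QC quantity only and is
    never used to reject wells automatically.
    """
    a = np.asarray(group.absorbances, dtype=float)
    mean = float(a.mean())
    if len(a) < 2 or mean == 0:
        cv = 0.0 if len(a) < 2 else float("nan")
    else:
        cv = 100.0 * float(a.std(ddof=1)) / mean
    return mean, cv


def fit_calibration(
    points: Iterable[Tuple[float, float]],
    linear_cap: float = DEFAULT_LINEAR_CAP_MG_L,
) -> CalibrationCurve:
    """Fit the OLS absorbance-vs-concentration line through standard points.

    ``points`` are (final concentration mg/L, mean absorbance AU) pairs.
    Requires >= 3 points with at least two distinct concentrations, all
    within the linear range.
    """
    pts = list(points)
    if len(pts) < 3:
        raise InsufficientDataError(f"calibration needs >=3 points, got {len(pts)}")
    conc = np.array([p[0] for p in pts], dtype=float)
    absb = np.array([p[1] for p in pts], dtype=float)
    if conc.min() < 0 or conc.max() > linear_cap * (1 + 1e-9):
        raise ValueError(
            f"standard concentrations must lie in [0, {linear_cap}] mg/L"
        )
    if np.ptp(conc) == 0:
        raise InvalidCurveError("all standard concentrations identical: singular fit")
    res = stats.linregress(conc, absb)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n_points=len(pts),
        valid_range=(0.0, float(linear_cap)),
    )


def invert_absorbance(curve: CalibrationCurve, absorbance: float) -> float:
    """Concentration (mg/L) read off the curve; negative results clamp to 0.

    Use :func:`invert_absorbance_checked` when the above-linear-range and
    clamping flags are needed (the pipeline does).
    """
    conc, _, _ = invert_absorbance_checked(curve, absorbance)
    return conc


def invert_absorbance_checked(
    curve: CalibrationCurve, absorbance: float
) -> tuple[float, bool, bool]:
    """Invert the curve, returning (conc, above_linear_range, clamped)."""
    if curve.slope <= 0:
        raise InvalidCurveError(f"curve slope must be positive, got {curve.slope}")
    raw = (absorbance - curve.intercept) / curve.slope
    above = raw > curve.valid_range[1] * (1 + 1e-9)
    clamped = raw < 0
    return (0.0 if clamped else raw), above, clamped
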