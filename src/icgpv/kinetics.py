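"""Mono-exponential elimination kinetics of plasma ICG.

After a bolus, plasma ICG follows C(t) = C0 * exp(-k t) during the
elimination phase (t ~ 2-5 min).  Concentrations are transformed to natural
logs and regressed on draw time in seconds; back-extrapolating the fitted
line to t = 0 (traditional) or t = 1 min gives the fully mixed concentration
used in PV = D/C0.  Derived per-minute quantities: elimination rate constant
k = -60 * slope, half-life ln2/k, plasma disappearance rate 100*k %/min,
hepatic clearance k * PV.

Natural logarithms are used throughout: a base-10 fit would silently rescale
k by ln(10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, NonpositiveConcentrationError

LN2 = math.log(2.0)


@dataclass(frozen=True)
class TimedConcentration:
    """One plasma ICG concentration at an exactly recorded draw time."""

    draw_time_s: float
    conc: float  # mg/L

    def __post_init__(self) -> None:
        if self.draw_time_s <= 0:
            raise ValueError("draw_time_s must be positive")
        if self.conc <= 0:
            raise NonpositiveConcentrationError(
                f"concentration must be > 0 for the log transform, got {self.conc}"
            )


@dataclass(frozen=True)
class DecayFit:
    """OLS fit of ln(conc) on draw time (seconds), with derived kinetics.

    ``slope_per_s`` is negative for a physiologic fit; ``physiologic`` flags
    a non-negative slope (warning, not an error).  Standard errors come from
    the usual OLS formulas; cov(slope, intercept) = -mean(t) * se_slope**2.
    """

    slope_per_s: float
    ln_intercept: float  # ln(mg/L) at t = 0
    r: float
    n_points: int
    se_slope: float = float("nan")
    se_ln_intercept: float = float("nan")
    cov_slope_intercept: float = float("nan")
    window_s: Tuple[float, float] | None = None

    @property
    def physiologic(self) -> bool:
        return self.slope_per_s < 0

    @property
    def k_per_min(self) -> float:
        """Elimination rate constant, 1/min."""
        return -self.slope_per_s * 60.0

    @property
    def c0_t0(self) -> float:
        """Back-extrapolated concentration at t = 0, mg/L."""
        return math.exp(self.ln_intercept)

    @property
    def c_t60(self) -> float:
        """Back-extrapolated concentration at t = 1 min, mg/L."""
        return math.exp(self.ln_intercept + self.slope_per_s * 60.0)

    @property
    def half_life_min(self) -> float:
        k = self.k_per_min
        return LN2 / k if k > 0 else float("nan")

    @property
    def pdr_pct_per_min(self) -> float:
        """Plasma disappearance rate, % per minute (100 * k)."""
        return 100.0 * self.k_per_min

    def se_ln_conc(self, t_s: float) -> float:
        """Standard error of the fitted ln-concentration at time t."""
        return math.sqrt(
            self.se_ln_intercept**2
            + (t_s**2) * self.se_slope**2
            + 2.0 * t_s * self.cov_slope_intercept
        )


def _as_samples(
    samples: Iterable[TimedConcentration | Tuple[float, float]]
) -> list[TimedConcentration]:
    out = []
    for s in samples:
        if isinstance(s, TimedConcentration):
            out.append(s)
        else:
            t, c = s
            out.append(TimedConcentration(draw_time_s=float(t), conc=float(c)))
    return out


def fit_decay(
    samples: Sequence[TimedConcentration | Tuple[float, float]],
    window_s: Tuple[float, float] | None = None,
) -> DecayFit:
    """Fit ln(conc) vs draw time by OLS.

    ``window_s``, when given, restricts the fit to draws inside the closed
    interval (the default protocol uses 120-300 s).  At least 3 samples with
    distinct times must remain.  Results are invariant to sample order and
    do not require evenly spaced draws.
    """
    pts = _as_samples(samples)
    if window_s is not None:
        lo, hi = window_s
        pts = [p for p in pts if lo <= p.draw_time_s <= hi]
    if len(pts) < 3:
        raise InsufficientDataError(f"decay fit needs >=3 samples, got {len(pts)}")
    t = np.array([p.draw_time_s for p in pts], dtype=float)
    y = np.log([p.conc for p in pts])
    if np.ptp(t) == 0 or len(np.unique(t)) < 2:
        raise ValueError("draw times must not all be identical")
    res = stats.linregress(t, y)
    return DecayFit(
        slope_per_s=float(res.slope),
        ln_intercept=float(res.intercept),
        r=float(res.rvalue),
        n_points=len(pts),
        se_slope=float(res.stderr),
        se_ln_intercept=float(res.intercept_stderr),
        cov_slope_intercept=float(-t.mean() * res.stderr**2),
        window_s=window_s,
    )


def extrapolate_concentration(fit: DecayFit, t_s: float) -> float:
    """Concentration on the fitted line at time ``t_s`` seconds (mg/L)."""
    return math.exp(fit.ln_intercept + fit.slope_per_s * t_s)


def clearance(k_per_min: float, pv_ml: float) -> float:
    """Hepatic ICG clearance k * PV, in mL/min."""
    if k_per_min <= 0:
        raise ValueError(f"k must be positive, got {k_per_min}")
    if pv_ml < 0:
        raise ValueError(f"plasma volume must be non-negative, got {pv_ml}")
    return k_per_min * pv_ml
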