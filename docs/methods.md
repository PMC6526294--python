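# Methods

## Measurement model

The estimator is the classical indicator-dilution chain for ICG:

1. **Standard series.** The 2.5 mg/mL aqueous stock is diluted to a premix
   series (5–30 mg/L) in 25 mL volumetric flasks; volumes follow exact mass
   balance (stock_µL = target × total / stock_conc) and are rounded to 1 µL
   for pipetting, with the balance checked before rounding. Each premix is
   then mixed 200 µL + 200 µL with the participant's pre-injection (blank)
   plasma, halving the concentration and matrix-matching the standards. The
   default curve uses the five final levels 2.5–10 mg/L; the six-level
   series up to 15 mg/L is available via `RunConfig(standard_series=...)`.
2. **Calibration.** Triplicate 805 nm reads are averaged per well group
   (CV% = 100·SD/mean with the n−1 denominator is reported for QC; a CV
   above the configurable 15% threshold warns but never rejects — there is
   no automatic outlier rule). The curve is an *unweighted* OLS line of
   absorbance on concentration; its Pearson r is the QC statistic. Because
   standards are prepared in the subject's own plasma, the plasma
   background sits in the intercept and no blank subtraction is performed;
   blank wells are read and reported only.
3. **Inversion and decay fit.** Sample concentrations are
   (A − intercept)/slope. Values above the 15 mg/L linear cap are excluded
   from the decay fit with a logged reason; negative inversions clamp to
   zero and are excluded (a log transform needs positive values). Remaining
   timed samples inside the fit window are regressed as ln C on draw time
   in **seconds** using natural logs (a base-10 fit would rescale k by
   ln 10; a unit test forbids it). At least 3 usable samples are required.
4. **Back-extrapolation and PV.** C₀ = exp(intercept) and
   C(60 s) = exp(intercept + 60·slope) give PV = D/C under both
   conventions, always reported side by side; they differ exactly by e^k.
   Dose D is gravimetric: (syringe pre − post mass)/density × 2.5 mg/mL.
   Derived kinetics: k = −60·slope (1/min), half-life ln2/k, PDR = 100·k
   %/min (the alternative 100·(1−e^(−k)) is not used), clearance k·PV.
   Per-participant half-lives are ln2/k; cohort half-life is their mean.

### Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| `stock_conc_mg_ml` | 2.5 | mg/mL | kit reconstitution (25 mg in 10 mL) |
| `target_dose_per_kg` | 0.25 | mg/kg | low end of the established dosing range; clears faster |
| `linear_cap_mg_l` | 15 | mg/L | Beer–Lambert linearity limit at 805 nm in plasma |
| `standard_series` | 2.5–10 | mg/L | five levels suffice to bracket observed samples |
| `fit_window_s` | (120, 300) | s | elimination phase; earlier draws are mixing-contaminated |
| `window_grace_s` | 15 | s | recorded draw times jitter around the nominal schedule; a draw logged at 118 s is still an elimination-phase draw |
| `density_g_ml` | 1.0 | g/mL | solution density for mass→volume; a ±1% error moves the dose ±1% |
| `bsa_formula` | dubois | — | standard in the PV literature; `mosteller` switchable |
| `cv_warn_pct` | 15 | % | triplicate QC warning only |

### Uncertainties

PV standard errors propagate the regression uncertainty of the
back-extrapolated ln-concentration (delta method: SE(PV)/PV =
SE(ln C at t)), using SE(intercept), SE(slope) and their analytic
covariance −t̄·SE(slope)². Dose uncertainty under gravimetric weighing is
negligible and not propagated.

## Cohort statistics

Means and SDs use the n−1 denominator. Associations of PV(t=0) with
height, weight, BMI and BSA use Spearman rank correlation (mid-ranked
ties). For n ≤ 9 the two-sided p-value is exact: all n! pairings are
enumerated (vectorised; 9! = 362,880) and p is the fraction with
|r| ≥ |r_obs|. Larger cohorts use the asymptotic t approximation. OLS
slopes (mL per predictor unit) carry normal-theory 95% CIs via
statsmodels. Degenerate inputs (constant PV or predictor) are flagged
rather than reported as numbers.

## Synthetic-study generator

The generator emulates the data-generating situation of the bench
protocol, not any particular cohort's individuals:

- **Anthropometrics** are truncated normals: weight 63.8 ± 7.4 kg on
  [45, 100], height 165 ± 7 cm on [145, 185], age 25 ± 4.5 y, body fat
  28.6 ± 5%. Elimination k ~ 0.25 ± 0.06 /min truncated to [0.10, 0.45].
- **True PV** couples to body size: PV = 1.18 L/m² × BSA + N(0, 0.08 L),
  clipped to [1, 3] L. This puts mean PV near 2.0 L at the reference
  anthropometrics and makes the PV–BSA rank correlation strong (~0.7–0.8),
  the association the cohort statistics are meant to detect.
- **Kinetics**: C(t) = (D/PV)·(1 − e^(−t/τ))·e^(−kt/60) with mixing time
  constant τ = 30 s; τ → 0 recovers the pure mono-exponential. A
  two-compartment variant (`k_peripheral_per_min > 0`) steepens the early
  curve for exploring the t=0 vs t=1 question.
- **Measurement layer**: absorbance = 0.06·conc + 0.05 AU plus additive
  Gaussian read noise (SD 0.005 AU), three reads per well; standards
  additionally carry a 2% pipetting CV on their realised concentration
  while the file records the nominal value. Draw times are jittered
  (SD 2 s) and the *jittered* time is recorded — matching a protocol that
  logs the exact second of each draw, so jitter adds no bias. At these
  defaults, calibration and decay correlation coefficients land at ≈0.99+,
  within the QC bands the bench protocol reports.
- **Seed contract**: every stochastic operation takes an explicit seed;
  per-subject seeds derive from the study seed via `SeedSequence.spawn`,
  and identical seeds produce byte-identical study directories.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: recirculation and true early-phase
distribution kinetics, hepatic saturation, capillary-leak states, plasma
matrix variability between subjects, plate position effects, or operator
error beyond Gaussian noise. In particular, under the saturating-mixing
form above the t=0 convention slightly *over*-estimates true PV (the
mixing factor depresses early concentrations below the back-extrapolated
line), whereas incomplete mixing in vivo is believed to make t=0
*under*-estimate PV. Which convention is closer to truth is a property of
the generative assumptions; the package reports both conventions and their
exact e^k link, and treats accuracy comparisons as simulation results, not
invariants.

## Numerical choices and degenerate inputs

- OLS lines via `scipy.stats.linregress`; tests pin them to the
  normal-equation closed form at 1e−10 relative.
- Calibration requires ≥3 points with ≥2 distinct concentrations (singular
  otherwise); decay fits require ≥3 positive concentrations at ≥2 distinct
  times. Non-negative decay slopes are flagged nonphysiologic (half-life
  reported as NaN) but do not raise.
- Inversion clamps negative concentrations to zero and flags them; the
  above-linear-range flag uses a 1e−9 relative tolerance at the cap.
- Volumes in dilution planning are rounded to 1 µL after exact planning.
- Problem sizes in the shipped checks (3-subject round trips, a 9-subject
  default cohort, 40–100-subject Monte-Carlo batches) keep the whole suite
  in a few seconds while giving the Monte-Carlo assertions comfortable
  margins.

## Known limitations

- v1 fits are unweighted with no robust-regression option; a single bad
  triplicate can tilt a curve (the CV warning surfaces it).
- The estimator is deliberately the log-linear mono-exponential method;
  richer compartmental models exist only inside the simulator.
- The 5 s injection duration is not subtracted from draw times (timer
  starts at the beginning of injection).
- Exact-permutation p-values are limited to n ≤ 9 by design; beyond that
  the asymptotic approximation is used silently.
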