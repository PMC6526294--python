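"""Cohort module: dose, PV, BSA normalisation, summaries and correlations."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from icgpv import (
    ICGDose,
    ParticipantRecord,
    build_pv_result,
    compute_dose,
    compute_pv,
    dubois_bsa,
    fit_decay,
    mosteller_bsa,
    planned_injection_volume_ml,
    spearman_exact,
    summarize_cohort,
)
from icgpv.cohort import body_surface_area
from icgpv.exceptions import InsufficientDataError


class TestDose:
    def test_gravimetric_dose(self):
        dose = ICGDose(syringe_weight_pre_g=10.5, syringe_weight_post_g=4.1)
        assert compute_dose(dose) == pytest.approx(16.0, rel=1e-12)

    def test_equal_weights_rejected(self):
        with pytest.raises(ValueError):
            ICGDose(syringe_weight_pre_g=4.1, syringe_weight_post_g=4.1)

    def test_planned_volume_formula(self):
        """0.25 mg/kg x 63.8 kg / 2.5 mg/mL = 6.38 mL to draw."""
        assert planned_injection_volume_ml(63.8) == pytest.approx(6.38, rel=1e-12)

    def test_density_scales_dose(self):
        base = ICGDose(10.5, 4.1, density_g_ml=1.0).dose_mg
        denser = ICGDose(10.5, 4.1, density_g_ml=1.01).dose_mg
        assert denser == pytest.approx(base / 1.01, rel=1e-12)


class TestBSA:
    def test_dubois_frozen_value(self):
        """Independent hand computation via exp/log of the power law."""
        assert dubois_bsa(70.0, 170.0) == pytest.approx(1.8097078017532484, rel=1e-12)

    def test_mosteller_frozen_value(self):
        assert mosteller_bsa(70.0, 170.0) == pytest.approx(1.818118685772619, rel=1e-12)

    @given(w=st.floats(40, 120), h=st.floats(140, 200))
    def test_weight_power_law(self, w, h):
        assert dubois_bsa(2 * w, h) == pytest.approx(
            dubois_bsa(w, h) * 2**0.425, rel=1e-12
        )

    def test_cohort_plausibility(self):
        """At the reference anthropometrics, PV/BSA ~ 941 mL/m^2 implies
        BSA ~ 1.7 m^2 — the Du Bois value lands in that range."""
        assert 1.6 < dubois_bsa(63.8, 165.0) < 1.8

    def test_unknown_formula_rejected(self):
        with pytest.raises(ValueError):
            body_surface_area(70, 170, "boyd")

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dubois_bsa(-70, 170)


class TestComputePV:
    def test_indicator_dilution(self):
        assert compute_pv(16.0, 8.0) == pytest.approx(2.0, rel=1e-12)

    def test_t1_convention_value(self):
        assert compute_pv(16.0, 6.230406264571239) == pytest.approx(
            2.568050833375483, rel=1e-12
        )

    @pytest.mark.parametrize("dose,c0", [(0.0, 8.0), (16.0, 0.0), (16.0, -1.0)])
    def test_invalid_inputs(self, dose, c0):
        with pytest.raises(ValueError):
            compute_pv(dose, c0)


class TestPVResult:
    @pytest.fixture
    def fit(self, exact_decay_samples):
        return fit_decay(exact_decay_samples)

    def test_convention_ratio_is_exp_k(self, fit):
        pv = build_pv_result(16.0, fit, weight_kg=63.8, height_cm=165.0)
        assert pv.pv_t1_ml / pv.pv_t0_ml == pytest.approx(
            math.exp(pv.k_per_min), rel=1e-12
        )
        assert pv.pv_t1_ml > pv.pv_t0_ml

    def test_unit_audit_ml_is_1000x_l(self, fit):
        pv = build_pv_result(16.0, fit)
        assert pv.pv_t0_ml == pytest.approx(1000.0 * compute_pv(16.0, fit.c0_t0), rel=1e-15)

    def test_normalisations_reconstruct_pv(self, fit):
        pv = build_pv_result(16.0, fit, weight_kg=63.8, height_cm=165.0)
        assert pv.pv_per_kg_ml * 63.8 == pytest.approx(pv.pv_t0_ml, rel=1e-9)
        assert pv.pv_per_bsa_ml_m2 * pv.bsa_m2 == pytest.approx(pv.pv_t0_ml, rel=1e-9)

    def test_clearance_links_k_and_pv(self, fit):
        pv = build_pv_result(16.0, fit)
        assert pv.clearance_t0_ml_min == pytest.approx(
            pv.k_per_min * pv.pv_t0_ml, rel=1e-12
        )


class TestParticipantRecord:
    def test_bmi_derived_when_absent(self):
        rec = ParticipantRecord(id="a", weight_kg=63.8, height_cm=165.0)
        assert rec.bmi == pytest.approx(63.8 / 1.65**2, rel=1e-9)

    def test_inconsistent_bmi_rejected(self):
        with pytest.raises(ValueError):
            ParticipantRecord(id="a", weight_kg=63.8, height_cm=165.0, bmi=30.0)


def _brute_spearman_r(x, y):
    """Oracle: mid-rank both vectors, then Pearson."""
    return float(np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1])


def _brute_exact_p(x, y):
    """Oracle: enumerate pairings with itertools, count |r| >= |r_obs|."""
    r_obs = _brute_spearman_r(x, y)
    ry = stats.rankdata(y)
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(_brute_spearman_r(x, perm)) >= abs(r_obs) - 1e-12:
            hits += 1
    return hits / total


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2, 3, 4, 5], [2.3, 1.1, 5.0, 4.4, 3.3]),
            ([1.5, 1.5, 3, 4, 9], [1, 2, 2, 4, 5]),  # ties on both sides
            ([5, 1, 4, 2, 3, 6], [10, 60, 20, 50, 30, 40]),
        ],
    )
    def test_matches_brute_force_oracle(self, x, y):
        r, p, method = spearman_exact(x, y)
        assert method == "exact-permutation"
        assert r == pytest.approx(_brute_spearman_r(x, y), rel=1e-10)
        assert p == pytest.approx(_brute_exact_p(x, y), abs=1e-12)

    def test_perfect_monotone_gives_r1(self):
        r, p, _ = spearman_exact([1, 2, 3, 4, 5], [10, 20, 25, 40, 100])
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(2 / math.factorial(5))

    def test_constant_input_degenerate(self):
        r, p, method = spearman_exact([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(r) and math.isnan(p) and method == "degenerate"

    def test_large_n_uses_asymptotic(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r, p, method = spearman_exact(x, y)
        assert method == "asymptotic"
        ref = stats.spearmanr(x, y)
        assert r == pytest.approx(float(ref.statistic), rel=1e-9)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-9)


def _cohort(pvs, weights=None, heights=None):
    pairs = []
    n = len(pvs)
    weights = weights or [55 + 3 * i for i in range(n)]
    heights = heights or [158 + 2 * i for i in range(n)]
    for i, (pv0, w, h) in enumerate(zip(pvs, weights, heights)):
        rec = ParticipantRecord(id=f"P{i}", weight_kg=w, height_cm=h, age_y=25.0)
        fitlike = fit_decay(
            [(t, (16.0 / pv0) * math.exp(-0.25 * t / 60.0)) for t in (120, 210, 300)]
        )
        pairs.append((rec, build_pv_result(16.0, fitlike, weight_kg=w, height_cm=h)))
    return pairs


class TestCohortSummary:
    def test_too_small_cohort(self):
        with pytest.raises(InsufficientDataError):
            summarize_cohort(_cohort([2.0, 2.1]))

    def test_constant_pv_flagged_degenerate(self):
        s = summarize_cohort(_cohort([2.0, 2.0, 2.0, 2.0]))
        assert s.sds["pv_t0_ml"] == pytest.approx(0.0)
        assert all(a.degenerate for a in s.associations.values())

    def test_monotone_pv_vs_bsa(self):
        """PV increasing with body size gives Spearman r = 1 against BSA."""
        s = summarize_cohort(_cohort([1.6, 1.8, 2.0, 2.2, 2.4]))
        assert s.associations["bsa_m2"].spearman_r == pytest.approx(1.0)

    def test_means_and_sds_use_sample_denominator(self):
        pvs = [1.5, 2.0, 2.5]
        s = summarize_cohort(_cohort(pvs))
        assert s.means["pv_t0_ml"] == pytest.approx(2000.0, rel=1e-9)
        assert s.sds["pv_t0_ml"] == pytest.approx(np.std(pvs, ddof=1) * 1000, rel=1e-9)

    def test_ols_slope_matches_normal_equations(self):
        pairs = _cohort([1.7, 2.3, 1.9, 2.6, 2.1])
        s = summarize_cohort(pairs)
        x = np.array([rec.weight_kg for rec, _ in pairs])
        y = np.array([pv.pv_t0_ml for _, pv in pairs])
        slope = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) @ (x - x.mean()))
        assert s.associations["weight_kg"].ols_slope == pytest.approx(slope, rel=1e-10)
        lo, hi = s.associations["weight_kg"].ols_ci95
        assert lo < slope < hi
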