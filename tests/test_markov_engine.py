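import math

import numpy as np
import pytest

from margcea.constants import CYCLE_DAYS, DAYS_PER_MONTH, DAYS_PER_YEAR
from margcea.economics import CostInputs, RegimenSpec, UtilitySet
from margcea.markov_engine import (ModelSpec, accrue, adjust_pfs_for_treatment,
                                   compute_trace, discount_factor,
                                   half_cycle_value, run_cohort,
                                   tot_over_pfs_ratio)
from margcea.params import build_cost_inputs, build_regimen, build_utilities
from margcea.survival_models import SurvivalFit
from margcea.synthetic_data import synthetic_life_table


def _exp_fit(rate):
    return SurvivalFit("exponential", {"rate": rate}, 0.0, 10, 10)


_ZERO_DISUTIL = {"neutrophil_count_decreased": 0.0, "anemia": 0.0,
                 "neutropenia": 0.0}


def _zero_costs():
    return CostInputs(country="US", drug_prices={
        "margetuximab": 0.0, "trastuzumab": 0.0, "capecitabine": 0.0,
        "eribulin": 0.0, "gemcitabine": 0.0, "vinorelbine": 0.0},
        supportive_care=0.0, routine_followup=0.0, end_of_life=0.0,
        ae_costs={"neutrophil_count_decreased": 0.0, "anemia": 0.0,
                  "neutropenia": 0.0},
        admin_first_hour=0.0, admin_addl_hour=0.0)


def _spec(fit_pfs, fit_os, utilities=None, costs=None, life=None, **kw):
    return ModelSpec(
        arm_label="margetuximab",
        fit_pfs=fit_pfs, fit_os=fit_os, life_table=life,
        utilities=utilities or UtilitySet(1.0, 1.0, _ZERO_DISUTIL),
        costs=costs or _zero_costs(),
        regimen=build_regimen("margetuximab"),
        **kw)


class TestDiscounting:
    def test_cycle_zero_undiscounted(self):
        assert discount_factor(0, 0.03) == 1.0

    def test_zero_rate_always_one(self):
        assert all(discount_factor(i, 0.0) == 1.0 for i in range(0, 300, 17))

    def test_three_percent_at_cycle_26(self):
        # 546 days elapsed
        assert discount_factor(26, 0.03) == pytest.approx(
            1.03 ** (-546 / 365), rel=1e-12)
        assert discount_factor(26, 0.03) == pytest.approx(0.9567, abs=5e-5)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, 1.5)


class TestHalfCycle:
    def test_trapezoid_endpoints(self):
        assert half_cycle_value(1.0, 0.0) == 0.5
        assert half_cycle_value(0.3, 0.3) == 0.3

    def test_life_years_match_analytic_integral(self):
        # exponential OS with hazard 0.1/cycle: E[T] = 1/lambda cycles
        rate_month = 0.1 / (CYCLE_DAYS / DAYS_PER_MONTH)
        fit = _exp_fit(rate_month)
        res = run_cohort(_spec(fit, fit, annual_discount=0.0))
        expected_years = (1 / 0.1) * CYCLE_DAYS / DAYS_PER_YEAR
        assert res.total_lys == pytest.approx(expected_years, rel=1e-3)


class TestTreatmentAdjustment:
    def test_margetuximab_ratio(self):
        # 6 cycles ToT over a 5.7-month median PFS
        assert tot_over_pfs_ratio(6.0, 5.7) == pytest.approx(
            6.0 / (5.7 * DAYS_PER_MONTH / CYCLE_DAYS), rel=1e-12)
        assert tot_over_pfs_ratio(6.0, 5.7) == pytest.approx(0.726, abs=1e-3)

    def test_trastuzumab_ratio(self):
        assert tot_over_pfs_ratio(5.0, 4.4) == pytest.approx(0.784, abs=5e-4)

    def test_ratio_above_one_clamped(self):
        assert tot_over_pfs_ratio(100.0, 4.4) == 1.0

    def test_unit_ratio_leaves_curve_unchanged(self):
        fit = _exp_fit(0.1)
        median_months = math.log(2) / 0.1
        median_cycles = median_months * DAYS_PER_MONTH / CYCLE_DAYS
        curve, ratio = adjust_pfs_for_treatment(fit, median_cycles)
        assert ratio == pytest.approx(1.0, rel=1e-9)
        t = np.linspace(0, 40, 50)
        np.testing.assert_allclose(curve(t), fit.sf(t), rtol=1e-9)


class TestCohort:
    def test_occupancy_conservation_and_monotone_death(self, round_trip):
        fits, _ = round_trip
        trace = compute_trace(fits["margetuximab"]["PFS"],
                              fits["margetuximab"]["OS"],
                              synthetic_life_table("US"))
        total = trace.pfs + trace.pd_state + trace.dead
        np.testing.assert_allclose(total, 1.0, atol=1e-9)
        assert np.all(np.diff(trace.dead) >= -1e-15)

    def test_alive_tracks_os_without_clamping(self):
        # PFS strictly below OS and hazards above background: alive == S_os
        fit_pfs = _exp_fit(0.25)
        fit_os = _exp_fit(0.08)
        trace = compute_trace(fit_pfs, fit_os, life_table=None)
        t_months = np.arange(trace.n_cycles + 1) * CYCLE_DAYS / DAYS_PER_MONTH
        np.testing.assert_allclose(trace.alive, fit_os.sf(t_months), atol=1e-6)

    def test_unit_utilities_make_qalys_equal_lys(self):
        fit = _exp_fit(0.15)
        res = run_cohort(_spec(fit, fit))
        assert res.total_qalys == pytest.approx(res.total_lys, rel=1e-12)

    def test_zero_utilities_leave_only_ae_disutility(self):
        fit = _exp_fit(0.15)
        utilities = UtilitySet(0.0, 0.0, {
            "neutrophil_count_decreased": 0.13, "neutropenia": 0.13})
        res = run_cohort(_spec(fit, fit, utilities=utilities))
        expected = -(0.09 * 0.13 + 0.20 * 0.13) * CYCLE_DAYS / DAYS_PER_YEAR
        assert res.total_qalys == pytest.approx(expected, rel=1e-9)

    def test_discounted_below_undiscounted(self, us_model):
        res = us_model.evaluate_arm("margetuximab")
        assert res.total_cost < res.undiscounted_cost
        assert res.total_qalys < res.undiscounted_qalys
        assert res.total_lys < res.undiscounted_lys

    def test_qalys_never_exceed_lys(self, us_model, cn_model):
        for model in (us_model, cn_model):
            for arm in ("margetuximab", "trastuzumab"):
                res = model.evaluate_arm(arm)
                assert res.total_qalys <= res.total_lys

    def test_higher_pfs_utility_increases_qalys(self, us_model):
        lo = us_model.evaluate_arm("margetuximab", {"utility.pfs": 0.65})
        hi = us_model.evaluate_arm("margetuximab", {"utility.pfs": 0.80})
        assert hi.total_qalys > lo.total_qalys

    @pytest.mark.parametrize("param", [
        "drug.margetuximab", "care.supportive", "ae_cost.neutropenia",
        "admin.first_hour"])
    def test_unit_costs_weakly_increase_total_cost(self, us_model, param):
        base = us_model.evaluate_arm("margetuximab")
        bumped = us_model.evaluate_arm(
            "margetuximab", {param: us_model.base_params()[param] * 1.5})
        assert bumped.total_cost >= base.total_cost

    def test_trace_csv_columns(self, us_model):
        res = us_model.evaluate_arm("margetuximab", keep_trace=True)
        assert list(res.trace.columns) == [
            "cycle", "t_months", "pfs", "pd", "dead", "on_treatment",
            "d_cost", "d_qaly", "d_ly"]
        assert np.all(res.trace["on_treatment"] <= res.trace["pfs"] + 1e-12)
        assert res.trace["d_cost"].sum() == pytest.approx(res.total_cost)

    def test_discounted_lys_match_numeric_integration(self, round_trip):
        """Trace-based discounted LYs vs 1-day trapezoid of S_os(t)·d(t)."""
        fits, _ = round_trip
        fit_pfs = fits["trastuzumab"]["PFS"]
        fit_os = fits["trastuzumab"]["OS"]
        # no life table so the trace follows S_os exactly
        trace = compute_trace(fit_pfs, fit_os, life_table=None)
        res = accrue(trace, _zero_costs(), UtilitySet(1.0, 1.0, _ZERO_DISUTIL),
                     build_regimen("trastuzumab"), annual_discount=0.03,
                     keep_trace=False)
        horizon_days = trace.n_cycles * CYCLE_DAYS
        days = np.arange(0.0, horizon_days + 1.0)
        integrand = fit_os.sf(days / DAYS_PER_MONTH) * 1.03 ** (-days / 365.0)
        direct = np.trapezoid(integrand, days) / DAYS_PER_YEAR
        assert res.total_lys == pytest.approx(direct, rel=2e-3)
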