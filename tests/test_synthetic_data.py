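import math
from dataclasses import replace

import numpy as np
import pytest
from lifelines import KaplanMeierFitter

from margcea.synthetic_data import (ArmCalibration, DigitizedCurve, IPDSample,
                                    LifeTable, RiskTable, calibrate_arms,
                                    cox_estimand_hr, generate_arm_ipd,
                                    km_estimate, make_risk_table,
                                    scale_for_median, synthetic_life_table)


class TestCalibration:
    def test_exponential_special_case_scale(self):
        # Weibull with shape 1 is exponential: median = scale * ln 2
        assert scale_for_median("weibull", 1.0, 6.931) == pytest.approx(10.0, abs=1e-3)

    def test_loglogistic_median_equals_scale(self):
        for shape in (0.8, 1.5, 2.6):
            assert scale_for_median("loglogistic", shape, 5.7) == 5.7

    @pytest.mark.parametrize("median,shape", [(-1, 1.0), (5.7, 0.0), (0.0, 2.0)])
    def test_invalid_parameters_rejected(self, median, shape):
        with pytest.raises(ValueError):
            scale_for_median("weibull", shape, median)

    def test_calibrations_hit_target_medians_exactly(self, calibrations):
        cals, _ = calibrations
        targets = {("margetuximab", "PFS"): 5.7, ("trastuzumab", "PFS"): 4.4,
                   ("margetuximab", "OS"): 21.6, ("trastuzumab", "OS"): 19.8}
        for key, med in targets.items():
            assert cals[key].median_months == pytest.approx(med, abs=1e-6)

    def test_implied_hazard_ratios(self, calibrations):
        _, implied = calibrations
        # Weibull OS: exact proportional hazards from the median ratio
        assert implied["OS"] == pytest.approx((19.8 / 21.6) ** 1.3, abs=1e-12)
        # log-logistic PFS: Cox-estimand average under 30-month follow-up,
        # calibrated to the trial's reported 0.71
        assert implied["PFS"] == pytest.approx(0.71, abs=0.01)

    def test_exponential_median_ratio_is_cox_estimand(self):
        # Shared Weibull shape 1 (= exponential): HR is exactly m2/m1 and the
        # Cox-estimand computation must agree with the closed form.
        m1, m2 = 10.0, 7.0
        hr = cox_estimand_hr(
            "weibull", (1.0, scale_for_median("weibull", 1.0, m1)),
            "weibull", (1.0, scale_for_median("weibull", 1.0, m2)),
            censor_months=60.0)
        assert hr == pytest.approx(m2 / m1, abs=0.002)


class TestGeneration:
    def test_no_censoring_when_followup_infinite(self, calibrations):
        cals, _ = calibrations
        cal = replace(cals[("margetuximab", "PFS")], n_patients=100,
                      max_followup_months=1e9)
        ipd = generate_arm_ipd(cal)
        assert len(ipd) == 100
        assert ipd.event.sum() == 100

    def test_same_seed_reproduces_identical_records(self, calibrations):
        cals, _ = calibrations
        cal = cals[("trastuzumab", "OS")]
        a, b = generate_arm_ipd(cal), generate_arm_ipd(cal)
        np.testing.assert_array_equal(a.time_months, b.time_months)
        np.testing.assert_array_equal(a.event, b.event)

    def test_empirical_median_near_calibration_target(self, calibrations):
        cals, _ = calibrations
        ipd = generate_arm_ipd(cals[("margetuximab", "PFS")])  # n = 20,000
        kmf = KaplanMeierFitter().fit(ipd.time_months, ipd.event)
        assert kmf.median_survival_time_ == pytest.approx(5.7, abs=0.15)

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ValueError):
            ArmCalibration("m", "PFS", "loglogistic", shape=-1.0, scale_months=5.7,
                           n_patients=10, max_followup_months=30, seed=1)
        with pytest.raises(ValueError):
            ArmCalibration("m", "PFS", "loglogistic", shape=1.5, scale_months=5.7,
                           n_patients=1, max_followup_months=30, seed=1)


class TestKaplanMeier:
    def test_single_event_among_ten(self):
        ipd = IPDSample(np.array([5.0] + [10.0] * 9), np.array([1] + [0] * 9))
        curve = km_estimate(ipd, np.array([0.0, 4.9, 5.0, 9.0]))
        assert curve.at(4.9) == pytest.approx(1.0)
        assert curve.at(5.0) == pytest.approx(0.9)
        assert curve.at(9.0) == pytest.approx(0.9)

    def test_all_censored_curve_is_flat_one(self):
        ipd = IPDSample(np.arange(1.0, 6.0), np.zeros(5, dtype=int))
        curve = km_estimate(ipd)
        assert np.all(curve.survival == 1.0)

    def test_five_distinct_events_product_limit(self):
        ipd = IPDSample(np.arange(1.0, 6.0), np.ones(5, dtype=int))
        curve = km_estimate(ipd, np.arange(0.0, 6.0))
        expected = [1.0, 0.8, 0.6, 0.4, 0.2, 0.0]
        np.testing.assert_allclose(curve.at(np.arange(0.0, 6.0)), expected)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            km_estimate(IPDSample(np.array([]), np.array([])))


class TestRiskTable:
    def test_no_exits_before_six_months(self):
        ipd = IPDSample(np.full(10, 7.0), np.ones(10, dtype=int))
        rt = make_risk_table(ipd, 6.0)
        assert rt.n_at_risk[0] == 10
        assert rt.n_at_risk[1] == 10

    def test_counts_match_brute_force_scan(self, small_pfs_ipd):
        rt = make_risk_table(small_pfs_ipd, 3.0)
        for start, n in zip(rt.interval_starts, rt.n_at_risk):
            brute = sum(1 for t in small_pfs_ipd.time_months if t >= start)
            assert n == brute

    def test_risk_table_validates_monotonicity(self):
        with pytest.raises(ValueError):
            RiskTable(np.array([0.0, 3.0]), np.array([5, 8]))


class TestLifeTable:
    def test_zero_hazard_gives_zero_probability(self):
        lt = synthetic_life_table("US", makeham_a=0.0, gompertz_b=0.0)
        assert np.all(lt.annual_death_prob == 0.0)

    def test_age_independent_hazard_closed_form(self):
        a, b = 0.001, 0.002
        lt = synthetic_life_table("US", makeham_a=a, gompertz_b=b, gompertz_c=0.0)
        expected = 1.0 - math.exp(-(a + b))
        np.testing.assert_allclose(lt.annual_death_prob, expected)

    def test_example_value_at_56(self):
        lt = synthetic_life_table("US", makeham_a=5e-4, gompertz_b=2e-5,
                                  gompertz_c=0.11)
        expected = 1.0 - math.exp(-(5e-4 + 2e-5 * math.exp(0.11 * 56)))
        assert lt.qx(56) == pytest.approx(expected, rel=1e-12)

    def test_probabilities_monotone_in_age(self):
        lt = synthetic_life_table("CN")
        assert np.all(np.diff(lt.annual_death_prob) >= 0)

    def test_explosive_parameters_rejected(self):
        with pytest.raises(ValueError):
            synthetic_life_table("US", makeham_a=0.5, gompertz_b=0.5, gompertz_c=0.2)

    def test_cycle_probability_conversion(self):
        lt = synthetic_life_table("US")
        q = lt.qx(60)
        assert lt.cycle_prob(60, 21.0) == pytest.approx(1 - (1 - q) ** (21 / 365))


class TestDigitizedCurveInvariants:
    def test_must_start_at_origin(self):
        with pytest.raises(ValueError):
            DigitizedCurve(np.array([1.0, 2.0]), np.array([0.9, 0.8]))

    def test_survival_must_not_increase(self):
        with pytest.raises(ValueError):
            DigitizedCurve(np.array([0.0, 1.0, 2.0]), np.array([1.0, 0.5, 0.7]))

    def test_km_risk_consistency_round_trip(self, small_pfs_ipd):
        # The curve emitted for an IPD equals KM recomputed on any subgrid.
        grid = np.arange(0.0, 30.0, 0.5)
        curve = km_estimate(small_pfs_ipd, grid)
        kmf = KaplanMeierFitter().fit(small_pfs_ipd.time_months, small_pfs_ipd.event)
        np.testing.assert_allclose(curve.at(grid), kmf.predict(grid).to_numpy(),
                                   atol=1e-12)
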