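import math
from dataclasses import replace

import numpy as np
import pytest
from lifelines import LogLogisticFitter, WeibullFitter

from margcea.survival_models import (FAMILY_ORDER, SurvivalFit, UndefinedMedianError,
                                     cycle_transitions, fit_all_families,
                                     fit_parametric, median_survival, select_best,
                                     survival_at)
from margcea.synthetic_data import (IPDSample, calibrate_arms, generate_arm_ipd,
                                    synthetic_life_table)


class TestFitting:
    def test_exponential_closed_form_mle(self):
        # 10 events totalling 100 months -> rate 0.1/month, median ln2/0.1
        ipd = IPDSample(np.full(10, 10.0), np.ones(10, dtype=int))
        fit = fit_parametric(ipd, "exponential")
        assert fit.params["rate"] == pytest.approx(0.1, rel=1e-12)
        assert median_survival(fit) == pytest.approx(math.log(2) / 0.1, rel=1e-12)

    def test_exponential_with_censoring(self):
        # events/Σt counts censored exposure in the denominator
        ipd = IPDSample(np.array([2.0, 4.0, 6.0, 8.0]), np.array([1, 0, 1, 0]))
        fit = fit_parametric(ipd, "exponential")
        assert fit.params["rate"] == pytest.approx(2 / 20.0, rel=1e-12)

    def test_loglogistic_parameter_recovery(self, calibrations):
        cals, _ = calibrations
        ipd = generate_arm_ipd(cals[("margetuximab", "PFS")])  # n = 20,000
        fit = fit_parametric(ipd, "loglogistic")
        assert fit.params["scale"] == pytest.approx(5.7, abs=0.15)

    def test_aic_bic_identities(self, small_pfs_ipd):
        for fit in fit_all_families(small_pfs_ipd):
            assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik, rel=1e-12)
            assert fit.bic == pytest.approx(
                fit.k * math.log(fit.n) - 2 * fit.loglik, rel=1e-12)
            assert fit.aic - fit.bic == pytest.approx(
                2 * fit.k - fit.k * math.log(fit.n), rel=1e-9)

    def test_all_censored_rejected(self):
        ipd = IPDSample(np.arange(1.0, 5.0), np.zeros(4, dtype=int))
        with pytest.raises(ValueError):
            fit_parametric(ipd, "weibull")

    @pytest.mark.parametrize("family", ["weibull", "loglogistic"])
    def test_agreement_with_lifelines(self, small_pfs_ipd, family):
        """Independent cross-check of the in-package MLE against lifelines."""
        ours = fit_parametric(small_pfs_ipd, family)
        ll = (WeibullFitter() if family == "weibull" else LogLogisticFitter()).fit(
            small_pfs_ipd.time_months, small_pfs_ipd.event)
        # lifelines: weibull (lambda_, rho_) = (scale, shape);
        # log-logistic (alpha_, beta_) = (scale, shape)
        theirs_scale = float(ll.lambda_ if family == "weibull" else ll.alpha_)
        theirs_shape = float(ll.rho_ if family == "weibull" else ll.beta_)
        assert ours.params["scale"] == pytest.approx(theirs_scale, rel=1e-3)
        assert ours.params["shape"] == pytest.approx(theirs_shape, rel=1e-3)
        assert ours.loglik == pytest.approx(float(ll.log_likelihood_), rel=1e-6)


class TestSelection:
    def test_single_fit_returned(self, small_pfs_ipd):
        fit = fit_parametric(small_pfs_ipd, "weibull")
        assert select_best([fit]) is fit

    def test_true_family_usually_wins(self):
        # Weibull(shape 1.8) data: AIC should pick weibull or gamma nearly always
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            t = rng.weibull(1.8, 5000) * 10.0
            ipd = IPDSample(t + 1e-9, np.ones(5000, dtype=int))
            best = select_best(fit_all_families(ipd), "AIC")
            wins += best.family in ("weibull", "gamma")
        assert wins >= 0.95 * n_rep

    def test_tie_broken_by_fewer_parameters(self):
        a = SurvivalFit("weibull", {"shape": 1.0, "scale": 2.0}, loglik=-9.0,
                        n=50, n_events=50)
        # exponential with one parameter and loglik chosen to equal weibull's AIC
        b = SurvivalFit("exponential", {"rate": 0.5}, loglik=-10.0, n=50, n_events=50)
        assert a.aic == b.aic
        assert select_best([a, b], "AIC").family == "exponential"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestEvaluation:
    def test_exponential_survival_at_median(self):
        fit = SurvivalFit("exponential", {"rate": 0.1}, 0.0, 10, 10)
        assert survival_at(fit, math.log(2) / 0.1) == pytest.approx(0.5, rel=1e-9)

    def test_loglogistic_survival_half_at_scale(self):
        for shape in (0.7, 1.5, 3.0):
            fit = SurvivalFit("loglogistic", {"shape": shape, "scale": 8.0},
                              0.0, 10, 10)
            assert survival_at(fit, 8.0) == pytest.approx(0.5, rel=1e-12)

    def test_weibull_direct_formula(self):
        fit = SurvivalFit("weibull", {"shape": 1.3, "scale": 24.6}, 0.0, 10, 10)
        assert survival_at(fit, 21.6) == pytest.approx(
            math.exp(-((21.6 / 24.6) ** 1.3)), rel=1e-12)

    def test_negative_time_rejected(self):
        fit = SurvivalFit("exponential", {"rate": 0.1}, 0.0, 10, 10)
        with pytest.raises(ValueError):
            survival_at(fit, -1.0)

    def test_bisection_median_matches_closed_form(self):
        # gamma has no closed form; cross-check against weibull's two routes
        wfit = SurvivalFit("weibull", {"shape": 1.7, "scale": 12.0}, 0.0, 10, 10)
        closed = median_survival(wfit)
        from scipy.optimize import brentq
        numeric = brentq(lambda t: wfit.sf(t) - 0.5, 1e-9, 1000.0, xtol=1e-8)
        assert closed == pytest.approx(numeric, abs=1e-6)

    def test_undefined_median_raises(self):
        fit = SurvivalFit("exponential", {"rate": 1e-6}, 0.0, 10, 10)
        with pytest.raises(UndefinedMedianError):
            median_survival(fit)


class TestCycleTransitions:
    def _exp_fit(self, rate_per_month):
        return SurvivalFit("exponential", {"rate": rate_per_month}, 0.0, 10, 10)

    def test_constant_hazard_closed_form(self):
        # Both curves exponential with hazard 0.05 per cycle, no background
        rate = 0.05 / (21.0 / 30.4375)  # per month so that 0.05 per 21-day cycle
        fit = self._exp_fit(rate)
        tv = cycle_transitions(fit, fit, life=None, cycle_index=3)
        q = 1 - math.exp(-0.05)
        assert tv.p_pfs_to_death == pytest.approx(q, rel=1e-9)
        assert tv.p_pfs_to_pd == pytest.approx(0.0, abs=1e-12)
        assert tv.p_pd_to_death == pytest.approx(q, rel=1e-9)

    def test_identical_curves_no_progression(self):
        fit = self._exp_fit(0.1)
        for i in range(0, 40, 7):
            tv = cycle_transitions(fit, fit, life=None, cycle_index=i)
            assert tv.p_pfs_to_pd == pytest.approx(0.0, abs=1e-12)

    def test_rows_normalised_and_death_absorbing(self, round_trip):
        fits, _ = round_trip
        life = synthetic_life_table("US")
        for i in (0, 10, 50, 200):
            tv = cycle_transitions(fits["margetuximab"]["PFS"],
                                   fits["margetuximab"]["OS"], life,
                                   cycle_index=i)
            assert tv.p_pfs_stay + tv.p_pfs_to_pd + tv.p_pfs_to_death == pytest.approx(1.0)
            assert tv.p_pd_stay + tv.p_pd_to_death == pytest.approx(1.0)

    def test_mortality_floor_applies(self):
        # OS model with essentially no hazard: death still at background rate
        fit_flat = self._exp_fit(1e-9)
        life = synthetic_life_table("US")
        tv = cycle_transitions(fit_flat, fit_flat, life, start_age=80.0,
                               cycle_index=0)
        floor = life.cycle_prob(80.0, 21.0)
        assert tv.p_pfs_to_death == pytest.approx(floor, rel=1e-9)
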