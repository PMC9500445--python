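"""Parametric survival fitting, model selection, and cycle transitions.

Fits the six candidate families (exponential, Weibull, log-normal, gamma,
log-logistic, Gompertz) to right-censored pseudo-IPD by maximum
likelihood, ranks them by AIC or BIC, and converts a fitted PFS/OS pair
plus background life-table mortality into per-cycle transition
probabilities for the three-state (PFS / progressed disease / death)
cohort model.

The transition construction is a partitioned-survival decomposition: PFS
occupancy follows the fitted S_pfs, the overall alive fraction follows
S_os, and the split of deaths between the PFS and PD states is solved so
that both marginals hold. Per-cycle death probability is floored at the
life-table background probability for the cohort's current age.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .constants import CYCLE_DAYS, DAYS_PER_MONTH, START_AGE
from .distributions import FAMILIES, Family, get_family
from .synthetic_data import IPDSample, LifeTable

__all__ = [
    "SurvivalFit",
    "TransitionVector",
    "FitFailureError",
    "fit_parametric",
    "fit_all_families",
    "select_best",
    "survival_at",
    "median_survival",
    "cycle_transitions",
    "FAMILY_ORDER",
]

logger = logging.getLogger(__name__)

#: Fixed family order used for deterministic tie-breaking in selection.
FAMILY_ORDER = ("exponential", "weibull", "lognormal", "gamma", "loglogistic", "gompertz")

_MEDIAN_SEARCH_MAX_MONTHS = 1000.0


class FitFailureError(RuntimeError):
    """Maximum-likelihood optimisation failed to converge for a family."""

    def __init__(self, family: str, message: str = ""):
        self.family = family
        super().__init__(f"fit failed for family {family!r}: {message}")


class UndefinedMedianError(ValueError):
    """Fitted survival never reaches 0.5 within the search horizon."""


@dataclass(frozen=True)
class SurvivalFit:
    """A maximum-likelihood fit of one parametric family to (pseudo-)IPD."""

    family: str
    params: dict[str, float]
    loglik: float
    n: int
    n_events: int

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n) - 2 * self.loglik

    @property
    def _family(self) -> Family:
        return get_family(self.family)

    @property
    def _values(self) -> tuple[float, ...]:
        return tuple(self.params[name] for name in self._family.param_names)

    def sf(self, t_months) -> np.ndarray:
        """Fitted survival function S(t), t in months."""
        return self._family.sf(t_months, self._values)

    def to_dict(self) -> dict:
        return {
            "family": self.family, "params": dict(self.params),
            "loglik": self.loglik, "aic": self.aic, "bic": self.bic,
            "n": self.n, "n_events": self.n_events,
            "median_months": median_survival(self),
        }


def _neg_loglik(theta: np.ndarray, fam: Family, t_event, t_cens) -> float:
    params = tuple(
        math.exp(v) if is_log else v
        for v, is_log in zip(theta, fam.log_scale)
    )
    try:
        ll = fam.logpdf(t_event, params).sum()
        if t_cens.size:
            ll += fam.logsf(t_cens, params).sum()
    except (ValueError, FloatingPointError):
        return 1e12
    if not np.isfinite(ll):
        return 1e12
    return -float(ll)


def _initial_guess(fam: Family, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Moment-style starting values on the optimiser's (log) scale."""
    t_ev = time[event == 1]
    m = float(np.mean(t_ev)) if t_ev.size else float(np.mean(time))
    m = max(m, 1e-6)
    s = float(np.std(np.log(np.maximum(time, 1e-12))))
    s = max(s, 0.2)
    guesses = {
        "exponential": (1.0 / m,),
        "weibull": (1.2, m),
        "lognormal": (math.log(m), s),
        "gamma": (1.5, 1.5 / m),
        "loglogistic": (1.5, m),
        "gompertz": (1.0 / m, 0.01),
    }[fam.name]
    return np.array([
        math.log(g) if is_log else g
        for g, is_log in zip(guesses, fam.log_scale)
    ])


def fit_parametric(ipd: IPDSample, family: str) -> SurvivalFit:
    """Maximum-likelihood fit of ``family`` with right-censoring.

    The exponential rate has the closed form (#events) / (Σ time); the
    remaining families are optimised numerically (Nelder-Mead polished by
    BFGS) on a log scale for positive parameters.
    """
    fam = get_family(family)
    time = ipd.time_months
    event = ipd.event
    if len(ipd) == 0 or ipd.n_events == 0:
        raise ValueError("fitting requires at least one event record")

    t_event = time[event == 1]
    t_cens = time[event == 0]

    if family == "exponential":
        rate = ipd.n_events / float(time.sum())
        params = {"rate": rate}
        ll = -_neg_loglik(np.array([math.log(rate)]), fam, t_event, t_cens)
        return SurvivalFit(family, params, ll, len(ipd), ipd.n_events)

    x0 = _initial_guess(fam, time, event)
    res = optimize.minimize(
        _neg_loglik, x0, args=(fam, t_event, t_cens), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000})
    res2 = optimize.minimize(
        _neg_loglik, res.x, args=(fam, t_event, t_cens), method="BFGS")
    best = res2 if res2.fun <= res.fun else res
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        raise FitFailureError(family, "likelihood not finite at optimum")
    values = tuple(
        math.exp(v) if is_log else v
        for v, is_log in zip(best.x, fam.log_scale)
    )
    params = dict(zip(fam.param_names, values))
    return SurvivalFit(family, params, -float(best.fun), len(ipd), ipd.n_events)


def fit_all_families(ipd: IPDSample, families=FAMILY_ORDER) -> list[SurvivalFit]:
    """Fit every requested family, skipping (and logging) failures."""
    fits = []
    for family in families:
        try:
            fits.append(fit_parametric(ipd, family))
        except FitFailureError as exc:
            logger.warning("skipping family: %s", exc)
    if not fits:
        raise FitFailureError("all", "no family converged")
    return fits


def select_best(fits: list[SurvivalFit], criterion: str = "AIC") -> SurvivalFit:
    """Minimum-criterion fit; ties go to fewer parameters, then family order."""
    if not fits:
        raise ValueError("select_best requires a non-empty list of fits")
    crit = criterion.upper()
    if crit not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    return min(fits, key=lambda f: (
        getattr(f, crit.lower()), f.k, FAMILY_ORDER.index(f.family)))


def survival_at(fit: SurvivalFit, t_months) -> np.ndarray | float:
    """S(t) of the fitted model; scalar in, scalar out."""
    t = np.asarray(t_months, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = fit.sf(t)
    return float(out) if np.isscalar(t_months) or t.ndim == 0 else out


def median_survival(fit: SurvivalFit) -> float:
    """Smallest t with S(t) ≤ 1/2 — closed form where available, else bisection."""
    closed = fit._family.median(fit._values)
    if closed is not None:
        if not (0 < closed <= _MEDIAN_SEARCH_MAX_MONTHS):
            raise UndefinedMedianError(
                f"median {closed} outside (0, {_MEDIAN_SEARCH_MAX_MONTHS}] months")
        return float(closed)
    if fit.sf(_MEDIAN_SEARCH_MAX_MONTHS) > 0.5:
        raise UndefinedMedianError(
            f"S(t) stays above 0.5 within {_MEDIAN_SEARCH_MAX_MONTHS} months")
    return float(optimize.brentq(
        lambda t: fit.sf(t) - 0.5, 1e-9, _MEDIAN_SEARCH_MAX_MONTHS, xtol=1e-6))


@dataclass(frozen=True)
class TransitionVector:
    """Per-cycle transition probabilities out of PFS and PD (death absorbs)."""

    cycle_index: int
    p_pfs_stay: float
    p_pfs_to_pd: float
    p_pfs_to_death: float
    p_pd_stay: float
    p_pd_to_death: float

    def __post_init__(self):
        probs = (self.p_pfs_stay, self.p_pfs_to_pd, self.p_pfs_to_death,
                 self.p_pd_stay, self.p_pd_to_death)
        if any(p < -1e-12 or p > 1 + 1e-12 for p in probs):
            raise ValueError(f"transition probabilities outside [0, 1]: {probs}")
        if abs(self.p_pfs_stay + self.p_pfs_to_pd + self.p_pfs_to_death - 1) > 1e-9:
            raise ValueError("PFS row must sum to 1")
        if abs(self.p_pd_stay + self.p_pd_to_death - 1) > 1e-9:
            raise ValueError("PD row must sum to 1")


def _clamped_sf(fit_pfs: SurvivalFit, fit_os: SurvivalFit, t: float) -> tuple[float, float]:
    """(S_pfs, S_os) at t months with the curve-crossing guard S_pfs ≤ S_os."""
    s_os = float(fit_os.sf(t))
    s_pfs = float(fit_pfs.sf(t))
    return min(s_pfs, s_os), s_os


def cycle_transitions(
    fit_pfs: SurvivalFit,
    fit_os: SurvivalFit,
    life: LifeTable | None,
    start_age: float = START_AGE,
    cycle_index: int = 0,
    cycle_days: float = CYCLE_DAYS,
    pfs_occupancy: float | None = None,
    pd_occupancy: float | None = None,
) -> TransitionVector:
    """Transition probabilities for one cycle of the three-state model.

    The overall per-cycle death probability is the OS-implied conditional
    probability 1 − S_os(t+Δ)/S_os(t), floored at the life-table background
    probability for the cohort's attained age. PFS exit comes from S_pfs the
    same way; PFS→death is capped at the smaller of the two so no row leaves
    [0, 1], and the PD→death probability absorbs the remaining deaths so the
    alive fraction tracks S_os. If occupancies are not supplied they default
    to their partitioned-survival values (PFS = S_pfs, PD = S_os − S_pfs).
    """
    t0 = cycle_index * cycle_days / DAYS_PER_MONTH
    t1 = (cycle_index + 1) * cycle_days / DAYS_PER_MONTH
    s_pfs_0, s_os_0 = _clamped_sf(fit_pfs, fit_os, t0)
    s_pfs_1, s_os_1 = _clamped_sf(fit_pfs, fit_os, t1)

    if s_os_0 <= 0:
        return TransitionVector(cycle_index, 0.0, 0.0, 1.0, 0.0, 1.0)

    q_bg = 0.0
    if life is not None:
        age = start_age + cycle_index * cycle_days / 365.0
        q_bg = life.cycle_prob(age, cycle_days)

    q_os = min(max(1.0 - s_os_1 / s_os_0, q_bg, 0.0), 1.0)
    # PFS members cannot die at less than the background rate either, so the
    # floor applies to PFS exit as well (the excess exits are deaths).
    e_pfs = 1.0 - (s_pfs_1 / s_pfs_0 if s_pfs_0 > 0 else 1.0)
    e_pfs = min(max(e_pfs, q_bg, 0.0), 1.0)

    p_pfs_death = min(q_os, e_pfs)
    p_pfs_pd = e_pfs - p_pfs_death

    pfs_occ = s_pfs_0 if pfs_occupancy is None else pfs_occupancy
    pd_occ = (s_os_0 - s_pfs_0) if pd_occupancy is None else pd_occupancy
    alive = pfs_occ + pd_occ
    if pd_occ > 1e-15:
        p_pd_death = (alive * q_os - pfs_occ * p_pfs_death) / pd_occ
        p_pd_death = min(max(p_pd_death, 0.0), 1.0)
    else:
        p_pd_death = q_os

    return TransitionVector(
        cycle_index,
        p_pfs_stay=1.0 - e_pfs,
        p_pfs_to_pd=p_pfs_pd,
        p_pfs_to_death=p_pfs_death,
        p_pd_stay=1.0 - p_pd_death,
        p_pd_to_death=p_pd_death,
    )
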