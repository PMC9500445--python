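"""Three-state Markov cohort engine on 21-day cycles.

The cohort starts fully in PFS and moves through {PFS, PD, death} under
time-dependent transition probabilities derived from the fitted survival
models with a life-table mortality floor. Rewards use a half-cycle
(trapezoid) correction on state occupancies; one-time entry quantities —
the loading-dose cost difference and the expected adverse-event cost and
disutility — are applied in full at cycle 0. Costs and outcomes are
discounted at an annual rate compounded by cycle time.

Drug acquisition and administration accrue on the on-treatment fraction,
which is the PFS occupancy scaled down by the ratio of median time on
treatment to median PFS (patients progress later than they stop therapy).

The occupancy trace depends only on the survival fits and the life table,
so it is computed once and reused when only prices, utilities or risks
change (as in sensitivity analysis); ``accrue`` maps a trace plus economic
inputs to totals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (ANNUAL_DISCOUNT, CYCLE_DAYS, DAYS_PER_MONTH,
                        DAYS_PER_YEAR, START_AGE)
from .economics import (CostInputs, RegimenSpec, UtilitySet, admin_cost_per_cycle,
                        drug_cost_per_cycle, expected_ae_cost,
                        expected_ae_disutility_qaly)
from .survival_models import SurvivalFit, cycle_transitions, median_survival
from .synthetic_data import LifeTable

__all__ = [
    "ModelSpec",
    "CohortTrace",
    "ArmResult",
    "discount_factor",
    "half_cycle_value",
    "adjust_pfs_for_treatment",
    "compute_trace",
    "accrue",
    "run_cohort",
    "tot_over_pfs_ratio",
]

logger = logging.getLogger(__name__)

#: Stop once this fraction of the cohort has died ...
DEATH_STOP = 0.999
#: ... or at this horizon, whichever comes first.
MAX_HORIZON_YEARS = 20.0

#: Assumed duration (years) of a grade ≥3 AE for the disutility decrement.
AE_DURATION_YEARS = CYCLE_DAYS / DAYS_PER_YEAR


def discount_factor(cycle_index: int, annual_discount: float,
                    cycle_days: float = CYCLE_DAYS) -> float:
    """(1 + r)^(−t/365) with t the days elapsed at the cycle start."""
    if not 0 <= annual_discount < 1:
        raise ValueError("annual discount rate must lie in [0, 1)")
    return (1.0 + annual_discount) ** (-cycle_index * cycle_days / DAYS_PER_YEAR)


def half_cycle_value(v_start: float, v_end: float) -> float:
    """Trapezoid (half-cycle corrected) accrual over one cycle."""
    return 0.5 * (v_start + v_end)


def tot_over_pfs_ratio(median_tot_cycles: float, median_pfs_months: float,
                       cycle_days: float = CYCLE_DAYS) -> float:
    """Ratio of median time on treatment to median PFS, clamped to (0, 1]."""
    if median_tot_cycles <= 0 or median_pfs_months <= 0:
        raise ValueError("medians must be positive")
    median_pfs_cycles = median_pfs_months * DAYS_PER_MONTH / cycle_days
    ratio = median_tot_cycles / median_pfs_cycles
    if ratio > 1.0:
        logger.warning("time-on-treatment ratio %.3f > 1; clamped to 1", ratio)
        ratio = 1.0
    return ratio


def adjust_pfs_for_treatment(fit_pfs: SurvivalFit, median_tot_cycles: float,
                             median_pfs_months: float | None = None):
    """On-treatment curve: ratio × S_pfs(t), the downward-adjusted PFS curve.

    Drug acquisition and administration accrue on this curve while state
    membership still follows S_pfs. Returns (curve callable, ratio).
    """
    if median_pfs_months is None:
        median_pfs_months = median_survival(fit_pfs)
    ratio = tot_over_pfs_ratio(median_tot_cycles, median_pfs_months)
    return (lambda t_months: ratio * fit_pfs.sf(t_months)), ratio


@dataclass
class ModelSpec:
    """Everything needed to run one arm of the cohort model."""

    arm_label: str
    fit_pfs: SurvivalFit
    fit_os: SurvivalFit
    life_table: LifeTable | None
    utilities: UtilitySet
    costs: CostInputs
    regimen: RegimenSpec
    start_age: float = START_AGE
    cycle_days: float = CYCLE_DAYS
    annual_discount: float = ANNUAL_DISCOUNT
    tot_ratio: float | None = None  # None: derive from regimen median ToT

    def __post_init__(self):
        if not 0 <= self.annual_discount < 1:
            raise ValueError("annual discount rate must lie in [0, 1)")
        if self.cycle_days <= 0:
            raise ValueError("cycle length must be positive")
        if self.tot_ratio is not None and not 0 < self.tot_ratio <= 1:
            raise ValueError("tot_ratio must lie in (0, 1]")

    def resolve_tot_ratio(self) -> float:
        if self.tot_ratio is not None:
            return self.tot_ratio
        if self.regimen.median_tot_cycles <= 0:
            return 1.0
        return tot_over_pfs_ratio(
            self.regimen.median_tot_cycles, median_survival(self.fit_pfs),
            self.cycle_days)


@dataclass
class CohortTrace:
    """State occupancies at cycle boundaries (length n_cycles + 1)."""

    pfs: np.ndarray
    pd_state: np.ndarray
    dead: np.ndarray
    cycle_days: float
    start_age: float
    n_clamped_cycles: int = 0

    @property
    def n_cycles(self) -> int:
        return len(self.pfs) - 1

    @property
    def alive(self) -> np.ndarray:
        return self.pfs + self.pd_state


def compute_trace(
    fit_pfs: SurvivalFit,
    fit_os: SurvivalFit,
    life_table: LifeTable | None,
    start_age: float = START_AGE,
    cycle_days: float = CYCLE_DAYS,
) -> CohortTrace:
    """Advance occupancy from (1, 0, 0) until >99.9% dead or 20 years."""
    max_cycles = int(math.ceil(MAX_HORIZON_YEARS * DAYS_PER_YEAR / cycle_days))
    pfs = [1.0]
    pd_occ = [0.0]
    dead = [0.0]
    n_clamped = 0
    for i in range(max_cycles):
        t0 = i * cycle_days / DAYS_PER_MONTH
        if float(fit_pfs.sf(t0)) > float(fit_os.sf(t0)) + 1e-12:
            n_clamped += 1
        tv = cycle_transitions(
            fit_pfs, fit_os, life_table, start_age, i, cycle_days,
            pfs_occupancy=pfs[-1], pd_occupancy=pd_occ[-1])
        new_pfs = pfs[-1] * tv.p_pfs_stay
        new_pd = pfs[-1] * tv.p_pfs_to_pd + pd_occ[-1] * tv.p_pd_stay
        new_dead = dead[-1] + pfs[-1] * tv.p_pfs_to_death + pd_occ[-1] * tv.p_pd_to_death
        pfs.append(new_pfs)
        pd_occ.append(new_pd)
        dead.append(new_dead)
        if new_dead > DEATH_STOP:
            break
    if n_clamped:
        logger.info("PFS curve clamped to OS at %d cycle starts", n_clamped)
    return CohortTrace(np.array(pfs), np.array(pd_occ), np.array(dead),
                       cycle_days, start_age, n_clamped)


@dataclass
class ArmResult:
    """Discounted and undiscounted totals for one arm, plus the cycle trace."""

    arm_label: str
    total_cost: float
    total_lys: float
    total_qalys: float
    undiscounted_cost: float
    undiscounted_lys: float
    undiscounted_qalys: float
    trace: pd.DataFrame | None = None

    def __post_init__(self):
        if self.total_qalys > self.total_lys + 1e-9:
            raise ValueError("QALYs cannot exceed LYs")

    def to_dict(self) -> dict:
        return {
            "arm": self.arm_label,
            "total_cost": self.total_cost,
            "total_lys": self.total_lys,
            "total_qalys": self.total_qalys,
            "undiscounted_cost": self.undiscounted_cost,
            "undiscounted_lys": self.undiscounted_lys,
            "undiscounted_qalys": self.undiscounted_qalys,
        }


def accrue(
    trace: CohortTrace,
    costs: CostInputs,
    utilities: UtilitySet,
    regimen: RegimenSpec,
    annual_discount: float = ANNUAL_DISCOUNT,
    tot_ratio: float = 1.0,
    arm_label: str = "",
    keep_trace: bool = True,
) -> ArmResult:
    """Map an occupancy trace plus economic inputs to cost/QALY/LY totals.

    Vectorised over cycles so sensitivity analyses can re-accrue a cached
    trace cheaply. Recurring drug/administration costs accrue on the
    half-cycle-corrected on-treatment fraction; the cycle-0 loading-dose
    difference and expected AE cost/disutility are one-time and not halved.
    """
    c = trace.n_cycles
    cy = trace.cycle_days / DAYS_PER_YEAR
    i = np.arange(c)
    df = (1.0 + annual_discount) ** (-i * trace.cycle_days / DAYS_PER_YEAR)

    trap_pfs = 0.5 * (trace.pfs[:-1] + trace.pfs[1:])
    trap_pd = 0.5 * (trace.pd_state[:-1] + trace.pd_state[1:])
    trap_alive = trap_pfs + trap_pd
    new_deaths = np.diff(trace.dead)
    on_treat = tot_ratio * trace.pfs
    trap_on_treat = 0.5 * (on_treat[:-1] + on_treat[1:])

    ly_inc = trap_alive * cy
    qaly_inc = (trap_pfs * utilities.u_pfs + trap_pd * utilities.u_pd) * cy

    recurring = (drug_cost_per_cycle(regimen, costs, 1)
                 + admin_cost_per_cycle(regimen, costs, 1))
    first = (drug_cost_per_cycle(regimen, costs, 0)
             + admin_cost_per_cycle(regimen, costs, 0))
    loading_delta = first - recurring

    cost_inc = recurring * trap_on_treat
    cost_inc = cost_inc + costs.supportive_care * trap_pd
    cost_inc = cost_inc + costs.routine_followup * trap_pfs
    cost_inc = cost_inc + costs.end_of_life * new_deaths

    # One-time entry quantities at cycle 0 (not half-cycle corrected).
    ae_cost = expected_ae_cost(regimen.ae_risks, costs.ae_costs)
    ae_qaly = expected_ae_disutility_qaly(
        regimen.ae_risks, utilities.ae_disutilities, AE_DURATION_YEARS)
    cost_inc0 = cost_inc.copy()
    cost_inc0[0] += ae_cost + loading_delta * on_treat[0]
    qaly_inc0 = qaly_inc.copy()
    qaly_inc0[0] -= ae_qaly

    result = ArmResult(
        arm_label=arm_label,
        total_cost=float(cost_inc0 @ df),
        total_lys=float(ly_inc @ df),
        total_qalys=float(qaly_inc0 @ df),
        undiscounted_cost=float(cost_inc0.sum()),
        undiscounted_lys=float(ly_inc.sum()),
        undiscounted_qalys=float(qaly_inc0.sum()),
    )
    if keep_trace:
        result.trace = pd.DataFrame({
            "cycle": i,
            "t_months": i * trace.cycle_days / DAYS_PER_MONTH,
            "pfs": trace.pfs[:-1],
            "pd": trace.pd_state[:-1],
            "dead": trace.dead[:-1],
            "on_treatment": on_treat[:-1],
            "d_cost": cost_inc0 * df,
            "d_qaly": qaly_inc0 * df,
            "d_ly": ly_inc * df,
        })
    return result


def run_cohort(spec: ModelSpec, keep_trace: bool = True) -> ArmResult:
    """Full single-arm run: trace computation plus economic accrual."""
    trace = compute_trace(spec.fit_pfs, spec.fit_os, spec.life_table,
                          spec.start_age, spec.cycle_days)
    return accrue(trace, spec.costs, spec.utilities, spec.regimen,
                  spec.annual_discount, spec.resolve_tot_ratio(),
                  arm_label=spec.arm_label, keep_trace=keep_trace)
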