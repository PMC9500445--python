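"""Costing rules and pairwise cost-effectiveness statistics.

Implements the per-cycle drug-acquisition and administration costing for
the two regimens (margetuximab 15 mg/kg every 3 weeks, trastuzumab
6 mg/kg after an 8 mg/kg loading dose, each on a four-drug chemotherapy
backbone mixed by trial usage shares), the risk-weighted expected cost
and disutility of grade ≥3 adverse events, and the incremental
cost-effectiveness statistics (ΔC, ΔQALY, ICER, NMB, dominance).

All monetary values are 2021 USD; Chinese inputs are entered already
converted at the fixed 6.45 CNY/USD rate, so currency never appears in
runtime arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

if TYPE_CHECKING:
    from .markov_engine import ArmResult

__all__ = [
    "CostInputs",
    "UtilitySet",
    "ChemoDosing",
    "RegimenSpec",
    "CEResult",
    "drug_cost_per_cycle",
    "admin_cost_per_cycle",
    "expected_ae_cost",
    "expected_ae_disutility_qaly",
    "icer",
    "nmb",
]


@dataclass
class CostInputs:
    """Country-specific unit costs (2021 USD).

    Exactly one administration schema applies: per-infusion first/additional
    hour rates (US) or a flat per-administration fee (CN).
    """

    country: str
    drug_prices: dict[str, float]  # $ per mg
    supportive_care: float  # per cycle, PD state
    routine_followup: float  # per cycle, PFS state
    end_of_life: float  # once per death
    ae_costs: dict[str, float]
    admin_first_hour: float | None = None
    admin_addl_hour: float | None = None
    admin_flat: float | None = None

    def __post_init__(self):
        hourly = self.admin_first_hour is not None and self.admin_addl_hour is not None
        flat = self.admin_flat is not None
        if hourly == flat:
            raise ValueError(
                "exactly one administration schema required: "
                "(admin_first_hour, admin_addl_hour) or admin_flat")
        values = [*self.drug_prices.values(), self.supportive_care,
                  self.routine_followup, self.end_of_life, *self.ae_costs.values()]
        values += [v for v in (self.admin_first_hour, self.admin_addl_hour,
                               self.admin_flat) if v is not None]
        if any(v < 0 for v in values):
            raise ValueError("all unit costs must be non-negative")


@dataclass
class UtilitySet:
    """Health-state utilities and one-time AE disutilities."""

    u_pfs: float
    u_pd: float
    ae_disutilities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.u_pd <= self.u_pfs <= 1):
            raise ValueError("require 0 ≤ u_pd ≤ u_pfs ≤ 1")
        if any(not 0 <= d <= 1 for d in self.ae_disutilities.values()):
            raise ValueError("AE disutilities must lie in [0, 1]")


@dataclass(frozen=True)
class ChemoDosing:
    """Per-drug dosing rule: dose per m² per administration, administrations
    per 21-day cycle, route (oral drugs incur no infusion cost)."""

    dose_mg_per_m2: float
    administrations_per_cycle: float
    oral: bool = False
    infusion_hours: float = 0.5


#: Trial-protocol chemotherapy dosing (21-day cycles).
DEFAULT_CHEMO_DOSING: dict[str, ChemoDosing] = {
    # 1000 mg/m² twice daily, days 1-14, oral
    "capecitabine": ChemoDosing(1000.0, 28.0, oral=True, infusion_hours=0.0),
    "eribulin": ChemoDosing(1.4, 2.0),
    "gemcitabine": ChemoDosing(1000.0, 2.0),
    "vinorelbine": ChemoDosing(25.0, 2.0),
}

#: Relative use of the four chemotherapy partners in the trial.
DEFAULT_CHEMO_MIX: dict[str, float] = {
    "vinorelbine": 0.356,
    "capecitabine": 0.267,
    "eribulin": 0.254,
    "gemcitabine": 0.123,
}


@dataclass
class RegimenSpec:
    """One arm's treatment regimen and safety profile."""

    antibody: str  # "margetuximab" or "trastuzumab"
    dose_mg_per_kg: float
    loading_dose_mg_per_kg: float | None  # first-cycle dose, if different
    chemo_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CHEMO_MIX))
    chemo_dosing: dict[str, ChemoDosing] = field(
        default_factory=lambda: dict(DEFAULT_CHEMO_DOSING))
    body_weight_kg: float = 70.0
    bsa_m2: float = 1.7
    antibody_infusion_hours_first: float = 1.5
    antibody_infusion_hours_later: float = 0.5
    ae_risks: dict[str, float] = field(default_factory=dict)
    median_tot_cycles: float = 0.0  # median time on treatment, cycles

    def __post_init__(self):
        if abs(sum(self.chemo_mix.values()) - 1.0) > 1e-9:
            raise ValueError("chemotherapy mix proportions must sum to 1")
        if self.body_weight_kg <= 0 or self.bsa_m2 <= 0:
            raise ValueError("body weight and BSA must be positive")
        unknown = set(self.chemo_mix) - set(self.chemo_dosing)
        if unknown:
            raise ValueError(f"no dosing rule for chemotherapy drug(s): {sorted(unknown)}")
        if any(not 0 <= r <= 1 for r in self.ae_risks.values()):
            raise ValueError("AE risks must lie in [0, 1]")

    def antibody_mg(self, cycle_index: int) -> float:
        dose = self.dose_mg_per_kg
        if cycle_index == 0 and self.loading_dose_mg_per_kg is not None:
            dose = self.loading_dose_mg_per_kg
        return dose * self.body_weight_kg


def _infusion_cost(costs: CostInputs, hours: float) -> float:
    """Cost of one infusion under the country's administration schema."""
    if costs.admin_flat is not None:
        return costs.admin_flat
    extra = max(hours - 1.0, 0.0)
    return costs.admin_first_hour + extra * costs.admin_addl_hour


def drug_cost_per_cycle(regimen: RegimenSpec, costs: CostInputs, cycle_index: int) -> float:
    """Acquisition cost of antibody plus mix-weighted chemotherapy for one cycle."""
    try:
        antibody_price = costs.drug_prices[regimen.antibody]
    except KeyError:
        raise ValueError(f"no price for antibody {regimen.antibody!r}") from None
    total = regimen.antibody_mg(cycle_index) * antibody_price
    for drug, share in regimen.chemo_mix.items():
        if drug not in costs.drug_prices:
            raise ValueError(f"no price for chemotherapy drug {drug!r}")
        rule = regimen.chemo_dosing[drug]
        mg = rule.dose_mg_per_m2 * regimen.bsa_m2 * rule.administrations_per_cycle
        total += share * mg * costs.drug_prices[drug]
    return total


def admin_cost_per_cycle(regimen: RegimenSpec, costs: CostInputs, cycle_index: int) -> float:
    """Administration cost: one antibody infusion plus mix-weighted IV chemo."""
    hours = (regimen.antibody_infusion_hours_first if cycle_index == 0
             else regimen.antibody_infusion_hours_later)
    total = _infusion_cost(costs, hours)
    for drug, share in regimen.chemo_mix.items():
        rule = regimen.chemo_dosing[drug]
        if rule.oral:
            continue
        # IV partners are given on days 1 and 8: one infusion per administration.
        n_infusions = rule.administrations_per_cycle
        total += share * n_infusions * _infusion_cost(costs, rule.infusion_hours)
    return total


def expected_ae_cost(risks: dict[str, float], ae_costs: dict[str, float]) -> float:
    """Risk-weighted one-time cost of managing grade ≥3 adverse events."""
    total = 0.0
    for ae, prob in risks.items():
        if not 0 <= prob <= 1:
            raise ValueError(f"AE risk for {ae!r} outside [0, 1]")
        if ae not in ae_costs:
            raise ValueError(f"no management cost configured for AE {ae!r}")
        total += prob * ae_costs[ae]
    return total


def expected_ae_disutility_qaly(
    risks: dict[str, float],
    disutilities: dict[str, float],
    duration_years: float,
) -> float:
    """One-time QALY decrement: Σ risk × disutility × assumed event duration."""
    total = 0.0
    for ae, prob in risks.items():
        if ae not in disutilities:
            raise ValueError(f"no disutility configured for AE {ae!r}")
        total += prob * disutilities[ae] * duration_years
    return total


@dataclass
class CEResult:
    """Incremental cost-effectiveness of intervention vs comparator."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: float | None
    dominance: str | None  # "dominant", "dominated", or None
    nmb_by_wtp: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost, "delta_qaly": self.delta_qaly,
            "delta_ly": self.delta_ly, "icer": self.icer,
            "dominance": self.dominance,
            "inmb_by_wtp": {str(k): v for k, v in self.nmb_by_wtp.items()},
        }


def nmb(total_cost: float, total_qalys: float, wtp: float) -> float:
    """Net monetary benefit: QALYs × WTP − cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return total_qalys * wtp - total_cost


def icer(
    intervention: "ArmResult",
    comparator: "ArmResult",
    wtps: tuple[float, ...] = (),
) -> CEResult:
    """Pairwise incremental statistics (intervention − comparator).

    The ICER is left undefined (None) when ΔQALY is numerically zero.
    Dominance is flagged when one strategy is both cheaper and more
    effective. ``nmb_by_wtp`` holds the *incremental* NMB at each WTP.
    """
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.total_qalys - comparator.total_qalys
    dl = intervention.total_lys - comparator.total_lys
    ratio = dc / dq if abs(dq) > 1e-9 else None
    dominance = None
    if dc < 0 and dq > 0:
        dominance = "dominant"
    elif dc > 0 and dq < 0:
        dominance = "dominated"
    inmb = {w: dq * w - dc for w in wtps}
    return CEResult(dc, dq, dl, ratio, dominance, inmb)
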