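"""Base-case model inputs for the US and China configurations.

Unit costs (2021 USD; Chinese prices pre-converted at 6.45 CNY/USD),
health-state utilities, grade ≥3 adverse-event risks and disutilities,
and sensitivity ranges/distribution families for every varied parameter.
One transcription note: the published US anemia management cost appears
with a shifted comma ("146,36.53"); it is entered here as 14,636.53,
consistent with its stated range 11,709.22–17,563.84.

Parameter names are flat, dotted keys so the sensitivity layer can
override any one of them without knowing the model's object structure.
"""

from __future__ import annotations

from .economics import CostInputs, RegimenSpec, UtilitySet

__all__ = [
    "build_cost_inputs",
    "build_utilities",
    "build_regimen",
    "base_parameters",
    "parameter_kinds",
    "AE_RISKS",
    "AE_DISUTILITIES",
    "MEDIAN_TOT_CYCLES",
]

_US_COSTS = {
    "drug.margetuximab": 8.75,
    "drug.trastuzumab": 8.64,
    "drug.capecitabine": 0.00,
    "drug.eribulin": 1274.36,
    "drug.gemcitabine": 0.02,
    "drug.vinorelbine": 0.86,
    "care.supportive": 5600.00,
    "care.followup": 1890.00,
    "care.end_of_life": 21585.00,
    "admin.first_hour": 136.61,
    "admin.addl_hour": 28.71,
    "ae_cost.neutrophil_count_decreased": 10603.70,
    "ae_cost.anemia": 14636.53,  # printed "146,36.53"; range 11,709.22-17,563.84
    "ae_cost.neutropenia": 10603.70,
}

_CN_COSTS = {
    "drug.margetuximab": 8.75,  # US market price (not yet marketed in China)
    "drug.trastuzumab": 1.94,
    "drug.capecitabine": 0.02,
    "drug.eribulin": 617.15,
    "drug.gemcitabine": 0.09,
    "drug.vinorelbine": 2.38,
    "care.supportive": 1616.78,
    "care.followup": 162.00,
    "care.end_of_life": 1275.03,
    "admin.flat": 22.00,
    "ae_cost.neutrophil_count_decreased": 3184.01,
    "ae_cost.anemia": 607.52,
    "ae_cost.neutropenia": 3184.01,
}

_UTILITIES = {
    "US": {"utility.pfs": 0.72, "utility.pd": 0.47},
    "CN": {"utility.pfs": 0.85, "utility.pd": 0.52},
}

#: Grade ≥3 AEs occurring in ≥5% of either arm.
AE_RISKS = {
    "margetuximab": {
        "risk.margetuximab.neutrophil_count_decreased": 0.09,
        "risk.margetuximab.neutropenia": 0.20,
    },
    "trastuzumab": {
        "risk.trastuzumab.neutrophil_count_decreased": 0.11,
        "risk.trastuzumab.anemia": 0.06,
        "risk.trastuzumab.neutropenia": 0.12,
    },
}

AE_DISUTILITIES = {
    "disutility.neutrophil_count_decreased": 0.13,
    "disutility.anemia": 0.07,
    "disutility.neutropenia": 0.13,
}

#: Median cycles on treatment reported for each arm.
MEDIAN_TOT_CYCLES = {"margetuximab": 6.0, "trastuzumab": 5.0}

_DISCOUNT = {"discount.annual": 0.03}

#: Published ranges that differ from the ±20%/±10% defaults.
_EXPLICIT_RANGES = {
    "discount.annual": (0.0, 0.08),
}


def base_parameters(country: str) -> dict[str, float]:
    """Flat base-case parameter map for one country."""
    costs = {"US": _US_COSTS, "CN": _CN_COSTS}[country]
    out: dict[str, float] = dict(costs)
    out.update(_UTILITIES[country])
    for arm_risks in AE_RISKS.values():
        out.update(arm_risks)
    out.update(AE_DISUTILITIES)
    out.update(_DISCOUNT)
    return out


def parameter_kinds(country: str) -> dict[str, str]:
    """Kind of each parameter: cost, utility, risk, or fixed-range special."""
    kinds = {}
    for name in base_parameters(country):
        if name.startswith(("drug.", "care.", "admin.", "ae_cost.")):
            kinds[name] = "cost"
        elif name.startswith(("utility.", "disutility.")):
            kinds[name] = "utility"
        elif name.startswith("risk."):
            kinds[name] = "risk"
        else:
            kinds[name] = "other"
    return kinds


def explicit_range(name: str) -> tuple[float, float] | None:
    return _EXPLICIT_RANGES.get(name)


def _strip(prefix: str, params: dict[str, float]) -> dict[str, float]:
    return {k[len(prefix):]: v for k, v in params.items() if k.startswith(prefix)}


def build_cost_inputs(country: str, params: dict[str, float] | None = None) -> CostInputs:
    """Assemble CostInputs from the flat parameter map (defaults if None)."""
    p = base_parameters(country) if params is None else params
    kwargs = dict(
        country=country,
        drug_prices=_strip("drug.", p),
        supportive_care=p["care.supportive"],
        routine_followup=p["care.followup"],
        end_of_life=p["care.end_of_life"],
        ae_costs=_strip("ae_cost.", p),
    )
    if "admin.flat" in p:
        kwargs["admin_flat"] = p["admin.flat"]
    else:
        kwargs["admin_first_hour"] = p["admin.first_hour"]
        kwargs["admin_addl_hour"] = p["admin.addl_hour"]
    return CostInputs(**kwargs)


def build_utilities(country: str, params: dict[str, float] | None = None) -> UtilitySet:
    p = base_parameters(country) if params is None else params
    return UtilitySet(
        u_pfs=p["utility.pfs"],
        u_pd=p["utility.pd"],
        ae_disutilities=_strip("disutility.", p),
    )


def build_regimen(arm: str, params: dict[str, float] | None = None,
                  body_weight_kg: float = 70.0, bsa_m2: float = 1.7) -> RegimenSpec:
    """Regimen for one arm: antibody dosing rule plus the shared chemo mix.

    AE risk keys are stripped of their arm prefix so they align with the
    AE cost/disutility names.
    """
    if arm not in AE_RISKS:
        raise ValueError(f"unknown arm {arm!r}")
    p = base_parameters("US") if params is None else params
    prefix = f"risk.{arm}."
    risks = {k[len(prefix):]: v for k, v in p.items() if k.startswith(prefix)}
    if arm == "margetuximab":
        dose, loading = 15.0, None
    else:
        dose, loading = 6.0, 8.0
    return RegimenSpec(
        antibody=arm,
        dose_mg_per_kg=dose,
        loading_dose_mg_per_kg=loading,
        body_weight_kg=body_weight_kg,
        bsa_m2=bsa_m2,
        ae_risks=risks,
        median_tot_cycles=MEDIAN_TOT_CYCLES[arm],
    )
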