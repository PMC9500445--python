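"""Deterministic and probabilistic sensitivity analysis.

One-way analysis reruns the two-arm model at each parameter's low/high
bound (±20% for costs, ±10% for utilities and risks, unless a published
range overrides) and ranks parameters by ICER swing for a tornado
diagram. Probabilistic analysis draws costs from gamma and utilities and
risks from beta distributions, moment-matched so the mean equals the
base case and the standard deviation is (high − low)/3.92 (the range
read as a 95% interval), then summarises the Monte-Carlo cloud of
(Δcost, ΔQALY) pairs as a cost-effectiveness acceptability curve. A
bisection on a price multiplier finds the smallest price reduction that
brings the ICER down to a willingness-to-pay threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .model import TwoArmModel
from .params import explicit_range, parameter_kinds

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "PSAResult",
    "default_ranges",
    "build_param_specs",
    "one_way_dsa",
    "sample_inputs",
    "run_psa",
    "ceac",
    "price_threshold",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain input: base value, range, and PSA distribution family."""

    name: str
    base: float
    low: float
    high: float
    family: str  # "gamma", "beta", or "fixed"

    def __post_init__(self):
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: require low ≤ base ≤ high")
        if self.family not in ("gamma", "beta", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution {self.family!r}")
        if self.family == "beta" and not (0 <= self.low and self.high <= 1):
            raise ValueError(f"{self.name}: beta requires a [0, 1]-bounded range")
        if self.family == "gamma" and self.low < 0:
            raise ValueError(f"{self.name}: gamma requires non-negative values")


def default_ranges(base: float, kind: str) -> tuple[float, float]:
    """±20% for costs, ±10% for utilities and risks (capped at 1)."""
    if base < 0:
        raise ValueError("base value must be non-negative")
    if kind == "cost":
        return 0.8 * base, 1.2 * base
    if kind in ("utility", "risk"):
        return 0.9 * base, min(1.1 * base, 1.0)
    raise ValueError(f"unknown parameter kind {kind!r}")


def build_param_specs(country: str, include_fixed: bool = True) -> list[ParamSpec]:
    """Sensitivity specifications for every varied input of one country."""
    from .params import base_parameters

    specs = []
    kinds = parameter_kinds(country)
    for name, base in base_parameters(country).items():
        kind = kinds[name]
        rng = explicit_range(name)
        if kind == "other":
            if not include_fixed:
                continue
            low, high = rng if rng else (base, base)
            specs.append(ParamSpec(name, base, low, high, "fixed"))
            continue
        low, high = rng if rng else default_ranges(base, kind)
        family = "gamma" if kind == "cost" else "beta"
        specs.append(ParamSpec(name, base, low, high, family))
    return specs


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    icer_at_low: float
    icer_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _icer_value(ce) -> float:
    # Dominant/dominated runs still have a well-defined cost/QALY ratio for
    # tornado plotting; undefined ΔQALY maps to NaN.
    return ce.icer if ce.icer is not None else math.nan


def one_way_dsa(model: TwoArmModel, specs: list[ParamSpec] | None = None,
                ) -> list[TornadoEntry]:
    """Rerun the model at each parameter's bounds; sort by descending swing."""
    if specs is None:
        specs = build_param_specs(model.country)
    entries = []
    for spec in specs:
        try:
            _, ce_low = model.evaluate({spec.name: spec.low})
            _, ce_high = model.evaluate({spec.name: spec.high})
            entries.append(TornadoEntry(spec.name, _icer_value(ce_low),
                                        _icer_value(ce_high)))
        except Exception as exc:  # flagged, not fatal
            logger.warning("DSA failed for %s: %s", spec.name, exc)
            entries.append(TornadoEntry(spec.name, math.nan, math.nan))
    entries.sort(key=lambda e: -(e.swing if math.isfinite(e.swing) else -1.0))
    return entries


def _gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return shape, scale


def _beta_moments(mean: float, sd: float) -> tuple[float, float]:
    var = sd ** 2
    if var >= mean * (1 - mean):
        raise ValueError("beta variance infeasible for this mean")
    nu = mean * (1 - mean) / var - 1
    return mean * nu, (1 - mean) * nu


def sample_inputs(specs: list[ParamSpec], rng: np.random.Generator,
                  ) -> dict[str, float]:
    """One joint draw: gamma for costs, beta for utilities/risks, base for fixed.

    Distributions are moment-matched to mean = base and
    sd = (high − low)/3.92; degenerate ranges (sd = 0) and infeasible beta
    moments fall back to the base value and a uniform(low, high) draw.
    """
    draw = {}
    for spec in specs:
        sd = (spec.high - spec.low) / 3.92
        if spec.family == "fixed" or sd <= 0 or spec.base <= 0:
            draw[spec.name] = spec.base
            continue
        if spec.family == "gamma":
            shape, scale = _gamma_moments(spec.base, sd)
            draw[spec.name] = float(rng.gamma(shape, scale))
        else:
            try:
                a, b = _beta_moments(spec.base, sd)
                draw[spec.name] = float(rng.beta(a, b))
            except ValueError:
                logger.warning("infeasible beta moments for %s; uniform fallback",
                               spec.name)
                draw[spec.name] = float(rng.uniform(spec.low, spec.high))
    return draw


@dataclass
class PSAResult:
    """Monte-Carlo (Δcost, ΔQALY) pairs from repeated joint input draws."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    n_iter: int

    def __post_init__(self):
        if len(self.delta_cost) != self.n_iter or len(self.delta_qaly) != self.n_iter:
            raise ValueError("iteration arrays must have length n_iter")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iter": np.arange(self.n_iter),
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
        })


def run_psa(model: TwoArmModel, n_iter: int = 1000, seed: int = 0,
            specs: list[ParamSpec] | None = None) -> PSAResult:
    """n_iter full two-arm evaluations on independent joint input draws."""
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    if specs is None:
        specs = build_param_specs(model.country)
    rng = np.random.default_rng(seed)
    dc = np.empty(n_iter)
    dq = np.empty(n_iter)
    for it in range(n_iter):
        for attempt in range(2):
            draw = sample_inputs(specs, rng)
            try:
                _, ce = model.evaluate(draw)
                dc[it], dq[it] = ce.delta_cost, ce.delta_qaly
                break
            except Exception as exc:
                logger.warning("PSA iteration %d failed (%s); resampling", it, exc)
                if attempt == 1:
                    raise RuntimeError(
                        f"PSA aborted: two consecutive failures at iteration {it}"
                    ) from exc
    return PSAResult(dc, dq, seed=seed, n_iter=n_iter)


def ceac(psa: PSAResult, wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
    """P(cost-effective) per WTP: fraction of draws with positive incremental NMB."""
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 700_001.0, 1000.0)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    probs = [(psa.delta_qaly * w - psa.delta_cost > 0).mean() for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": probs})


def price_threshold(model: TwoArmModel, wtp: float | None = None,
                    target_drug: str = "margetuximab",
                    tol: float = 1e-3) -> float | None:
    """Smallest price reduction of ``target_drug`` making the ICER ≤ WTP.

    Returns the reduction fraction 1 − m, where m is the price multiplier;
    0.0 if the base case is already cost-effective; None when even a free
    drug leaves the ICER above the threshold. Solved by bisection on the
    incremental net monetary benefit, which is monotone in the multiplier.
    """
    if wtp is None:
        wtp = model.wtp

    def inmb(mult: float) -> float:
        _, ce = model.evaluate(price_multipliers={target_drug: mult})
        return ce.delta_qaly * wtp - ce.delta_cost

    if inmb(1.0) >= 0:
        return 0.0
    if inmb(0.0) < 0:
        logger.warning("no feasible %s price threshold at WTP %s", target_drug, wtp)
        return None
    m = optimize.brentq(inmb, 0.0, 1.0, xtol=tol)
    # report the smallest reduction that is actually cost-effective
    if inmb(m) < 0:
        m = max(m - tol, 0.0)
    return 1.0 - m
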