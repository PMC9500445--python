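"""Parametric survival families shared by the data generator and the fitters.

Six families are supported: exponential, Weibull, log-normal, gamma,
log-logistic and Gompertz. Each is exposed through a small uniform
interface — survival function, log-density, random sampling, and a
closed-form median where one exists — parameterised in months:

* exponential: ``rate`` λ (1/month), S(t) = exp(-λt)
* weibull: ``shape`` k, ``scale`` λ, S(t) = exp(-(t/λ)^k)
* lognormal: ``mu``, ``sigma`` of log-time
* gamma: ``shape`` a, ``rate`` r (scale = 1/r)
* loglogistic: ``shape`` β, ``scale`` α, S(t) = 1 / (1 + (t/α)^β)
* gompertz: hazard h(t) = b·exp(c·t), S(t) = exp(-(b/c)(e^{ct} - 1))

scipy.stats supplies the first five; Gompertz in this actuarial
parameterisation (c unconstrained, c → 0 degenerating to the exponential)
is implemented directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = ["FAMILIES", "Family", "get_family"]

_EPS_C = 1e-9  # |c| below this treats Gompertz as exponential


def _gompertz_cumhaz(t, b, c):
    t = np.asarray(t, dtype=float)
    if abs(c) < _EPS_C:
        return b * t
    return (b / c) * np.expm1(c * t)


def _gompertz_sf(t, b, c):
    return np.exp(-_gompertz_cumhaz(t, b, c))


def _gompertz_logpdf(t, b, c):
    t = np.asarray(t, dtype=float)
    return np.log(b) + c * t - _gompertz_cumhaz(t, b, c)


def _gompertz_rvs(rng, n, b, c):
    u = rng.uniform(size=n)
    if abs(c) < _EPS_C:
        return -np.log(u) / b
    arg = 1.0 - c * np.log(u) / b
    # c < 0 has a survivor plateau exp(b/c); resample the defective mass
    out = np.full(n, np.inf)
    ok = arg > 0
    out[ok] = np.log(arg[ok]) / c
    return out


def _gompertz_median(b, c):
    if abs(c) < _EPS_C:
        return math.log(2) / b
    arg = 1.0 + c * math.log(2) / b
    if arg <= 0:
        return None  # S never reaches 1/2 (decreasing hazard plateau)
    return math.log(arg) / c


@dataclass(frozen=True)
class Family:
    """One parametric survival family behind a uniform callable surface."""

    name: str
    param_names: tuple[str, ...]
    #: True where the parameter is positive and fitted on the log scale.
    log_scale: tuple[bool, ...]
    _frozen: Callable  # params -> scipy-like frozen dist (sf/logpdf/rvs)
    closed_form_median: Callable | None = None

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def _dist(self, params: Sequence[float]):
        return self._frozen(*params)

    def sf(self, t, params):
        return np.clip(self._dist(params).sf(np.asarray(t, dtype=float)), 0.0, 1.0)

    def logpdf(self, t, params):
        return self._dist(params).logpdf(np.asarray(t, dtype=float))

    def logsf(self, t, params):
        return self._dist(params).logsf(np.asarray(t, dtype=float))

    def rvs(self, rng: np.random.Generator, n: int, params):
        return self._dist(params).rvs(size=n, random_state=rng)

    def median(self, params) -> float | None:
        if self.closed_form_median is not None:
            return self.closed_form_median(*params)
        return None


class _GompertzFrozen:
    def __init__(self, b, c):
        self.b, self.c = b, c

    def sf(self, t):
        return _gompertz_sf(t, self.b, self.c)

    def logsf(self, t):
        return -_gompertz_cumhaz(t, self.b, self.c)

    def logpdf(self, t):
        return _gompertz_logpdf(t, self.b, self.c)

    def rvs(self, size, random_state):
        return _gompertz_rvs(random_state, size, self.b, self.c)


FAMILIES: dict[str, Family] = {
    "exponential": Family(
        "exponential", ("rate",), (True,),
        lambda rate: stats.expon(scale=1.0 / rate),
        closed_form_median=lambda rate: math.log(2) / rate,
    ),
    "weibull": Family(
        "weibull", ("shape", "scale"), (True, True),
        lambda shape, scale: stats.weibull_min(c=shape, scale=scale),
        closed_form_median=lambda shape, scale: scale * math.log(2) ** (1.0 / shape),
    ),
    "lognormal": Family(
        "lognormal", ("mu", "sigma"), (False, True),
        lambda mu, sigma: stats.lognorm(s=sigma, scale=math.exp(mu)),
        closed_form_median=lambda mu, sigma: math.exp(mu),
    ),
    "gamma": Family(
        "gamma", ("shape", "rate"), (True, True),
        lambda shape, rate: stats.gamma(a=shape, scale=1.0 / rate),
    ),
    "loglogistic": Family(
        "loglogistic", ("shape", "scale"), (True, True),
        lambda shape, scale: stats.fisk(c=shape, scale=scale),
        closed_form_median=lambda shape, scale: scale,
    ),
    "gompertz": Family(
        "gompertz", ("rate", "shape"), (True, False),
        lambda rate, shape: _GompertzFrozen(rate, shape),
        closed_form_median=_gompertz_median,
    ),
}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown survival family {name!r}; expected one of {sorted(FAMILIES)}"
        ) from None
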