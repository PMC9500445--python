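"""Shared time-unit conventions.

All survival functions are parameterised in months; the Markov engine runs
on 21-day cycles. Fixing the month length removes month/cycle rounding
ambiguity everywhere downstream.
"""

DAYS_PER_MONTH: float = 30.4375
DAYS_PER_YEAR: float = 365.0
CYCLE_DAYS: float = 21.0
CYCLE_MONTHS: float = CYCLE_DAYS / DAYS_PER_MONTH
CYCLE_YEARS: float = CYCLE_DAYS / DAYS_PER_YEAR

#: Default model start age (trial ITT population: women 56 years and over).
START_AGE: float = 56.0

#: Annual discount rate applied to both costs and health outcomes.
ANNUAL_DISCOUNT: float = 0.03

#: Willingness-to-pay thresholds, $/QALY (China: three times GDP per capita).
WTP = {"US": 150_000.0, "CN": 37_653.0}

#: Fixed exchange rate used to express Chinese costs in 2021 USD.
CNY_PER_USD: float = 6.45
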