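# Methods

This note documents the model implemented in `margcea`, the assumptions
behind each stage, the defaults and why they were chosen, and what the
synthetic study conditions do and do not establish about the real
evidence base.

## The decision problem

Margetuximab plus chemotherapy is compared with trastuzumab plus
chemotherapy for women with ERBB2-positive advanced breast cancer who
progressed after two or more anti-ERBB2 regimens. The comparison is run
from the US and the Chinese health-system perspectives, with lifetime
costs in 2021 USD (Chinese inputs pre-converted at 6.45 CNY/USD),
life-years (LY) and quality-adjusted life-years (QALY) as outcomes, and
the incremental cost-effectiveness ratio (ICER, $/QALY) as the primary
result, judged against willingness-to-pay (WTP) thresholds of $150,000
(US) and $37,653 (China, three times GDP per capita).

## Cohort model

A three-state Markov cohort model — progression-free (PFS), progressed
disease (PD), death — advances in 21-day cycles. The cohort starts
entirely in PFS at age 56. Transition probabilities are time-dependent
and derived from two fitted survival curves per arm by a
partitioned-survival decomposition:

* overall per-cycle death probability: `q(t) = 1 − S_os(t+Δ)/S_os(t)`,
  floored at the life-table background probability for the cohort's
  attained age (annual `q_x` converted by `1 − (1−q_x)^{21/365}`);
* PFS exit: `e(t) = 1 − S_pfs(t+Δ)/S_pfs(t)`, floored at the same
  background probability (PFS members cannot die at less than the
  background rate);
* PFS→death is `min(q, e)`; the remaining PFS exits progress; the
  PD→death probability is solved each cycle so the alive fraction tracks
  `S_os` exactly, clamped to [0, 1].

If the independently fitted curves cross in extrapolation, `S_pfs` is
clamped to `S_os` and the number of clamped cycles logged. The model
stops when death occupancy exceeds 0.999 or at 20 years, whichever
comes first; with the default inputs the 0.999 rule triggers around
year 10, so the cap is not binding. Internally time is measured in days
(1 month = 30.4375 days, cycle = 21 days) to avoid month/cycle rounding
ambiguity.

Rewards use a half-cycle (trapezoid) correction on state occupancies.
One-time entry quantities — the trastuzumab loading-dose cost difference
and the expected adverse-event cost and disutility — are charged in full
at cycle 0, deliberately not halved, so loading doses are not eroded by
the correction. Costs and outcomes are discounted at 3%/year compounded
continuously over cycle time, `(1+r)^{−t/365}`.

## Survival inputs

The evidence base is a pair of published Kaplan-Meier figures per arm
(PFS and OS) with numbers at risk; patient-level data are not available.
The package therefore works with three layers:

1. **Synthetic generation** (`synthetic_data`): event times are drawn
   from a log-logistic model for PFS and a Weibull model for OS — the
   families adopted for the published curves — calibrated so arm medians
   equal the reported 5.7/4.4 months (PFS) and 21.6/19.8 months (OS),
   with administrative censoring at 30 months emulating trial follow-up.
   Shapes are shared between arms within an endpoint, so the contrast is
   a pure accelerated-failure-time shift fixed by the median ratio.
2. **Figure emulation**: KM curves are sampled on a 0.1-month grid
   (digitization stand-in) and 3-month interval numbers at risk are
   tabulated.
3. **Reconstruction and refit** (`ipd_reconstruction`,
   `survival_models`): pseudo individual-patient data are rebuilt from
   the curve + risk table, and the endpoint's family is refitted by
   maximum likelihood.

### Shape calibration to the reported hazard ratios

The trial reports Cox hazard ratios of 0.71 (PFS) and 0.89 (OS) alongside
the medians. For the Weibull OS model a shared shape of 1.3 implies a
constant HR of (19.8/21.6)^1.3 ≈ 0.893, matching the report directly; 1.3
also encodes a mildly rising OS hazard typical of advanced disease. The
log-logistic is not proportional-hazards: its hazard ratio starts at
(m₀/m₁)^β and drifts toward 1, so what a Cox model estimates is an
event-weighted average. The package computes that estimand exactly (the
population partial-likelihood score solved by quadrature,
`cox_estimand_hr`) and the default PFS shape of 2.6 is the value at which
the estimand equals 0.71 under 30-month follow-up
(`solve_loglogistic_shape_for_hr`). Shallower shapes cannot reach the
reported HR: at shape 1.5 the event-weighted average is ≈ 0.82 regardless
of sample size. Both shapes are configurable.

### Reconstruction algorithm

Within each number-at-risk interval the algorithm assumes censoring is
spread uniformly, initialises the interval's censoring count from the
attrition not explained by the curve's survival drop, assigns integer
event counts at each digitized step so the running product-limit
estimate tracks the curve, and iterates the censoring count until the
implied number at risk at the next interval start matches the published
value. Event times sit at the digitized step times; censoring times at
uniform quantile midpoints; patients still at risk after the last
coordinate are censored at the end of follow-up. A digitized drop lying
exactly on a risk-table boundary is attributed to the earlier interval
(the published count excludes those events); symmetrically, a deficit no
larger than the boundary coordinate's own event count is tolerated when
real event-time ties sit on the boundary. An optional known total event
count rebalances the final assignment. Fidelity is summarised as the
sup-norm distance between the input curve and the KM curve of the
output; with no censoring before follow-up end the round trip is exact,
and with 20% random censoring and 6-month intervals the deviation stays
below 0.02.

### Parametric fitting

Six families are supported (exponential, Weibull, log-normal, gamma,
log-logistic, Gompertz), all parameterised in months: Gompertz as hazard
`b·e^{ct}`, log-normal by (μ, σ) of log-time, gamma by (shape, rate).
Right-censored maximum likelihood is optimised on a log scale for
positive parameters (Nelder-Mead polished by BFGS); the exponential rate
has the closed form events/exposure. AIC and BIC are both reported;
selection ties break toward fewer parameters, then a fixed family order.
The fitted Weibull and log-logistic models agree with the corresponding
lifelines fitters to three significant figures on shared data (tested).

## Treatment costing

Margetuximab is dosed at 15 mg/kg every cycle; trastuzumab at 6 mg/kg
after an 8 mg/kg loading dose. The chemotherapy backbone is a
usage-weighted mix (vinorelbine 35.6%, capecitabine 26.7%, eribulin
25.4%, gemcitabine 12.3%) with protocol dosing: capecitabine
1,000 mg/m² twice daily days 1–14 (oral), eribulin 1.4 mg/m² and
gemcitabine 1,000 mg/m² and vinorelbine 25 mg/m² on days 1 and 8.
Body weight defaults to 70 kg and body-surface area to 1.7 m²
(conventional model defaults; the source analysis does not state them),
both configurable. Administration is costed per infusion: US first-hour
plus additional-hour rates (antibody infusions 1.5 h at cycle 0, 0.5 h
thereafter; IV chemotherapy 0.5 h), China a flat per-administration fee.

Drug acquisition and administration accrue on the **on-treatment
fraction**: the PFS occupancy scaled by the ratio of median time on
treatment to median PFS (6 cycles / 8.26 cycles ≈ 0.726 for
margetuximab; 5 / 6.38 ≈ 0.784 for trastuzumab), reflecting that
patients stop therapy before progressing. Routine follow-up accrues on
PFS occupancy, best supportive care on PD occupancy (both per cycle, the
single published figures read as per-cycle rates), and end-of-life care
once per incident death. Grade ≥3 adverse events occurring in ≥5% of
either arm (neutropenia, decreased neutrophil count, anemia) enter as
one-time risk-weighted expectations at model entry: risk × management
cost, and risk × disutility × an assumed 3-week duration. Timing of AE
handling (one-time vs per-cycle) is a documented simplification; the
accrual function takes the expectation explicitly so alternatives are
easy to wire.

One transcription note: the published US anemia management cost appears
with a shifted comma ("146,36.53"); it is entered as $14,636.53,
consistent with its stated range ($11,709.22–$17,563.84), and the
correction is recorded in every pipeline manifest.

## Sensitivity analysis

* **One-way (tornado)**: each parameter is moved to its bounds — ±20%
  for costs, ±10% for utilities and risks (capped at 1), the published
  0–0.08 range for the discount rate — holding the rest at base; entries
  are ranked by ICER swing.
* **Probabilistic**: costs are drawn from gamma and utilities/risks from
  beta distributions, moment-matched so the mean equals the base case
  and the SD is (high − low)/3.92 (the range read as a 95% interval);
  the discount rate is fixed. Infeasible beta moments fall back to
  uniform draws with a warning. Default 1,000 iterations. Survival-curve
  parameters are held at their fitted values — the published input table
  assigns them no distribution — so the PSA quantifies economic-input
  uncertainty only.
* **CEAC**: the probability of cost-effectiveness at each WTP is the
  fraction of draws with positive incremental net monetary benefit, on a
  $0–$700,000 grid by default.
* **Price threshold**: the smallest price reduction of a target drug
  that brings the ICER to the WTP is found by root-finding on the
  incremental net monetary benefit, which is monotone in the price
  multiplier; the returned reduction is verified cost-effective and
  0.002 less reduction is verified not to be (bracketing witness).

Because state occupancies depend only on the survival fits and the life
table, traces are computed once and cached; sensitivity evaluations
re-accrue economics over the cached traces, making a 1,000-iteration
PSA a sub-second computation. This is an exact reformulation, not an
approximation: the same accrual code produces the base case.

## Background mortality

National life tables enter as (age, annual death probability) CSVs. The
bundled stand-ins are Gompertz–Makeham,
`q_x = 1 − exp(−(a + b·e^{c·age}))`, with a = 5·10⁻⁴, c = 0.11 and
b = 1.5·10⁻⁵ (US) / 1.3·10⁻⁵ (CN), putting `q_56` near 0.006–0.008 as in
period tables for women at that age. With the default disease curves the
background floor binds only in the far tail, so results are insensitive
to the stand-in's exact level; real tables drop in with the same schema.

## What the synthetic conditions show — and what they do not

The generators reproduce the *summary structure* of the trial evidence:
family shapes, medians, average hazard ratios, follow-up truncation, and
number-at-risk reporting. Passing round trips therefore demonstrate that
the reconstruction-and-refit machinery recovers known truth through the
published-figure bottleneck, and that the economic engine is internally
consistent. They do not reproduce the actual digitized curves, so
absolute cost and QALY totals — and quantities that scale with the
incremental cost, such as the base ICER (≈ $546k US / $589k China here)
and the price-reduction thresholds — differ from the source analysis'
printed values, while the qualitative conclusions (costlier and more
effective in both countries; not cost-effective at either national WTP;
a far larger price cut needed in China than in the US; margetuximab
price the dominant tornado driver) are stable. One consequence worth
flagging: with the larger synthetic incremental cost, the ±10% PFS
utility swing narrowly outranks the ±20% trastuzumab price swing in the
US tornado (≈ $113k vs ≈ $101k), so the trastuzumab price sits third
rather than second there.

## Numerical choices

* Tie-breaks in reconstruction are deterministic (earliest sub-interval
  gets the extra event; censorings at quantile midpoints), so identical
  inputs give byte-identical outputs.
* Medians use closed forms where they exist and bisection to 10⁻⁶ months
  otherwise; an error is raised if survival stays above ½ for 1,000
  months.
* Degenerate inputs: all-censored samples are rejected by the fitters;
  `S_os = 0` yields an absorbing-death transition row rather than an
  error; zero-width sensitivity ranges collapse to fixed draws.
* Problem sizes: round trips and hazard-ratio checks use 20,000 patients
  per arm (Monte-Carlo SD of a refitted median ≈ 0.03 months, of a Cox
  HR ≈ 0.008), PSA uses 1,000 iterations; unit tests use 500–2,000
  patients.

## Known limitations

* The time-on-treatment adjustment scales the whole PFS curve by a
  constant ratio; a duration cap at the median would shift costs earlier
  and lower incremental cost.
* AE risks are sampled independently in the PSA; any within-arm
  correlation is ignored.
* Vial wastage, dose rounding, indirect costs and treatment after
  progression beyond best supportive care are out of scope.
* The synthetic evidence layer cannot stand in for the real digitized
  curves where absolute magnitudes matter; file-based curve and risk
  inputs are the intended path for a faithful re-analysis.
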