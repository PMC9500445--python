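"""Pseudo individual-patient data from digitized survival curves.

Published Kaplan-Meier figures carry nearly all the information a
parametric refit needs, but only as a step curve plus numbers at risk.
This module inverts the product-limit construction: within each
number-at-risk interval it assumes censoring is spread uniformly, solves
integer event/censoring counts so that (i) the KM estimator of the output
matches the digitized curve at each coordinate as closely as integer
counts allow and (ii) the number at risk matches the published table
exactly at each interval start, and emits (time, event) records. The
fidelity of a run is summarised by the sup-norm distance between the
input curve and the KM curve of the reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .synthetic_data import DigitizedCurve, IPDSample, RiskTable

__all__ = ["ReconstructionResult", "reconstruct_ipd", "validate_reconstruction"]

logger = logging.getLogger(__name__)

_MAX_ITER = 40


class InfeasibleInputError(ValueError):
    """Curve and risk table imply negative event or censoring counts."""


@dataclass
class ReconstructionResult:
    ipd: IPDSample
    n_events_assigned: int
    n_censored_assigned: int
    max_km_deviation: float

    def __post_init__(self):
        if self.n_events_assigned + self.n_censored_assigned != len(self.ipd):
            raise ValueError("event + censored counts must equal total patients")
        if self.max_km_deviation < 0:
            raise ValueError("max_km_deviation must be non-negative")


def _km_sup_deviation(curve: DigitizedCurve, ipd: IPDSample) -> float:
    """Sup-norm distance between the curve and the KM of the pseudo-IPD."""
    if len(ipd) == 0:
        return float(np.max(np.abs(1.0 - curve.survival)))
    kmf = KaplanMeierFitter().fit(ipd.time_months, ipd.event)
    grid = np.unique(np.concatenate([curve.time_months, ipd.time_months]))
    grid = grid[grid <= curve.time_months[-1]]
    km = np.minimum.accumulate(np.clip(kmf.predict(grid).to_numpy(), 0.0, 1.0))
    return float(np.max(np.abs(km - curve.at(grid))))


def reconstruct_ipd(
    curve: DigitizedCurve,
    risk: RiskTable | None,
    total_events: int | None = None,
    arm_label: str = "",
    endpoint: str = "",
) -> ReconstructionResult:
    """Invert a digitized KM curve (plus numbers at risk) into pseudo-IPD.

    Parameters
    ----------
    curve
        Digitized step-curve coordinates, starting at (0, 1).
    risk
        Interval numbers at risk. If None, a curve-only fallback is used
        that assumes no censoring before the end of follow-up (lower
        fidelity; a warning is logged).
    total_events
        If given, the final event count is rebalanced toward it by
        converting censorings at the last event coordinate (and the
        reverse), within feasibility.

    Notes
    -----
    Within each risk interval the censoring count starts from the
    attrition unexplained by the curve's survival drop and is then
    adjusted iteratively until the implied number at risk at the next
    interval start matches the published value. Censoring times are
    placed at uniform quantile midpoints of the interval; event times at
    the digitized step times; patients still at risk past the last
    coordinate are censored at the end of follow-up.
    """
    t = curve.time_months
    s = curve.survival
    n_coords = len(t)

    if risk is None:
        logger.warning(
            "no risk table supplied; curve-only reconstruction assumes no "
            "censoring before last follow-up")
        # Treat the whole curve as one interval with a nominal cohort of
        # patients inferred from the smallest survival increment.
        drops = -np.diff(s)
        min_drop = drops[drops > 1e-12].min() if np.any(drops > 1e-12) else 1.0
        n0 = max(int(round(1.0 / min_drop)), 1)
        risk = RiskTable(np.array([0.0]), np.array([n0]))

    starts = risk.interval_starts
    n_at_risk = risk.n_at_risk
    if starts[0] > t[0]:
        raise InfeasibleInputError("risk table must start at or before the curve origin")

    n_total = int(n_at_risk[0])
    event_times: list[float] = []
    censor_times: list[float] = []

    # Running state across intervals: current at-risk count and the KM level
    # of the reconstruction at the last assigned event.
    n_now = n_total
    km_prev = 1.0

    # Coordinate indices per interval [starts[k], starts[k+1]).
    bounds = np.r_[starts, np.inf]
    last_event_coord = None

    for k in range(len(starts)):
        # Left-open/right-closed: a digitized drop exactly at a risk-table
        # boundary pools events from just before it, so it belongs to the
        # earlier interval (the published number at risk excludes them).
        lo_open = -np.inf if k == 0 else bounds[k]
        in_interval = np.where((t > lo_open) & (t <= bounds[k + 1]))[0]
        width_lo = float(bounds[k])
        width_hi = float(min(bounds[k + 1], t[-1]))
        n_target = int(n_at_risk[k + 1]) if k + 1 < len(starts) else None

        if n_target is not None and n_target > n_now:
            raise InfeasibleInputError(
                f"number at risk rises from {n_now} to {n_target} at "
                f"t={starts[k + 1]:g}")

        # Initial censoring guess: attrition not explained by survival drop.
        if n_target is not None:
            s_lo = float(curve.at(width_lo))
            s_hi = float(curve.at(bounds[k + 1]))
            expected_no_cens = n_now * (s_hi / s_lo) if s_lo > 0 else 0.0
            nc = int(round(max(expected_no_cens - n_target, 0.0)))
        else:
            nc = 0

        for _ in range(_MAX_ITER):
            d_trial: list[tuple[int, int]] = []  # (coord index, events)
            cens_trial: list[float] = []
            n_run = n_now
            km_run = km_prev
            # Censor times at uniform quantile midpoints of the interval.
            if nc > 0 and width_hi > width_lo:
                cens_times = width_lo + (np.arange(nc) + 0.5) / nc * (width_hi - width_lo)
            else:
                cens_times = np.empty(0)
            c_ptr = 0
            for idx, j in enumerate(in_interval):
                if n_run <= 0 or km_run <= 0:
                    break
                d = int(round(n_run * (1.0 - s[j] / km_run)))
                d = max(0, min(d, n_run))
                if d > 0:
                    km_run *= 1.0 - d / n_run
                    d_trial.append((j, d))
                    n_run -= d
                # censorings falling between this coordinate and the next
                nxt = t[in_interval[idx + 1]] if idx + 1 < len(in_interval) else bounds[k + 1]
                while c_ptr < nc and cens_times[c_ptr] < nxt and n_run > 0:
                    cens_trial.append(float(max(cens_times[c_ptr], t[j])))
                    n_run -= 1
                    c_ptr += 1
            # leftover censorings after the last coordinate in the interval
            while c_ptr < nc and n_run > 0:
                cens_trial.append(float(cens_times[c_ptr]))
                n_run -= 1
                c_ptr += 1

            if n_target is None or n_run == n_target:
                break
            step = n_run - n_target
            if nc + step < 0:
                if nc == 0:
                    # Events tied exactly to the boundary are counted at
                    # risk in a real table but read as pre-boundary drops
                    # from a digitized curve; tolerate a deficit up to the
                    # boundary coordinate's own event count.
                    d_boundary = sum(
                        d for j, d in d_trial if t[j] == bounds[k + 1])
                    if n_target - n_run <= d_boundary:
                        break
                    raise InfeasibleInputError(
                        f"curve implies fewer than {n_target} at risk at "
                        f"t={starts[k + 1]:g} even with no censoring")
                nc = 0
            else:
                nc += step
        # Commit the interval.
        for j, d in d_trial:
            event_times.extend([float(t[j])] * d)
            if d > 0:
                last_event_coord = float(t[j])
        censor_times.extend(cens_trial)
        km_prev = km_run
        n_now = n_run

    # Patients still at risk at the end of the curve: administrative censoring.
    tail_censor = float(t[-1])
    censor_times.extend([tail_censor] * n_now)

    # Optional rebalancing toward a known total event count.
    if total_events is not None and last_event_coord is not None:
        diff = len(event_times) - int(total_events)
        if diff > 0:
            # Convert the latest events back to censorings at the same times.
            for _ in range(min(diff, len(event_times))):
                censor_times.append(event_times.pop())
        elif diff < 0:
            # Promote tail censorings to events at the last event time.
            promotable = [i for i, c in enumerate(censor_times) if c >= last_event_coord]
            for i in promotable[: -diff]:
                censor_times[i] = -1.0  # mark
                event_times.append(last_event_coord)
            censor_times = [c for c in censor_times if c >= 0]

    times = np.concatenate([np.asarray(event_times), np.asarray(censor_times)])
    events = np.concatenate([
        np.ones(len(event_times), dtype=int),
        np.zeros(len(censor_times), dtype=int),
    ])
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    # KM requires strictly positive times; digitized origins can sit at 0.
    times = np.maximum(times, 1e-9)
    ipd = IPDSample(times, events, arm_label=arm_label, endpoint=endpoint)
    deviation = _km_sup_deviation(curve, ipd)
    return ReconstructionResult(
        ipd=ipd,
        n_events_assigned=int(events.sum()),
        n_censored_assigned=int((1 - events).sum()),
        max_km_deviation=deviation,
    )


def validate_reconstruction(original: DigitizedCurve, result: ReconstructionResult) -> float:
    """Sup-norm distance between the source curve and the reconstruction's KM."""
    return _km_sup_deviation(original, result.ipd)
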