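"""Kaplan-Meier DFS/OS estimation with the cohort-exclusion rule.

Patients whose deaths were unrelated to treatment are removed entirely
before estimation (not censored), matching the study's analysis set.
Curves are product-limit estimates; ``rate_at`` evaluates the step
function right-continuously, so a query at an event time returns the
post-event value. Group comparisons report 1- and 2-year DFS/OS rates
per group; no log-rank testing is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from irhpc.cohort_model import PatientRecord


@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival estimate.

    ``times`` are the distinct observed times (events and censorings);
    ``survival`` is S(t) just after each time; ``at_risk`` and
    ``events`` count subjects at risk and events at each time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    n_start: int


def km_fit(times, events) -> KmCurve:
    """Fit the Kaplan-Meier estimator (event = 1, censored = 0).

    Ties of events and censorings at the same time are handled
    events-first, the standard product-limit convention.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("no subjects")
    if (t < 0).any():
        raise ValueError("times must be >= 0")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tbl = kmf.event_table
    grid = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy(dtype=float)
    keep = grid > 0  # lifelines prepends t=0; S starts at 1 by construction
    return KmCurve(times=grid[keep], survival=surv[keep],
                   at_risk=tbl["at_risk"].to_numpy(dtype=int)[keep],
                   events=tbl["observed"].to_numpy(dtype=int)[keep],
                   n_start=int(t.size))


def rate_at(curve: KmCurve, t: float) -> float:
    """S(t) of the fitted step function (right-continuous).

    Queries beyond the last observed time return the final value with
    an extrapolation warning.
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    if curve.times.size and t > curve.times[-1]:
        warnings.warn(f"t={t} beyond last observed time {curve.times[-1]}; "
                      "returning the final estimate (extrapolation)", stacklevel=2)
    idx = np.searchsorted(curve.times, t, side="right")
    return 1.0 if idx == 0 else float(curve.survival[idx - 1])


def filter_survival_cohort(records: list[PatientRecord]
                           ) -> tuple[list[PatientRecord], list[str]]:
    """Drop patients flagged as treatment-unrelated deaths.

    Returns the analysis subset (records untouched) and the excluded
    case ids.
    """
    kept, excluded = [], []
    for rec in records:
        s = rec.survival
        if s is not None and s.os_event == 1 and s.death_unrelated_to_treatment == 1:
            excluded.append(rec.case_id)
        else:
            kept.append(rec)
    if not kept:
        warnings.warn("all patients excluded from the survival analysis", stacklevel=2)
    return kept, excluded


@dataclass(frozen=True)
class GroupSurvival:
    group: str
    n: int
    dfs: KmCurve
    os: KmCurve
    dfs_1yr: float
    dfs_2yr: float
    os_1yr: float
    os_2yr: float


def km_by_group(records: list[PatientRecord], groups: dict[str, str]
                ) -> dict[str, GroupSurvival]:
    """Per-group DFS/OS curves with 1- and 2-year rates.

    ``groups`` maps case_id to a group label and must cover every
    analysed patient with a survival record; empty groups are simply
    absent from the result.
    """
    by_label: dict[str, list[PatientRecord]] = {}
    for rec in records:
        if rec.survival is None:
            continue
        if rec.case_id not in groups:
            raise ValueError(f"no group assignment for case {rec.case_id}")
        by_label.setdefault(groups[rec.case_id], []).append(rec)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for label, recs in sorted(by_label.items()):
            dfs = km_fit([r.survival.dfs_time for r in recs],
                         [r.survival.dfs_event for r in recs])
            osc = km_fit([r.survival.os_time for r in recs],
                         [r.survival.os_event for r in recs])
            out[label] = GroupSurvival(
                group=label, n=len(recs), dfs=dfs, os=osc,
                dfs_1yr=rate_at(dfs, 12), dfs_2yr=rate_at(dfs, 24),
                os_1yr=rate_at(osc, 12), os_2yr=rate_at(osc, 24))
    return out


def median_followup(times) -> tuple[float, tuple[float, float]]:
    """Simple median of observed follow-up times with the (min, max)
    range; the even-n median is the mean of the central pair."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("no follow-up times")
    return float(np.median(t)), (float(t.min()), float(t.max()))
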