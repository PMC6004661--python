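"""Time-to-onset analysis of adverse-event reports.

For every report exposed to the target drug, the event time is the number of
days from the (earliest) administration start date to the onset date of the
target event; for non-cases — or cases stopped by another adverse event —
the time runs to the end of drug use and the observation is censored.  Times
beyond one year are administratively censored at 365 days, and non-positive
date differences are clamped to day 1 (the product-limit estimator needs
positive times).  Reports lacking the required dates are excluded and
tallied rather than silently dropped.

Kaplan-Meier estimation and the two-group log-rank test are delegated to
lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .reports import DrugClassDef, PTSet, ReportRecord, ReportSet, classify_case, is_exposed

MAX_DAYS = 365


@dataclass(frozen=True)
class SurvivalRecord:
    case_id: str
    group: str
    time: int  # days, in [1, MAX_DAYS]
    event: bool  # True = target-event onset, False = censored

    def __post_init__(self) -> None:
        if not 1 <= self.time <= MAX_DAYS:
            raise ValueError(f"time must lie in [1, {MAX_DAYS}], got {self.time}")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate as a step-function table."""

    times: np.ndarray  # ordered distinct observed times
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray
    events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "at_risk": self.at_risk,
            "events": self.events,
            "survival": self.survival,
        })


@dataclass(frozen=True)
class LogRankResult:
    statistic: float  # 1-d.f. chi-square
    p_value: float


def _clamp(days: int) -> tuple[int, bool]:
    """Apply the 365-day administrative cap; returns (time, capped)."""
    if days > MAX_DAYS:
        return MAX_DAYS, True
    return max(days, 1), False


def derive_time(
    report: ReportRecord,
    target: DrugClassDef | str,
    pts: PTSet,
    group: str | None = None,
    include_concomitant: bool = False,
) -> SurvivalRecord | None:
    """Per-report event time under the reporting-database censoring rules.

    Returns None when the report is not exposed to the target or lacks the
    dates the rule needs (callers tally these exclusions).
    """
    if not is_exposed(report, target, include_concomitant=include_concomitant):
        return None
    label = group or (target.class_name if isinstance(target, DrugClassDef) else target)
    if isinstance(target, DrugClassDef):
        members = target.members
    else:
        from .reports import normalize_drug_name

        members = frozenset({normalize_drug_name(target)})
    roles = ("suspect", "concomitant") if include_concomitant else ("suspect",)
    entries = [d for d in report.drugs if d.drug_name in members and d.role in roles]

    starts = [d.start_date for d in entries if d.start_date is not None]
    if not starts:
        return None
    start = min(starts)  # exposure begins at first administration

    if classify_case(report, pts):
        onsets = [
            e.onset_date for e in report.events
            if e.pt_id in pts.pt_ids and e.onset_date is not None
        ]
        if not onsets:
            return None
        days = (min(onsets) - start).days
        time, capped = _clamp(days)
        return SurvivalRecord(report.case_id, label, time, event=not capped)

    ends = [d.end_date for d in entries if d.end_date is not None]
    if not ends:
        return None
    days = (max(ends) - start).days
    time, _ = _clamp(days)
    return SurvivalRecord(report.case_id, label, time, event=False)


def survival_records(
    reports: ReportSet,
    target: DrugClassDef | str,
    pts: PTSet,
    group: str | None = None,
    include_concomitant: bool = False,
) -> tuple[list[SurvivalRecord], int]:
    """Derive times for every exposed report; returns (records, n_excluded).

    ``n_excluded`` counts exposed reports dropped for missing dates.
    """
    records: list[SurvivalRecord] = []
    excluded = 0
    for r in reports:
        if not is_exposed(r, target, include_concomitant=include_concomitant):
            continue
        rec = derive_time(r, target, pts, group=group, include_concomitant=include_concomitant)
        if rec is None:
            excluded += 1
        else:
            records.append(rec)
    return records, excluded


def km_curve(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit curve over the distinct observed times.

    Ties are handled in the standard way: events at a time are processed
    before censorings at the same time.
    """
    if not records:
        raise ValueError("cannot estimate a survival curve from zero records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    # event_table carries a t=0 anchor row with no observations; drop it
    table = kmf.event_table[kmf.event_table.index > 0]
    obs_times = table.index.to_numpy()
    surv = kmf.survival_function_at_times(obs_times).to_numpy()
    return KMCurve(
        times=obs_times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(),
        events=table["observed"].to_numpy(),
    )


def logrank(
    group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]
) -> LogRankResult:
    """Two-group log-rank test (1-d.f. chi-square)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in group_a + group_b):
        raise ValueError("log-rank test requires at least one event")
    res = logrank_test(
        [r.time for r in group_a], [r.time for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    return LogRankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))
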