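"""The four electronic-monitoring adherence statistics.

For a prescription of ``d`` doses/day over a period of ``D`` calendar days:

* **dose-taking adherence** — pills taken / pills prescribed × 100,
  capped at 100 (extra unscheduled pills cannot push it above the
  ceiling);
* **dose-frequency adherence** — days of *correct daily dosing* / D × 100,
  where a day is correct iff the number of intakes equals ``d`` and every
  intake has the prescribed pill count (timing is deliberately not part
  of this metric — timing lives in dose-interval adherence);
* **dose-interval adherence** — days with a *correct dosing interval* /
  D × 100. A correct interval lies within the target interval ± margin
  (9–15 h for a 12 h target at ±25 %). For a twice-daily schedule the
  one countable interval per day is first intake → second intake of that
  calendar day, so a perfect patient scores 100; the overnight interval
  is excluded (see :func:`overnight_intervals` for the diagnostic);
* **drug holidays** — days with no intake at all / D × 100.

All metrics use calendar days of the local clock and half-open periods
``[start, start + days)``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .events_io import (
    DAYS_PER_PERIOD,
    N_VISITS,
    IntakeEvent,
    PatientRecord,
    PrescriptionSchedule,
    ValidationError,
)

__all__ = [
    "AdherencePeriodSummary",
    "allowed_interval_bounds",
    "dose_taking_adherence",
    "dose_frequency_adherence",
    "dose_interval_adherence",
    "drug_holidays",
    "overnight_intervals",
    "summarize_period",
    "summarize_patient",
    "cohort_period_metrics",
    "METRIC_NAMES",
]

METRIC_NAMES = ("dose_taking", "dose_frequency", "dose_interval", "drug_holidays")


@dataclass(frozen=True)
class AdherencePeriodSummary:
    """The four adherence percentages for one patient × follow-up period."""

    patient_id: str
    period_index: int
    dose_taking: float
    dose_frequency: float
    dose_interval: float
    drug_holidays: float

    def __post_init__(self) -> None:
        for name in METRIC_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} = {v} outside [0, 100]")


def allowed_interval_bounds(schedule: PrescriptionSchedule) -> tuple[float, float]:
    """Allowed dosing-interval range in hours: target × (1 ∓ margin).

    A 12 h target with a ±25 % margin gives (9.0, 15.0).
    """
    return (
        schedule.target_interval_h * (1.0 - schedule.interval_margin),
        schedule.target_interval_h * (1.0 + schedule.interval_margin),
    )


def _in_period(
    events: Sequence[IntakeEvent], start: dt.date, days: int
) -> list[IntakeEvent]:
    if days < 1:
        raise ValidationError("period must cover at least one day")
    end = start + dt.timedelta(days=days)
    return [e for e in events if start <= e.timestamp.date() < end]


def _by_day(
    events: Sequence[IntakeEvent], start: dt.date, days: int
) -> dict[int, list[IntakeEvent]]:
    out: dict[int, list[IntakeEvent]] = {}
    for e in _in_period(events, start, days):
        out.setdefault((e.timestamp.date() - start).days, []).append(e)
    for evs in out.values():
        evs.sort(key=lambda e: (e.timestamp, e.order))
    return out


def dose_taking_adherence(
    events: Sequence[IntakeEvent],
    schedule: PrescriptionSchedule,
    start: dt.date,
    days: int,
) -> float:
    """Pills taken over pills prescribed, × 100, capped at 100."""
    prescribed = days * schedule.doses_per_day * schedule.pills_per_dose
    if prescribed == 0:
        raise ValidationError("no pills prescribed in period")
    taken = sum(e.pills_taken for e in _in_period(events, start, days))
    return min(100.0, 100.0 * taken / prescribed)


def dose_frequency_adherence(
    events: Sequence[IntakeEvent],
    schedule: PrescriptionSchedule,
    start: dt.date,
    days: int,
) -> float:
    """Days of correct daily dosing over days in the period, × 100."""
    by_day = _by_day(events, start, days)
    correct = sum(
        1
        for evs in by_day.values()
        if len(evs) == schedule.doses_per_day
        and all(e.pills_taken == schedule.pills_per_dose for e in evs)
    )
    return 100.0 * correct / days


def dose_interval_adherence(
    events: Sequence[IntakeEvent],
    schedule: PrescriptionSchedule,
    start: dt.date,
    days: int,
) -> float:
    """Days whose first→second intake interval lies in the allowed range, × 100.

    Days with fewer than two intakes contribute no correct interval.
    Bounds are inclusive: a 9 h or 15 h interval under the default
    schedule counts as correct.
    """
    low, high = allowed_interval_bounds(schedule)
    by_day = _by_day(events, start, days)
    correct = 0
    for evs in by_day.values():
        if len(evs) >= 2:
            iv = (evs[1].timestamp - evs[0].timestamp).total_seconds() / 3600.0
            if low <= iv <= high:
                correct += 1
    return 100.0 * correct / days


def drug_holidays(
    events: Sequence[IntakeEvent],
    schedule: PrescriptionSchedule,
    start: dt.date,
    days: int,
) -> float:
    """Days without any medication intake over days in the period, × 100."""
    by_day = _by_day(events, start, days)
    return 100.0 * (days - len(by_day)) / days


def overnight_intervals(
    events: Sequence[IntakeEvent], start: dt.date, days: int
) -> list[float]:
    """Diagnostic: hours from each day's last intake to the next day's first."""
    by_day = _by_day(events, start, days)
    out = []
    for d in range(days - 1):
        if d in by_day and d + 1 in by_day:
            gap = by_day[d + 1][0].timestamp - by_day[d][-1].timestamp
            out.append(gap.total_seconds() / 3600.0)
    return out


def summarize_period(record: PatientRecord, period_index: int) -> AdherencePeriodSummary:
    """All four metrics over one half-open 4-week follow-up window."""
    start, _end = record.period_range(period_index)  # validates 1..6
    args = (record.events, record.schedule, start, DAYS_PER_PERIOD)
    return AdherencePeriodSummary(
        patient_id=record.patient_id,
        period_index=period_index,
        dose_taking=dose_taking_adherence(*args),
        dose_frequency=dose_frequency_adherence(*args),
        dose_interval=dose_interval_adherence(*args),
        drug_holidays=drug_holidays(*args),
    )


def summarize_patient(record: PatientRecord) -> list[AdherencePeriodSummary]:
    return [summarize_period(record, k) for k in range(1, N_VISITS + 1)]


# ---------------------------------------------------------------------------
# Vectorized cohort path
# ---------------------------------------------------------------------------


def cohort_period_metrics(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    schedule: PrescriptionSchedule,
    n_periods: int = N_VISITS,
) -> pd.DataFrame:
    """Per patient × period metric table for a whole cohort, vectorized.

    ``events`` needs columns ``patient_id, timestamp, pills_taken``
    (timestamp as datetime64); ``cohort`` needs ``patient_id, start_date``.
    Returns a long DataFrame with columns ``patient_id, period`` and the
    four metric columns, covering periods ``1..n_periods`` of
    ``DAYS_PER_PERIOD`` days for every patient (rows for event-free
    periods are included: 0 % adherence, 100 % holidays).
    """
    low, high = allowed_interval_bounds(schedule)
    dpp = DAYS_PER_PERIOD
    per_day_pills = schedule.doses_per_day * schedule.pills_per_dose
    start_map = dict(zip(cohort["patient_id"], pd.to_datetime(cohort["start_date"])))

    df = events.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    starts = df["patient_id"].map(start_map)
    df["day"] = (df["timestamp"].dt.normalize() - starts).dt.days
    df = df[(df["day"] >= 0) & (df["day"] < dpp * n_periods)]
    df = df.sort_values(["patient_id", "timestamp"], kind="stable")

    grid = pd.MultiIndex.from_product(
        [cohort["patient_id"], range(1, n_periods + 1)], names=["patient_id", "period"]
    )
    if df.empty:
        out = pd.DataFrame(index=grid).reset_index()
        out["dose_taking"] = 0.0
        out["dose_frequency"] = 0.0
        out["dose_interval"] = 0.0
        out["drug_holidays"] = 100.0
        return out

    df["bad"] = df["pills_taken"] != schedule.pills_per_dose
    df["k"] = df.groupby(["patient_id", "day"]).cumcount()
    g = df.groupby(["patient_id", "day"], sort=True)
    day_tab = g.agg(
        n=("pills_taken", "size"),
        pills=("pills_taken", "sum"),
        bad_pills=("bad", "any"),
    ).reset_index()
    # first->second intake interval within the calendar day, in hours
    keys = ["patient_id", "day"]
    firsts = df.loc[df["k"] == 0, keys + ["timestamp"]].rename(columns={"timestamp": "first_ts"})
    seconds = df.loc[df["k"] == 1, keys + ["timestamp"]].rename(columns={"timestamp": "second_ts"})
    day_tab = day_tab.merge(firsts, on=keys, how="left").merge(seconds, on=keys, how="left")
    iv_h = (day_tab["second_ts"] - day_tab["first_ts"]).dt.total_seconds() / 3600.0
    day_tab["interval_ok"] = iv_h.between(low, high).fillna(False)
    day_tab["freq_ok"] = (day_tab["n"] == schedule.doses_per_day) & ~day_tab["bad_pills"]
    day_tab["period"] = day_tab["day"] // dpp + 1

    per = day_tab.groupby(["patient_id", "period"]).agg(
        pills=("pills", "sum"),
        days_with_intake=("day", "size"),
        correct_days=("freq_ok", "sum"),
        correct_intervals=("interval_ok", "sum"),
    )
    per = per.reindex(grid, fill_value=0).reset_index()
    prescribed = dpp * per_day_pills
    per["dose_taking"] = np.minimum(100.0, 100.0 * per["pills"] / prescribed)
    per["dose_frequency"] = 100.0 * per["correct_days"] / dpp
    per["dose_interval"] = 100.0 * per["correct_intervals"] / dpp
    per["drug_holidays"] = 100.0 * (dpp - per["days_with_intake"]) / dpp
    return per[["patient_id", "period", *METRIC_NAMES]]
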