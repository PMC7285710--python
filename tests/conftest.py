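import datetime as dt

import numpy as np
import pytest

from adhermon import IntakeEvent, PrescriptionSchedule

START = dt.date(2020, 1, 6)  # a Monday


@pytest.fixture
def schedule() -> PrescriptionSchedule:
    return PrescriptionSchedule()


def ev(day: int, hh: int, mm: int = 0, pills: int = 1, pid: str = "P1",
       order: int = 0, start: dt.date = START) -> IntakeEvent:
    """Shorthand intake event on study day ``day`` at hh:mm."""
    ts = dt.datetime.combine(start + dt.timedelta(days=day), dt.time(hh, mm))
    return IntakeEvent(pid, ts, pills, order=order)


def perfect_log(days: int, schedule: PrescriptionSchedule | None = None,
                pid: str = "P1", start: dt.date = START) -> list[IntakeEvent]:
    """Every dose taken exactly on schedule with the right pill count."""
    schedule = schedule or PrescriptionSchedule()
    return [
        IntakeEvent(pid, ts, schedule.pills_per_dose, order=i)
        for i, ts in enumerate(schedule.slot_times(start, days))
    ]


def random_log(rng: np.random.Generator, max_days: int = 14,
               pid: str = "P1", start: dt.date = START):
    """A random minute-resolution event log for oracle-equivalence checks.

    Mixes realistic near-schedule intakes (jittered around 08:00/20:00,
    occasionally far outside the window, occasionally wrong pill count)
    with uniformly random openings and empty days, so matching, window
    classification and the per-day metrics all get exercised.
    """
    days = int(rng.integers(1, max_days + 1))
    events = []
    order = 0
    for d in range(days):
        for base_hh in (8, 20):
            r = rng.random()
            if r < 0.15:
                continue  # forgotten dose
            if r < 0.85:  # near-schedule intake with jitter (sometimes huge)
                jitter = int(rng.normal(0, 60 if rng.random() < 0.8 else 240))
                jitter = max(-5 * 60, min(5 * 60, jitter))
                ts = dt.datetime.combine(
                    start + dt.timedelta(days=d), dt.time(base_hh, 0)
                ) + dt.timedelta(minutes=jitter)
            else:  # unscheduled opening at a uniform minute
                ts = dt.datetime.combine(
                    start + dt.timedelta(days=d), dt.time(0, 0)
                ) + dt.timedelta(minutes=int(rng.integers(0, 24 * 60)))
            pills = 1 if rng.random() < 0.9 else int(rng.integers(2, 4))
            order += 1
            events.append(IntakeEvent(pid, ts, pills, order=order))
    events.sort(key=lambda e: (e.timestamp, e.order))
    return events, days
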