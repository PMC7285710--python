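"""Independent brute-force oracles for the metrics and the alarm engine.

Everything here is deliberately written from the definitions, using only
plain Python datetimes and dictionaries, so the package implementation
(pandas/vectorized, arithmetic alarm placement) can be checked against an
unrelated code path: metrics by exhaustive day-by-day recount, feedback
by a minute-resolution discrete-event replay of the timeline.
"""

from __future__ import annotations

import datetime as dt


def metrics_recount(events, schedule, start, days):
    """Exhaustive day-by-day recount of the four adherence percentages."""
    end = start + dt.timedelta(days=days)
    per_day = {start + dt.timedelta(days=d): [] for d in range(days)}
    for e in sorted(events, key=lambda e: (e.timestamp, e.order)):
        d = e.timestamp.date()
        if start <= d < end:
            per_day[d].append(e)

    prescribed = days * len(schedule.dose_times) * schedule.pills_per_dose
    taken = sum(e.pills_taken for evs in per_day.values() for e in evs)

    correct_days = 0
    correct_intervals = 0
    holidays = 0
    lo = schedule.target_interval_h * (1 - schedule.interval_margin)
    hi = schedule.target_interval_h * (1 + schedule.interval_margin)
    for evs in per_day.values():
        if not evs:
            holidays += 1
        if len(evs) == len(schedule.dose_times) and all(
            e.pills_taken == schedule.pills_per_dose for e in evs
        ):
            correct_days += 1
        if len(evs) >= 2:
            iv = (evs[1].timestamp - evs[0].timestamp).total_seconds() / 3600.0
            if lo <= iv <= hi:
                correct_intervals += 1
    return {
        "dose_taking": min(100.0, 100.0 * taken / prescribed),
        "dose_frequency": 100.0 * correct_days / days,
        "dose_interval": 100.0 * correct_intervals / days,
        "drug_holidays": 100.0 * holidays / days,
    }


def greedy_match(events, schedule, start, days):
    """Reference matcher: slots in time order, nearest unmatched event
    within +/- half the target interval, equidistant ties to the earlier
    event. Returns {slot_index: (scheduled, event or None)}."""
    slot_times = [
        dt.datetime.combine(start + dt.timedelta(days=d), t)
        for d in range(days)
        for t in schedule.dose_times
    ]
    pool = sorted(events, key=lambda e: (e.timestamp, e.order))
    half = dt.timedelta(hours=schedule.target_interval_h / 2)
    used = [False] * len(pool)
    out = {}
    for idx, sched in enumerate(slot_times):
        best = None
        for j, e in enumerate(pool):
            if used[j] or abs(e.timestamp - sched) > half:
                continue
            if best is None or abs(e.timestamp - sched) < abs(pool[best].timestamp - sched):
                best = j
        if best is not None:
            used[best] = True
            out[idx] = (sched, pool[best])
        else:
            out[idx] = (sched, None)
    return out


def minute_replay_feedback(events, schedule, start, days):
    """Minute-resolution replay of the alarm timeline.

    Walks the clock one minute at a time and emits
    (kind, minute, escalation_index, slot_index) whenever the monitoring
    rules say a text goes out. Event timestamps must lie on whole
    minutes. Returns the stream sorted like the engine output.
    """
    assert all(e.timestamp.second == 0 and e.timestamp.microsecond == 0 for e in events)
    matches = greedy_match(events, schedule, start, days)
    window = dt.timedelta(hours=schedule.window_h)
    gap = dt.timedelta(minutes=schedule.escalation_gap_min)
    latency = dt.timedelta(minutes=schedule.alarm_latency_min)
    minute = dt.timedelta(minutes=1)
    out = []
    for idx, (sched, ev) in matches.items():
        taken_at = ev.timestamp if ev is not None else None
        first = sched + window + latency
        last = first + schedule.max_escalations * gap
        # walk the alarm span one minute at a time, asking at each instant
        # "is an alarm due now, and is the dose still untaken?"
        t, sent = first, 0
        while t <= last:
            due = (t - first) == sent * gap
            if due:
                if taken_at is not None and taken_at <= t:
                    break  # dose is in hand at this instant: chain stops
                out.append(("missed_dose", t, sent, idx))
                sent += 1
            t += minute
        # violation texts at the intake instant
        if taken_at is not None:
            if abs(taken_at - sched) > window:
                out.append(("timing_error", taken_at, 0, idx))
            elif ev.pills_taken != schedule.pills_per_dose:
                out.append(("dosage_error", taken_at, 0, idx))
    out.sort(key=lambda f: (f[1], f[3], f[2]))
    return out
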