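"""Match intake events to scheduled dose slots and generate alarm feedback.

The monitoring system watches each scheduled dose. When the allowed ±window
around a scheduled time passes without an intake ("window break"), a
missed-dose text fires immediately, followed by up to ``max_escalations``
further texts at ``escalation_gap`` intervals while the dose remains
untaken. A dose taken inside the window with the wrong pill count triggers
a dosage-error text at the intake instant; a dose taken outside the window
triggers a dosing-time-error text at the intake instant (timing takes
precedence over pill count — one text per violation).

Matching rule: slots are processed in chronological order; a slot's
candidate intake is the not-yet-matched event nearest its scheduled time
within ±(target_interval / 2), so matching is unambiguous for twice-daily
schedules. Ties (equidistant before/after) go to the earlier event.
"""

from __future__ import annotations

import datetime as dt
from typing import Sequence

from .events_io import (
    DoseSlot,
    FeedbackEvent,
    IntakeEvent,
    PrescriptionSchedule,
)

__all__ = [
    "match_intakes_to_slots",
    "generate_feedback",
    "count_feedback_by_kind",
    "feedback_for_patient",
]


def match_intakes_to_slots(
    events: Sequence[IntakeEvent],
    schedule: PrescriptionSchedule,
    start: dt.date,
    days: int,
) -> tuple[list[DoseSlot], list[IntakeEvent]]:
    """Assign intake events to scheduled dose slots over ``days`` days.

    Returns one :class:`DoseSlot` per scheduled dose in the half-open
    period ``[start, start + days)`` plus the leftover events that matched
    no slot (unscheduled intakes). Each event is matched to at most one
    slot. Slot status:

    * ``taken_ok`` — matched intake inside [scheduled − window,
      scheduled + window] with the prescribed pill count;
    * ``taken_dosage_error`` — in-window but wrong pill count;
    * ``taken_out_of_window`` — matched intake outside the window;
    * ``missed`` — no matched intake.
    """
    if days < 1:
        raise ValueError("period must cover at least one day")
    half = dt.timedelta(hours=schedule.target_interval_h / 2.0)
    window = schedule.window
    slot_times = schedule.slot_times(start, days)
    ordered = sorted(events, key=lambda e: (e.timestamp, e.order))
    pid = ordered[0].patient_id if ordered else ""
    matched: set[int] = set()
    slots: list[DoseSlot] = []
    lo = 0  # events before slot_time - half can match no later slot either
    for idx, sched in enumerate(slot_times):
        while lo < len(ordered) and ordered[lo].timestamp < sched - half:
            lo += 1
        best: tuple[dt.timedelta, int] | None = None
        j = lo
        while j < len(ordered) and ordered[j].timestamp <= sched + half:
            if j not in matched:
                dist = abs(ordered[j].timestamp - sched)
                # nearest wins; equidistant -> earlier event (lower sort position)
                if best is None or dist < best[0]:
                    best = (dist, j)
            j += 1
        if best is None:
            slots.append(DoseSlot(pid, sched, idx))
            continue
        matched.add(best[1])
        ev = ordered[best[1]]
        if abs(ev.timestamp - sched) <= window:
            status = (
                "taken_ok"
                if ev.pills_taken == schedule.pills_per_dose
                else "taken_dosage_error"
            )
        else:
            status = "taken_out_of_window"
        slots.append(DoseSlot(ev.patient_id, sched, idx, status, ev))
    unscheduled = [ev for j, ev in enumerate(ordered) if j not in matched]
    return slots, unscheduled


def generate_feedback(
    slots: Sequence[DoseSlot],
    schedule: PrescriptionSchedule,
) -> list[FeedbackEvent]:
    """Generate the alarm/text stream for resolved dose slots.

    For a slot still untaken at its window break, a ``missed_dose`` alarm
    fires at ``scheduled + window + latency`` (escalation index 0) and
    again after each ``escalation_gap`` while the dose remains untaken, up
    to ``max_escalations`` extra texts. An alarm fires only if the matched
    intake (if any) is strictly later than the alarm instant; the chain
    stops as soon as the dose is taken. A late intake still earns its
    ``timing_error`` text — the violation factually occurred.
    """
    latency = dt.timedelta(minutes=schedule.alarm_latency_min)
    gap = schedule.escalation_gap
    out: list[FeedbackEvent] = []
    for slot in slots:
        ev = slot.matched_event
        taken_at = ev.timestamp if ev is not None else None
        if taken_at is None or taken_at > slot.scheduled + schedule.window:
            first = slot.scheduled + schedule.window + latency
            for k in range(schedule.max_escalations + 1):
                alarm_at = first + k * gap
                if taken_at is not None and taken_at <= alarm_at:
                    break
                out.append(
                    FeedbackEvent(slot.patient_id, alarm_at, "missed_dose", k, slot.slot_index)
                )
        if slot.status == "taken_dosage_error":
            out.append(
                FeedbackEvent(slot.patient_id, ev.timestamp, "dosage_error", 0, slot.slot_index)
            )
        elif slot.status == "taken_out_of_window":
            out.append(
                FeedbackEvent(slot.patient_id, ev.timestamp, "timing_error", 0, slot.slot_index)
            )
    out.sort(key=lambda f: (f.timestamp, f.slot_index, f.escalation_index))
    return out


def count_feedback_by_kind(
    feedback: Sequence[FeedbackEvent], dedupe: bool = True
) -> dict[str, int]:
    """Count feedback messages by kind.

    With ``dedupe`` on (the reporting convention), the escalation chain of
    one missed slot counts as a single missed-dose feedback occurrence;
    with it off, raw message counts are returned.
    """
    counts: dict[str, int] = {}
    seen_slots: set[tuple[str, int]] = set()
    for f in feedback:
        if dedupe and f.kind == "missed_dose":
            key = (f.patient_id, f.slot_index)
            if key in seen_slots:
                continue
            seen_slots.add(key)
        counts[f.kind] = counts.get(f.kind, 0) + 1
    return counts


def feedback_for_patient(
    events: Sequence[IntakeEvent],
    schedule: PrescriptionSchedule,
    start: dt.date,
    days: int,
) -> list[FeedbackEvent]:
    """Convenience: match then generate feedback for one patient's log."""
    slots, _ = match_intakes_to_slots(events, schedule, start, days)
    return generate_feedback(slots, schedule)
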