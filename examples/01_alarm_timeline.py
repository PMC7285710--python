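"""Walk through one day of the missed-dose alarm logic.

A patient on the default twice-daily schedule (08:00/20:00, ±3 h window)
skips the morning dose until 11:40 and takes the evening dose on time.
The engine fires the first alarm at the window break (11:00), escalates
once at 11:30, then the late intake at 11:40 cancels the final
escalation and earns a dosing-time-error text instead.
"""

import datetime as dt

from adhermon import (
    IntakeEvent,
    PrescriptionSchedule,
    count_feedback_by_kind,
    generate_feedback,
    match_intakes_to_slots,
)

start = dt.date(2020, 1, 6)
schedule = PrescriptionSchedule()
events = [
    IntakeEvent("P1", dt.datetime(2020, 1, 6, 11, 40), 1, order=1),
    IntakeEvent("P1", dt.datetime(2020, 1, 6, 20, 2), 1, order=2),
]

slots, unscheduled = match_intakes_to_slots(events, schedule, start, days=1)
for slot in slots:
    print(f"slot {slot.slot_index} scheduled {slot.scheduled:%H:%M}: {slot.status}")

feedback = generate_feedback(slots, schedule)
print("\nalarm/text stream:")
for f in feedback:
    print(f"  {f.timestamp:%H:%M} {f.kind} (escalation {f.escalation_index})")

print("\ncounts (escalations of one slot deduplicated):",
      count_feedback_by_kind(feedback, dedupe=True))
print("counts (raw messages):", count_feedback_by_kind(feedback, dedupe=False))
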