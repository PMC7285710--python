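"""Compute the four adherence metrics for a hand-built one-week log.

The patient takes every dose except one evening dose, and spaces one
day's doses only 8 hours apart (below the 9–15 h allowed interval).
Dose-taking counts pills (13/14), dose-frequency counts complete days
(6/7), dose-interval counts days with a correctly spaced pair (5/7:
one day lacks a second intake, another is spaced 8 h), and drug
holidays counts empty days (0/7).
"""

import datetime as dt

from adhermon import (
    IntakeEvent,
    PrescriptionSchedule,
    dose_frequency_adherence,
    dose_interval_adherence,
    dose_taking_adherence,
    drug_holidays,
)

start = dt.date(2020, 1, 6)
schedule = PrescriptionSchedule()

events = []
for day in range(7):
    d = start + dt.timedelta(days=day)
    if day == 2:  # evening dose skipped entirely
        events.append(IntakeEvent("P1", dt.datetime.combine(d, dt.time(8, 2)), 1))
        continue
    if day == 4:  # doses only 8 h apart: 08:00 and 16:00
        events.append(IntakeEvent("P1", dt.datetime.combine(d, dt.time(8, 0)), 1))
        events.append(IntakeEvent("P1", dt.datetime.combine(d, dt.time(16, 0)), 1))
        continue
    events.append(IntakeEvent("P1", dt.datetime.combine(d, dt.time(8, 1)), 1))
    events.append(IntakeEvent("P1", dt.datetime.combine(d, dt.time(20, 3)), 1))

for name, fn in [
    ("dose-taking   ", dose_taking_adherence),
    ("dose-frequency", dose_frequency_adherence),
    ("dose-interval ", dose_interval_adherence),
    ("drug holidays ", drug_holidays),
]:
    print(f"{name}: {fn(events, schedule, start, 7):6.2f} %")
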