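# Methods

This note records the model this package implements, the parameter
choices that matter, what the synthetic cohort does and does not emulate,
and the numerical/design decisions taken where more than one reading was
defensible.

## Dosing schedule and feedback algorithm

A prescription is a set of fixed daily clock times (default 08:00 and
20:00), a target between-dose interval τ (default 12 h), a pill count per
dose (default 1), an intake window of ±w hours around each scheduled time
(default 3), and an interval margin m (default 0.25). The allowed
between-dose interval is [τ(1−m), τ(1+m)] = [9, 15] h at the defaults;
both bounds are treated as inclusive.

The alarm engine resolves each scheduled dose ("slot") against the event
log and emits:

- **missed-dose texts** — the first at the window break (scheduled + w),
  then up to `max_escalations` (default 2) further texts at
  `escalation_gap` (default 30 min) intervals, each sent only if the dose
  is still untaken at that instant. An intake at exactly an alarm instant
  counts as taken: the alarm does not fire. Delivery latency is modeled
  as zero (a configurable `alarm_latency_min` exists, default 0): the
  "sent within 1 h" bound of a deployed system is an operational
  property, not algorithmic content.
- **dosage-error texts** — at the intake instant, for an in-window intake
  with the wrong pill count.
- **dosing-time-error texts** — at the intake instant, for an intake
  outside the window. A late intake that arrives mid-escalation both
  stops the remaining escalations and earns this text (the violation
  factually occurred). An out-of-window intake with a wrong pill count
  yields the timing text only: timing takes precedence, one text per
  violation.

**Matching rule.** The trial literature does not specify how openings map
to slots, so the package fixes one deterministic rule: slots are
processed chronologically; a slot's candidate is the not-yet-matched
event nearest its scheduled time within ±τ/2 (so candidacy regions of
adjacent slots of a twice-daily schedule do not overlap ambiguously);
equidistant ties go to the earlier event, and simultaneous openings keep
file order. Unmatched openings are reported as unscheduled intakes and,
by default, generate no feedback (the treatment of "overuse" alarms is
left configurable because no rule is defined for it).

**Counting convention.** For reporting, the escalation chain of one
missed slot is one feedback occurrence (`dedupe=True`); raw message
counts remain available.

## Adherence metrics

Over a period of D calendar days (periods are half-open 28-day windows
[visit_{k−1}, visit_k), six per trial) with d doses/day:

- **dose-taking** = pills taken / (D·d·pills_per_dose) × 100, capped at
  100 so unscheduled extra pills cannot push a percentage above its
  ceiling. Timing is deliberately irrelevant here — the formula counts
  pills.
- **dose-frequency** = days of correct daily dosing / D × 100, where a
  day is correct iff its intake count equals d and every intake has the
  prescribed pill count. In-window timing is *not* required: timing is
  measured by dose-interval adherence, keeping the four metrics
  non-redundant.
- **dose-interval** = days with a correct interval / D × 100. The
  denominator is days, so for a twice-daily schedule exactly one
  within-day interval (first→second intake of the calendar day) is
  countable per day, making 100 % attainable for a perfect patient. The
  overnight (evening→next morning) interval is excluded from the metric
  and surfaced separately by `overnight_intervals` as a diagnostic. This
  one-interval-per-day reading resolves an internal oddity of the
  published formula (intervals divided by days) and is an interpretive
  choice, not the only possible one.
- **drug holidays** = days with zero intakes / D × 100.

Days are calendar days of the local clock; timestamps are timezone-naive
local time (daylight-saving shifts and travel are out of scope). The same
metrics are applied to both arms; encoding the control arm's paper diary
in the same event-log format is an assumption — diaries may lack reliable
clock times, in which case control-arm dose-interval adherence would be
less trustworthy than the pill-box arm's.

## Trial statistics

- CV (%) = 100 × SD/mean of a patient's trough series, with the sample
  (n−1) SD: six visits are a sample, not a population.
- Continuous outcomes: two-sided pooled-variance Student t
  (`equal_var=False` switches to Welch). Trough outcomes summarize each
  patient as the mean over their six visits before comparing arms (a
  per-visit alternative would be a mixed model, which is out of scope).
- Event counts: Pearson chi-squared without continuity correction,
  replaced by Fisher's exact test whenever any expected cell is < 5; the
  method used is reported with every p-value.
- Paired before/after scores: paired t on differences; all-zero
  differences return p = 1, constant nonzero differences are rejected as
  degenerate rather than reported as infinitely significant.
- No multiplicity adjustment anywhere, mirroring standard trial reporting
  of each outcome at α = 0.05; report headers state this.
- Comparisons on subgroups smaller than two patients are flagged
  `not_computable` instead of raising, so a trial where nobody (or
  everybody) triggered feedback still produces a report.

## Synthetic cohort

The generator encodes the causal story the monitoring system assumes:
non-adherence is unintentional forgetfulness, so alarms can rescue doses
but nothing models intentional refusal.

Per slot: forget with probability `p_miss`; otherwise take at the
scheduled time plus Gaussian jitter (`timing_sd_min`, default 20 min)
truncated to the window, except a rare late tail (`p_late_tail`) lands
the intake 1 min–2 h past the window break. Taken doses carry a wrong
pill count with probability `p_dose_error`. In the intervention arm a
forgotten dose gets one rescue draw per alarm (`p_respond` each), the
response landing uniformly within the following 30-min gap; the control
arm has no alarms. Forgetting is independent across slots — no day-level
autocorrelation or weekend structure.

Trough levels per visit: mean × (1 − coupling × missed_pp) + N(0, sd),
floored at 0.05 (a log-normal toggle exists). Defaults: tacrolimus mean
5.2 ng/mL, sd 1.25 (within-patient CV ≈ 24 %); mycophenolic acid mean
2.7 μg/mL, sd 1.03 (CV ≈ 38 %); coupling 0.01 per percentage point of
missed pills. Clinical-event flags are arm-independent Bernoulli draws
(anti-HLA 10 %, BK viremia 2 %) — plumbing for the count comparisons, not
biology.

**Presets.** The default `"ceiling"` preset encodes the near-perfect
adherence regime of a stable transplant cohort: `p_miss = 0.001`,
`p_dose_error = 0.00035`, `p_late_tail = 0`, `p_respond = 0.04` per
alarm. These rates are calibrated so a 51-patient intervention arm over
24 weeks (17,136 slots) produces on the order of 17 missed-dose, 6
dosage-error and 2 timing-error feedback occurrences with all adherence
metrics above 98–99 % — the regime in which such a trial shows a ceiling
effect. `"low-adherence"` (`p_miss = 0.2`, `p_respond = 0.5`) exercises
the pipeline away from the ceiling, where alarms visibly raise
intervention-arm dose-taking.

**What the generator does not emulate**, hence what passing tests do not
show about real data: between-patient heterogeneity in mean trough level
(arm-level trough SDs are therefore smaller than a real cohort's, though
within-patient CVs are realistic); correlated lapses (holidays, travel);
diary-recording error in the control arm; intake ≠ ingestion (a box
opening is not a swallowed pill); dropout and missing visits.

**Determinism.** A master seed spawns one independent stream per patient
(`numpy` `SeedSequence` spawning), so the full pipeline — simulate →
feedback → metrics → analyze — is bit-for-bit reproducible, and the
written CSVs are byte-identical across runs with the same seed.

## Numerical and edge-case choices

- Interval bounds inclusive; window bounds inclusive
  ([scheduled − w, scheduled + w]).
- A slot's alarm chain stops at the first instant the matched intake
  exists (strict inequality: intake at the alarm instant suppresses it).
- Zero-pill rows, malformed timestamps and unknown columns are hard
  validation errors naming the offending line — no silent coercion.
- Zero-variance t-test inputs: equal means → t = 0, p = 1; unequal
  constant samples raise. In cohort comparisons the degenerate case is
  flagged per row (`method = "degenerate"`) rather than raised, because
  near-ceiling adherence data genuinely produce constant columns (e.g.
  drug holidays identically zero in both arms).
- Dose-taking capping happens at the period level (total pills), not per
  slot.

## Known limitations

- The within-day-interval reading of dose-interval adherence, and the
  diary-as-event-log assumption for the control arm, are interpretive
  (both flagged above).
- The feedback engine models recognition and delivery as instantaneous;
  deployed systems batch and delay.
- Statistical comparisons are per-outcome t/chi-squared tests, as in the
  emulated trial design; no longitudinal modeling of the six periods.
- At trial scale the familywise chance of at least one nominally
  significant adherence comparison across the 24 per-period tests is
  large by construction (≈ 1 − 0.95^18 for the ~18 non-degenerate tests),
  which is exactly why per-outcome testing without adjustment should be
  interpreted row-wise, not as a global null test; the acceptance script
  reports both the per-replicate and per-comparison non-rejection rates.
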