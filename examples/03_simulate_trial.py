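"""Simulate a trial-scale two-arm cohort and summarize adherence by period.

Generates 51 intervention and 54 control patients over 24 weeks with the
near-ceiling behavior preset, computes the per-patient × period metric
table, and prints arm means per 4-week period — the per-period adherence
summary a monitoring trial reports. Near the ceiling both arms should sit
above 98–99 % on every metric with essentially no drug holidays.
"""

from adhermon import cohort_period_metrics, simulate_cohort
from adhermon.adherence_metrics import METRIC_NAMES

data = simulate_cohort(master_seed=42)  # defaults: 51/54 patients, 168 days
print(f"{len(data.records)} patients, {len(data.events)} intake events")

table = cohort_period_metrics(data.events, data.cohort, data.schedule)
merged = table.merge(data.cohort[["patient_id", "arm"]], on="patient_id")
summary = merged.groupby(["arm", "period"])[list(METRIC_NAMES)].mean().round(2)
print("\nmean adherence (%) by arm and 4-week period:")
print(summary.to_string())
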