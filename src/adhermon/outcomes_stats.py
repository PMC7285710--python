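"""Secondary-outcome computations and arm-wise trial statistics.

Continuous outcomes (trough levels, their within-patient coefficient of
variation, adherence metrics) are compared between groups with the
two-sided pooled-variance Student t-test; 2×2 event counts with the
uncorrected Pearson chi-squared test, falling back to Fisher's exact test
whenever any expected cell is below 5. Within-group before/after scores
use the paired t-test. No multiplicity adjustment is applied; each
outcome is tested at α = 0.05 and the method used is reported per row.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .adherence_metrics import METRIC_NAMES
from .events_io import N_VISITS, PatientRecord, ValidationError

__all__ = [
    "TrialResult",
    "coefficient_of_variation",
    "two_sample_t",
    "paired_t",
    "count_comparison",
    "compare_groups",
    "feedback_subgroup_analysis",
    "DRUGS",
]

DRUGS = ("tacrolimus", "mycophenolic_acid")


def coefficient_of_variation(levels: Sequence[float]) -> float:
    """Within-patient variability: 100 × sample SD / mean of trough levels.

    Uses the n−1 (sample) standard deviation. Requires at least two
    levels and a positive mean.
    """
    x = np.asarray(levels, dtype=float)
    if x.size < 2:
        raise ValidationError("CV needs at least two trough levels")
    m = x.mean()
    if m <= 0:
        raise ValidationError("CV undefined for nonpositive mean level")
    return 100.0 * x.std(ddof=1) / m


def two_sample_t(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided independent-samples Student t-test (pooled variance).

    ``equal_var=False`` switches to the Welch variant.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValidationError("degenerate samples: zero variance, unequal means")
    with warnings.catch_warnings():
        # near-constant ceiling data trips scipy's precision-loss warning
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def paired_t(before: Sequence[float], after: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on within-pair differences."""
    before = np.asarray(before, float)
    after = np.asarray(after, float)
    if before.shape != after.shape:
        raise ValidationError("paired samples must have equal length")
    if before.size < 2:
        raise ValidationError("paired test needs n >= 2 pairs")
    d = after - before
    if d.std(ddof=1) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise ValidationError(
            "degenerate paired sample: constant nonzero differences have zero variance"
        )
    t, p = stats.ttest_1samp(d, 0.0)
    return float(t), float(p)


def count_comparison(events_a: tuple[int, int], events_b: tuple[int, int]) -> tuple[float, str]:
    """Compare two event proportions k/n; returns ``(p, method)``.

    Pearson chi-squared (no continuity correction) on the 2×2 table, with
    Fisher's exact test whenever any expected cell count is below 5.
    """
    (ka, na), (kb, nb) = events_a, events_b
    if min(ka, na - ka, kb, nb - kb) < 0:
        raise ValidationError("negative counts in 2x2 table")
    table = np.array([[ka, na - ka], [kb, nb - kb]], dtype=float)
    if table.sum() == 0:
        return math.nan, "none"
    expected = stats.contingency.expected_freq(table) if table.sum() else table
    if (expected < 5).any() or (table.sum(axis=0) == 0).any():
        _, p = stats.fisher_exact(table)
        return float(p), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p), "chi2"


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------


@dataclass
class TrialResult:
    """Arm-wise (or subgroup-wise) outcome comparison tables."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    rows: list[dict] = field(default_factory=list)  # continuous outcomes
    event_rows: list[dict] = field(default_factory=list)  # 2x2 event counts

    def add_continuous(self, outcome: str, a: Sequence[float], b: Sequence[float],
                       equal_var: bool = True) -> None:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        row = {
            "outcome": outcome,
            "mean_a": float(a.mean()) if a.size else None,
            "sd_a": float(a.std(ddof=1)) if a.size > 1 else None,
            "mean_b": float(b.mean()) if b.size else None,
            "sd_b": float(b.std(ddof=1)) if b.size > 1 else None,
        }
        if a.size < 2 or b.size < 2:
            row.update(statistic=None, p=None, method="not_computable")
        else:
            try:
                t, p = two_sample_t(a, b, equal_var=equal_var)
                row.update(statistic=t, p=p, method="t" if equal_var else "welch_t")
            except ValidationError:
                # both groups constant at different values: flag, don't fail
                row.update(statistic=None, p=None, method="degenerate")
        self.rows.append(row)

    def add_event(self, outcome: str, k_a: int, k_b: int) -> None:
        if min(self.n_a, self.n_b) == 0:
            p, method = None, "not_computable"
        else:
            p, method = count_comparison((k_a, self.n_a), (k_b, self.n_b))
        self.event_rows.append(
            {
                "outcome": outcome,
                "count_a": int(k_a),
                "pct_a": 100.0 * k_a / self.n_a if self.n_a else math.nan,
                "count_b": int(k_b),
                "pct_b": 100.0 * k_b / self.n_b if self.n_b else math.nan,
                "p": p,
                "method": method,
            }
        )

    @property
    def p_values(self) -> dict[str, float]:
        out = {r["outcome"]: r["p"] for r in self.rows if r["p"] is not None}
        out.update({r["outcome"]: r["p"] for r in self.event_rows if r["p"] is not None})
        return out

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "rows": self.rows,
            "event_rows": self.event_rows,
        }


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def _patient_outcomes(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-patient trough means and CVs, one row per patient."""
    rows = []
    for r in records:
        row: dict = {"patient_id": r.patient_id, "arm": r.arm}
        for drug in DRUGS:
            levels = [
                r.troughs[v][drug]
                for v in sorted(r.troughs)
                if drug in r.troughs.get(v, {})
            ]
            row[f"{drug}_trough"] = float(np.mean(levels)) if levels else math.nan
            row[f"{drug}_cv"] = (
                coefficient_of_variation(levels) if len(levels) >= 2 else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _clinical_names(records: Sequence[PatientRecord]) -> list[str]:
    names: list[str] = []
    for r in records:
        for k in r.clinical_events:
            if k not in names:
                names.append(k)
    return names


def _build_comparison(
    group_a: Sequence[PatientRecord],
    group_b: Sequence[PatientRecord],
    metrics: pd.DataFrame | None,
    label_a: str,
    label_b: str,
    equal_var: bool = True,
) -> TrialResult:
    res = TrialResult(label_a, label_b, len(group_a), len(group_b))
    ids_a = {r.patient_id for r in group_a}
    ids_b = {r.patient_id for r in group_b}
    out = _patient_outcomes(list(group_a) + list(group_b))
    in_a = out["patient_id"].isin(ids_a)
    for drug in DRUGS:
        for suffix, label in (("trough", "trough_level"), ("cv", "cv")):
            col = f"{drug}_{suffix}"
            res.add_continuous(
                f"{drug}_{label}", out.loc[in_a, col], out.loc[~in_a, col], equal_var
            )
    if metrics is not None and not metrics.empty:
        ma = metrics[metrics["patient_id"].isin(ids_a)]
        mb = metrics[metrics["patient_id"].isin(ids_b)]
        for metric in METRIC_NAMES:
            for period in range(1, N_VISITS + 1):
                res.add_continuous(
                    f"{metric}_period_{period}",
                    ma.loc[ma["period"] == period, metric],
                    mb.loc[mb["period"] == period, metric],
                    equal_var,
                )
    for name in _clinical_names(list(group_a) + list(group_b)):
        k_a = sum(bool(r.clinical_events.get(name)) for r in group_a)
        k_b = sum(bool(r.clinical_events.get(name)) for r in group_b)
        res.add_event(name, k_a, k_b)
    return res


def compare_groups(
    cohort: Sequence[PatientRecord],
    metrics: pd.DataFrame | None = None,
    equal_var: bool = True,
) -> TrialResult:
    """Intervention-vs-control comparison over all trial outcomes.

    ``metrics`` is a per-patient × period adherence table
    (:func:`adhermon.adherence_metrics.cohort_period_metrics`); when given,
    each adherence metric is compared per period between arms. Trough
    levels are summarized per patient as the mean over the 6 visits, CV
    as the within-patient coefficient of variation; clinical events as
    2×2 count comparisons.
    """
    arm_a = [r for r in cohort if r.arm == "intervention"]
    arm_b = [r for r in cohort if r.arm == "control"]
    if len(arm_a) < 2 or len(arm_b) < 2:
        raise ValidationError("each arm needs at least 2 patients")
    return _build_comparison(arm_a, arm_b, metrics, "intervention", "control", equal_var)


def feedback_subgroup_analysis(
    intervention: Sequence[PatientRecord],
    feedback_counts: Mapping[str, int],
    metrics: pd.DataFrame | None = None,
    equal_var: bool = True,
) -> TrialResult:
    """Within-intervention comparison: patients with ≥1 feedback vs none.

    ``feedback_counts`` maps patient id → deduplicated feedback
    occurrences (escalations of one slot count once). An empty subgroup
    yields a result whose comparisons are flagged non-computable rather
    than an error.
    """
    bad_arm = [r.patient_id for r in intervention if r.arm != "intervention"]
    if bad_arm:
        raise ValidationError(f"non-intervention patients in subgroup analysis: {bad_arm}")
    with_fb = [r for r in intervention if feedback_counts.get(r.patient_id, 0) >= 1]
    without = [r for r in intervention if feedback_counts.get(r.patient_id, 0) == 0]
    return _build_comparison(with_fb, without, metrics, "feedback_ge1", "no_feedback", equal_var)
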