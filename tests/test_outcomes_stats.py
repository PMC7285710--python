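import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adhermon import (
    PatientRecord,
    ValidationError,
    coefficient_of_variation,
    compare_groups,
    count_comparison,
    feedback_subgroup_analysis,
    paired_t,
    two_sample_t,
)
from adhermon.adherence_metrics import METRIC_NAMES

from conftest import START


class TestCV:
    def test_constant_series_has_zero_variability(self):
        assert coefficient_of_variation([5, 5, 5, 5]) == 0.0

    def test_two_point_closed_form(self):
        # SD of (4, 6) is sqrt(2), mean 5
        assert coefficient_of_variation([4, 6]) == pytest.approx(100 * math.sqrt(2) / 5)

    @given(
        st.lists(st.floats(0.5, 50), min_size=2, max_size=8),
        st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, levels, c):
        assert coefficient_of_variation([c * x for x in levels]) == pytest.approx(
            coefficient_of_variation(levels), rel=1e-9, abs=1e-9
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            coefficient_of_variation([5.0])
        with pytest.raises(ValidationError):
            coefficient_of_variation([1.0, -3.0])


class TestTwoSampleT:
    def test_identical_samples(self):
        t, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1

    def test_pooled_variance_hand_computation(self):
        a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0]
        # textbook pooled t computed from first principles
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t_hand = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        p_hand = 2 * stats.t.sf(abs(t_hand), na + nb - 2)
        t, p = two_sample_t(a, b)
        assert t == pytest.approx(t_hand)
        assert p == pytest.approx(p_hand)

    def test_antisymmetry(self):
        t1, p1 = two_sample_t([1, 2, 5], [2, 4, 8])
        t2, p2 = two_sample_t([2, 4, 8], [1, 2, 5])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValidationError):
            two_sample_t([1.0], [1.0, 2.0])
        with pytest.raises(ValidationError):
            two_sample_t([2.0, 2.0], [3.0, 3.0])

    def test_null_p_values_are_uniform(self):
        # Kolmogorov-Smirnov on 500 simulated null comparisons
        rng = np.random.default_rng(12345)
        ps = [
            two_sample_t(rng.normal(size=20), rng.normal(size=20))[1]
            for _ in range(500)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPairedT:
    def test_no_change_gives_p_one(self):
        before = [3.0, 4.0, 5.0]
        assert paired_t(before, before) == (0.0, 1.0)

    def test_constant_nonzero_shift_is_degenerate(self):
        with pytest.raises(ValidationError, match="zero variance"):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_reduces_to_one_sample_t_on_differences(self):
        rng = np.random.default_rng(42)
        before = rng.normal(3.6, 1.0, 40)
        after = before + rng.normal(0.3, 0.7, 40)
        t, p = paired_t(before, after)
        ref = stats.ttest_1samp(after - before, 0.0)
        assert t == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


def fisher_two_sided(ka: int, na: int, kb: int, nb: int) -> float:
    """Independent oracle: exact hypergeometric enumeration of the 2x2 table."""
    total, n = ka + kb, na + nb
    denom = comb(n, total)

    def prob(x: int) -> float:
        return comb(na, x) * comb(nb, total - x) / denom

    p_obs = prob(ka)
    return sum(
        prob(x)
        for x in range(max(0, total - nb), min(na, total) + 1)
        if prob(x) <= p_obs * (1 + 1e-12)
    )


class TestCountComparison:
    def test_identical_proportions_show_no_association(self):
        p, _method = count_comparison((5, 50), (5, 50))
        assert p == pytest.approx(1.0)

    def test_sparse_table_uses_fisher_and_matches_enumeration(self):
        p, method = count_comparison((1, 12), (6, 13))
        assert method == "fisher"
        assert p == pytest.approx(fisher_two_sided(1, 12, 6, 13), rel=1e-9)

    def test_trial_sized_event_split_reports_method(self):
        # 3/51 vs 8/54: the smallest expected cell is 51*11/105 = 5.34, just
        # above the Fisher cut-off, so the Pearson test applies
        p, method = count_comparison((3, 51), (8, 54))
        assert method == "chi2"
        assert 0.0 < p < 1.0

    def test_extreme_split_is_significant(self):
        p, _ = count_comparison((0, 10), (10, 10))
        assert p < 0.01
        # a sparse extreme split goes through Fisher and matches enumeration
        p2, method = count_comparison((0, 10), (9, 10))
        assert method == "fisher"
        assert p2 == pytest.approx(fisher_two_sided(0, 10, 9, 10), rel=1e-9)
        assert p2 < 0.01

    def test_large_balanced_table_uses_chi2(self):
        p, method = count_comparison((20, 100), (30, 100))
        assert method == "chi2"
        chi2, p_ref, _, _ = stats.chi2_contingency(
            [[20, 80], [30, 70]], correction=False
        )
        assert p == pytest.approx(p_ref)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            count_comparison((-1, 10), (0, 10))


def _patient(pid, arm, tac, mpa, hla=False):
    troughs = {
        v + 1: {"tacrolimus": tac[v], "mycophenolic_acid": mpa[v]} for v in range(6)
    }
    return PatientRecord(
        pid, arm, START, troughs=troughs, clinical_events={"de_novo_anti_hla": hla}
    )


def _mirrored_cohort(n=5, seed=0):
    rng = np.random.default_rng(seed)
    cohort, metrics_rows = [], []
    for i in range(n):
        tac = rng.normal(5.2, 1.2, 6)
        mpa = rng.normal(2.7, 1.0, 6)
        hla = bool(rng.random() < 0.3)
        vals = rng.uniform(95, 100, 4)
        for arm, tag in (("intervention", "I"), ("control", "C")):
            cohort.append(_patient(f"{tag}{i}", arm, tac, mpa, hla))
            for k in range(1, 7):
                metrics_rows.append(
                    {
                        "patient_id": f"{tag}{i}",
                        "period": k,
                        **{m: vals[j] for j, m in enumerate(METRIC_NAMES)},
                    }
                )
    return cohort, pd.DataFrame(metrics_rows)


class TestCompareGroups:
    def test_mirrored_arms_show_no_differences(self):
        cohort, metrics = _mirrored_cohort()
        res = compare_groups(cohort, metrics)
        assert res.n_a == res.n_b == 5
        for outcome, p in res.p_values.items():
            assert p == pytest.approx(1.0), outcome

    def test_row_count_is_data_independent(self):
        res1 = compare_groups(_mirrored_cohort(5, 1)[0], _mirrored_cohort(5, 1)[1])
        res2 = compare_groups(_mirrored_cohort(9, 2)[0], _mirrored_cohort(9, 2)[1])
        assert len(res1.rows) == len(res2.rows) == 4 + 4 * 6
        assert len(res1.event_rows) == len(res2.event_rows) == 1

    def test_single_patient_arm_rejected(self):
        cohort, _ = _mirrored_cohort(3)
        tiny = [r for r in cohort if r.arm == "control"][:1]
        tiny += [r for r in cohort if r.arm == "intervention"]
        with pytest.raises(ValidationError):
            compare_groups(tiny)


class TestFeedbackSubgroup:
    def test_split_reproduces_input_partition(self):
        cohort, metrics = _mirrored_cohort(8, seed=3)
        arm = [r for r in cohort if r.arm == "intervention"]
        counts = {r.patient_id: (1 if i < 3 else 0) for i, r in enumerate(arm)}
        res = feedback_subgroup_analysis(arm, counts, metrics)
        assert (res.n_a, res.n_b) == (3, 5)

    def test_empty_subgroup_flagged_not_error(self):
        cohort, _ = _mirrored_cohort(4, seed=4)
        arm = [r for r in cohort if r.arm == "intervention"]
        res = feedback_subgroup_analysis(arm, {})
        assert res.n_a == 0 and res.n_b == 4
        assert all(r["method"] == "not_computable" for r in res.rows)

    def test_subgroup_means_recompute_from_partition(self):
        cohort, metrics = _mirrored_cohort(8, seed=5)
        arm = [r for r in cohort if r.arm == "intervention"]
        counts = {r.patient_id: (2 if i % 2 else 0) for i, r in enumerate(arm)}
        res = feedback_subgroup_analysis(arm, counts, metrics)
        with_fb = [r for r in arm if counts[r.patient_id] >= 1]
        expect = np.mean(
            [np.mean([r.troughs[v]["tacrolimus"] for v in range(1, 7)]) for r in with_fb]
        )
        row = next(r for r in res.rows if r["outcome"] == "tacrolimus_trough_level")
        assert row["mean_a"] == pytest.approx(expect)
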