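"""Age correlations, case-control comparisons and BH correction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirledit.cohort import (
    bh_correct,
    category_summary,
    mannwhitney_site,
    run_cohort_analysis,
    spearman_age,
)
from mirledit.errors import CohortError, InputError, ParameterError

from _oracles import bh_sorted_min, mannwhitney_enum_p, spearman_perm_p


class TestSpearmanAge:
    def test_perfect_monotone_gives_rho_one(self):
        rho, p = spearman_age([0.1, 0.2, 0.3, 0.4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_perfect_antitone_gives_rho_minus_one(self):
        rho, _ = spearman_age([0.4, 0.3, 0.2, 0.1], [10, 20, 30, 40])
        assert rho == pytest.approx(-1.0)

    def test_single_rank_swap_gives_rho_point_eight(self):
        # ranks (1,4,2,3) vs (1,3,2,4): sum d^2 = 2, 1 - 6*2/60 = 0.8
        rho, _ = spearman_age([0.1, 0.4, 0.2, 0.3], [10, 30, 20, 40])
        assert rho == pytest.approx(0.8)

    def test_zero_variance_yields_nan_signal(self):
        rho, p = spearman_age([0.2, 0.2, 0.2, 0.2], [10, 20, 30, 40])
        assert math.isnan(rho) and math.isnan(p)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            spearman_age([0.1, 0.2], [10, 20])

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_permutation_oracle_on_small_vectors(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(3, 7))
        levels = rng.choice([0.0, 0.1, 0.2, 0.5, 0.9], n)
        ages = rng.choice([5.0, 10.0, 20.0, 40.0, 70.0], n)
        if np.ptp(levels) == 0 or np.ptp(ages) == 0:
            return
        rho, p = spearman_age(levels, ages)
        o_rho, o_p = spearman_perm_p(list(levels), list(ages))
        assert rho == pytest.approx(o_rho, abs=1e-12)
        assert p == pytest.approx(o_p, abs=1e-12)

    def test_large_n_uses_t_approximation_consistent_with_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(7)
        levels = rng.random(30)
        ages = levels + rng.normal(0, 0.3, 30)
        rho, p = spearman_age(levels, ages)
        ref = stats.spearmanr(levels, ages)
        assert rho == pytest.approx(float(ref.statistic), abs=1e-12)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-6)


class TestMannWhitney:
    def test_complete_separation_of_three_vs_three(self):
        res = mannwhitney_site([0.9, 0.8, 0.7], [0.1, 0.2, 0.3])
        assert res.u_statistic == 9
        assert res.p_value == pytest.approx(0.1)  # 2 of 20 labelings
        assert res.direction == "hyper"

    def test_identical_groups_give_p_one_and_no_direction(self):
        res = mannwhitney_site([0.2, 0.2], [0.2, 0.2])
        assert res.p_value == 1.0
        assert res.direction is None
        assert not res.significant

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_enumeration_oracle_on_small_groups(self, trial):
        rng = np.random.default_rng(200 + trial)
        n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        case = rng.choice([0.0, 0.05, 0.1, 0.3, 0.7], n1)
        control = rng.choice([0.0, 0.05, 0.1, 0.3, 0.7], n2)
        res = mannwhitney_site(case, control)
        o_u, o_p = mannwhitney_enum_p(list(case), list(control))
        assert res.u_statistic == pytest.approx(o_u)
        assert res.p_value == pytest.approx(o_p, abs=1e-12)

    def test_swapping_group_labels_preserves_p_and_flips_direction(self):
        rng = np.random.default_rng(3)
        case = rng.random(8)
        control = rng.random(6) * 0.5
        a = mannwhitney_site(case, control)
        b = mannwhitney_site(control, case)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert (a.direction, b.direction) == ("hyper", "hypo")
        assert a.u_statistic + b.u_statistic == len(case) * len(control)

    def test_p_decreases_with_larger_shift(self):
        rng = np.random.default_rng(4)
        base = rng.random(25)
        control = rng.random(25)
        p_small = mannwhitney_site(base + 0.1, control).p_value
        p_large = mannwhitney_site(base + 0.6, control).p_value
        assert p_large < p_small

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            mannwhitney_site([], [0.1])

    def test_type_one_error_rate_of_the_exact_test(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 400
        for _ in range(reps):
            res = mannwhitney_site(rng.random(6), rng.random(6))
            hits += res.p_value < 0.05
        assert hits / reps <= 0.08  # exact test is conservative at 0.05


class TestBhCorrect:
    def test_singleton_is_identity(self):
        assert bh_correct([0.01]) == pytest.approx([0.01])

    def test_worked_four_value_example(self):
        assert bh_correct([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones_stay_capped_at_one(self):
        assert bh_correct([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(InputError):
            bh_correct([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_matches_sorted_minimum_definition(self, p_values):
        ours = bh_correct(p_values)
        brute = bh_sorted_min(p_values)
        assert np.allclose(ours, brute, atol=1e-12)


def _toy_matrix_and_design():
    rng = np.random.default_rng(12)
    samples = [f"c{i}" for i in range(10)] + [f"n{i}" for i in range(10)]
    design = pd.DataFrame(
        {
            "sample": samples,
            "group": ["case"] * 10 + ["control"] * 10,
            "region": ["SFG"] * 20,
            "age": list(range(1, 21)),
        }
    )
    signal = np.concatenate([
        rng.normal(0.4, 0.03, 10), rng.normal(0.05, 0.02, 10)
    ]).clip(0, 1)
    null = rng.normal(0.2, 0.03, 20).clip(0, 1)
    matrix = pd.DataFrame(
        [signal, null], index=["hp_9_A_g", "hp_12_C_u"], columns=samples
    )
    return matrix, design


class TestRunCohortAnalysis:
    def test_separated_site_is_significant_hyper(self):
        matrix, design = _toy_matrix_and_design()
        _, comparisons = run_cohort_analysis(matrix, design)
        by_site = {c.site: c for c in comparisons}
        assert by_site["hp_9_A_g"].significant
        assert by_site["hp_9_A_g"].direction == "hyper"
        assert not by_site["hp_12_C_u"].significant

    def test_correlations_are_bh_corrected_within_group(self):
        matrix, design = _toy_matrix_and_design()
        correlations, _ = run_cohort_analysis(matrix, design)
        assert set(correlations) == {"case", "control"}
        for results in correlations.values():
            assert len(results) == 2
            for r in results:
                assert math.isnan(r.q_value) or r.q_value >= r.p_value - 1e-12

    def test_subgroup_filter_is_strictly_younger_than(self):
        matrix, design = _toy_matrix_and_design()
        design.loc[:, "age"] = [5, 9] + [12] * 8 + [5, 9] + [12] * 8
        _, comparisons = run_cohort_analysis(matrix, design, subgroup_max_age=10)
        assert comparisons[0].n_case == 2
        assert comparisons[0].n_control == 2

    def test_filter_emptying_a_group_raises(self):
        matrix, design = _toy_matrix_and_design()
        design.loc[design["group"] == "case", "age"] = 50
        with pytest.raises(CohortError):
            run_cohort_analysis(matrix, design, subgroup_max_age=10)

    def test_sample_without_design_row_raises(self):
        matrix, design = _toy_matrix_and_design()
        with pytest.raises(CohortError):
            run_cohort_analysis(matrix, design[:-1])


def test_category_summary_covers_all_nine_categories():
    table = category_summary(["A-to-I", "A-to-I", "3'-U"])
    assert len(table) == 9
    assert table.loc["A-to-I", "count"] == 2
    assert table.loc["A-to-I", "percent"] == pytest.approx(200 / 3)
    assert table["count"].sum() == 3
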