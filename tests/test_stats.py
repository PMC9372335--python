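import numpy as np
import pytest

from fluencyrp import (
    GeneratorConfig,
    apply_cohort_filters,
    default_vocabulary,
    fit_logistic_ladder,
    generate_cohort,
    lr_compare,
    lr_from_loglikelihoods,
    welch_ttest,
    zscore,
)


class TestCohortFilters:
    def test_three_rule_filter(self, small_cohort, vocab):
        # P1: HC x3 -> kept, first pair only; P2: single visit -> dropped;
        # P3: HC then ProbAD -> dropped as dual-group
        sample = apply_cohort_filters(small_cohort, vocab)
        assert list(sample.rows["participant_id"]) == ["P1"]
        assert list(sample.rows[["visit_a", "visit_b"]].iloc[0]) == [1, 2]
        assert sample.filter_counts == {
            "input": 3, "lt2_lists": 1, "dual_group": 1, "other_group": 0,
            "retained": 1,
        }

    def test_other_diagnoses_dropped(self, make_list, vocab):
        from fluencyrp import cohort_from_lists
        cohort = cohort_from_lists([
            make_list(["cat"], pid="P1", visit=1, group="MCI"),
            make_list(["cat"], pid="P1", visit=2, group="MCI"),
            make_list(["cat"], pid="P2", visit=1, group="HC"),
            make_list(["dog"], pid="P2", visit=2, group="HC"),
        ])
        sample = apply_cohort_filters(cohort, vocab)
        assert list(sample.rows["participant_id"]) == ["P2"]
        assert sample.filter_counts["other_group"] == 1

    def test_all_single_visit_is_error_with_counts(self, make_list, vocab):
        from fluencyrp import cohort_from_lists
        cohort = cohort_from_lists([make_list(["cat"], pid="P1", visit=1)])
        with pytest.raises(ValueError, match="lt2_lists.*1"):
            apply_cohort_filters(cohort, vocab)

    def test_first_pair_by_visit_index_not_file_order(self, make_list, vocab):
        from fluencyrp import cohort_from_lists
        cohort = cohort_from_lists([
            make_list(["pig"], pid="P1", visit=3),
            make_list(["cat"], pid="P1", visit=1),
            make_list(["dog"], pid="P1", visit=2),
        ])
        sample = apply_cohort_filters(cohort, vocab)
        assert list(sample.rows[["visit_a", "visit_b"]].iloc[0]) == [1, 2]


class TestWelch:
    def test_identical_samples_t_zero(self):
        res = welch_ttest([1, 2, 3], [1, 2, 3])
        assert res.t == 0 and res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # x=[1,2,3,4], y=[3,4,5,6]: equal n and variance (5/3 each), so
        # se = sqrt(2*(5/3)/4), t = -2/se = -2.1909, and the
        # Welch-Satterthwaite df reduces to n1+n2-2 = 6 exactly
        res = welch_ttest([1, 2, 3, 4], [3, 4, 5, 6])
        assert res.t == pytest.approx(-2.19089, abs=1e-4)
        assert res.df == pytest.approx(6.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 15)
        assert welch_ttest(x, y).t == pytest.approx(-welch_ttest(y, x).t)

    def test_fractional_df_under_unequal_variance(self):
        rng = np.random.default_rng(2)
        res = welch_ttest(rng.normal(0, 1, 10), rng.normal(0, 5, 30))
        assert res.df != int(res.df)

    def test_degenerate_constant_samples(self):
        res = welch_ttest([2.0, 2.0], [1.0, 1.0])
        assert res.degenerate and np.isinf(res.t) and res.t > 0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            welch_ttest([1.0], [1, 2, 3])


class TestZscore:
    def test_forced_by_sample_sd(self):
        assert zscore([1, 2, 3]) == pytest.approx([-1, 0, 1])

    def test_idempotent_on_standardized_input(self):
        v = zscore(np.random.default_rng(3).normal(5, 2, 50))
        assert zscore(v) == pytest.approx(v)

    def test_constant_vector_names_predictor(self):
        with pytest.raises(ValueError, match="dfd"):
            zscore([5, 5, 5], name="dfd")


@pytest.fixture(scope="module")
def sim_sample():
    cohort = generate_cohort(GeneratorConfig(seed=11, n_participants=60, n_visits=2))
    return apply_cohort_filters(cohort, default_vocabulary())


class TestLogisticLadder:
    def test_design_size_two_predictors(self, sim_sample):
        fit = fit_logistic_ladder(sim_sample, ["average_length", "dfd"])
        # intercept + 2 mains + 1 two-way product
        assert fit.n_params == 4 and fit.df == 3
        assert set(fit.column_names) == {
            "intercept", "average_length", "dfd", "average_length:dfd"}

    def test_design_size_three_predictors(self, sim_sample):
        fit = fit_logistic_ladder(
            sim_sample, ["average_length", "repetition_proportion_avg", "dfd"])
        assert fit.n_params == 8 and fit.df == 7  # 1 + 3 + 3 + 1

    def test_uninformative_predictor_slope_near_zero(self, make_list, vocab):
        from fluencyrp import cohort_from_lists
        lists = []
        for k, group in enumerate(["HC", "HC", "ProbAD", "ProbAD"] * 6):
            tokens = ["cat", "dog"] if k % 2 else ["dog", "cat", "pig"]
            lists += [make_list(tokens, pid=f"P{k}", visit=1, group=group),
                      make_list(tokens, pid=f"P{k}", visit=2, group=group)]
        sample = apply_cohort_filters(cohort_from_lists(lists), vocab)
        fit = fit_logistic_ladder(sample, ["average_length"])
        assert fit.converged
        assert fit.params == pytest.approx([0.0, 0.0], abs=1e-6)

    def test_separable_data_flagged_not_raised(self, make_list, vocab):
        from fluencyrp import cohort_from_lists
        lists = []
        for k in range(12):
            group = "HC" if k < 6 else "ProbAD"
            n = 10 if k < 6 else 3  # length perfectly separates the groups
            tokens = [f"w{i}" for i in range(n)]
            lists += [make_list(tokens, pid=f"P{k}", visit=1, group=group),
                      make_list(tokens, pid=f"P{k}", visit=2, group=group)]
        sample = apply_cohort_filters(cohort_from_lists(lists), vocab=None)
        fit = fit_logistic_ladder(sample, ["average_length"])
        assert not fit.converged

    def test_lr_paper_style_loglikelihoods(self):
        cmp12 = lr_from_loglikelihoods(-31.833, -24.865, 4)
        assert cmp12.lr_statistic == pytest.approx(13.936)
        assert cmp12.p_value == pytest.approx(0.0075, abs=5e-4)
        cmp910 = lr_from_loglikelihoods(-71.794, -45.051, 4)
        assert cmp910.lr_statistic == pytest.approx(53.486)

    def test_lr_identical_fits(self, sim_sample):
        fit = fit_logistic_ladder(sim_sample, ["average_length"])
        cmp = lr_compare(fit, fit)
        assert cmp.lr_statistic == pytest.approx(0.0, abs=1e-9)
        assert cmp.p_value == pytest.approx(1.0)

    def test_non_nested_rejected(self, sim_sample):
        a = fit_logistic_ladder(sim_sample, ["average_length"])
        b = fit_logistic_ladder(sim_sample, ["dfd"])
        with pytest.raises(ValueError, match="not nested"):
            lr_compare(a, b)

    def test_lr_invariant_to_predictor_order(self, sim_sample):
        red = fit_logistic_ladder(sim_sample, ["average_length", "dfd"])
        f1 = fit_logistic_ladder(
            sim_sample, ["average_length", "dfd", "repetition_proportion_avg"])
        f2 = fit_logistic_ladder(
            sim_sample, ["repetition_proportion_avg", "dfd", "average_length"])
        assert lr_compare(red, f1).lr_statistic == pytest.approx(
            lr_compare(red, f2).lr_statistic, abs=1e-6)
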