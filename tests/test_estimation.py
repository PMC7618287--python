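"""Post-stratified coverage estimation, cluster SEs and the quality gap."""

import numpy as np
import pandas as pd
import pytest

from ecsc import (
    CSC,
    ECSC,
    DesignError,
    IndicatorConfig,
    PopulationTable,
    UndefinedEstimateError,
    adjustment_factors,
    cluster_se,
    coverage_estimate,
    quality_gap,
    sample_survey,
    survey_counts,
    threshold_matrix,
)
from ecsc.vision import STRATA
from conftest import (
    OPERABLE,
    OPERATED_GOOD,
    make_survey,
    person,
    uniform_population,
)


class TestClusterSE:
    def test_zero_between_cluster_residual_gives_zero_se(self):
        x = np.array([10.0, 20.0, 30.0])
        assert cluster_se(0.4 * x, x) == pytest.approx(0.0, abs=1e-14)

    def test_hand_worked_three_cluster_example(self):
        # r = 12/30 = 0.4; residuals (-2, 0, 2); se = 100*sqrt(1.5*8)/30
        se = cluster_se([2, 4, 6], [10, 10, 10])
        assert se == pytest.approx(100 * np.sqrt(1.5 * 8) / 30, rel=1e-12)
        assert se == pytest.approx(11.547005, abs=1e-6)

    def test_fewer_than_two_clusters_is_design_error(self):
        with pytest.raises(DesignError):
            cluster_se([2.0], [10.0])

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            cluster_se([0.0, 0.0], [0.0, 0.0])


class TestAdjustmentFactors:
    def test_uniform_sampling_fraction_gives_equal_weights(self):
        people = [
            person(i, cluster=f"c{i % 3}", age=age, sex=sex)
            for i, (sex, age) in enumerate(
                (s, a) for s in ("F", "M") for a in (55, 65, 75, 85) for _ in range(5)
            )
        ]
        survey = make_survey(people)
        pop = uniform_population(survey, factor=20)
        w = adjustment_factors(survey_counts(survey), pop)
        assert np.allclose(w["w"], 20.0)

    def test_direct_ratio_of_population_to_examined(self):
        counts = pd.DataFrame(
            [
                {"sex": "F", "age_band": "50-59", "examined": 100},
                {"sex": "F", "age_band": "60-69", "examined": 100},
            ]
        )
        pop = PopulationTable(
            {s: 0 for s in STRATA}
            | {("F", "50-59"): 1000, ("F", "60-69"): 500, ("M", "50-59"): 1}
        )
        w = adjustment_factors(counts, pop, sex="F")
        by_band = dict(zip(w["age_band"], w["w"]))
        assert by_band["50-59"] == pytest.approx(10.0)
        assert by_band["60-69"] == pytest.approx(5.0)

    def test_collapsing_empty_stratum_conserves_population(self):
        counts = pd.DataFrame(
            [
                {"sex": s, "age_band": b, "examined": 10}
                for s in ("F", "M")
                for b in ("50-59", "60-69", "70-79")  # nobody examined 80+
            ]
        )
        pop = PopulationTable({(s, b): 100 for s, b in STRATA})
        w = adjustment_factors(counts, pop)
        assert w["N"].sum() == pytest.approx(800)
        merged = w[(w["sex"] == "F") & (w["age_band"] == "70-79")]["N"].iloc[0]
        assert merged == pytest.approx(200)  # 80+ folded into 70-79

    def test_empty_stratum_hard_error_mode(self):
        counts = pd.DataFrame([{"sex": "F", "age_band": "50-59", "examined": 10}])
        pop = PopulationTable({(s, b): 100 for s, b in STRATA})
        with pytest.raises(DesignError):
            adjustment_factors(counts, pop, empty_stratum="error")


def _two_stratum_survey():
    """Stratum F/50-59: 20 operated + 20 operable; F/60-69: 10 operated + 40 operable."""
    people = []
    i = 0
    for age, n_op, n_need in ((55, 20, 20), (65, 10, 40)):
        for _ in range(n_op):
            people.append(person(i, cluster=f"c{i % 4}", age=age, right=OPERATED_GOOD))
            i += 1
        for _ in range(n_need):
            people.append(person(i, cluster=f"c{i % 4}", age=age, right=OPERABLE))
            i += 1
    return make_survey(people)


class TestCoverageEstimate:
    def test_hand_worked_weighted_ratio(self):
        # w = (10, 5), num = (20, 10), den = (40, 50):
        # 100 * (10*20 + 5*10) / (10*40 + 5*50) = 100*250/650 = 38.4615...
        survey = _two_stratum_survey()
        pop = PopulationTable(
            {s: 0 for s in STRATA} | {("F", "50-59"): 400, ("F", "60-69"): 250}
        )
        est = coverage_estimate(survey, pop, indicator=CSC)
        assert est.value == pytest.approx(100 * 250 / 650, rel=1e-12)

    def test_post_stratification_identity_under_uniform_weights(self):
        survey = _two_stratum_survey()
        pop = uniform_population(survey, factor=10)
        est = coverage_estimate(survey, pop, indicator=CSC)
        crude = 100 * 30 / 90  # 30 operated among 90 denominator members
        assert est.value == pytest.approx(crude, abs=1e-10)

    def test_scale_invariance_of_population_counts(self):
        survey = _two_stratum_survey()
        pop = PopulationTable(
            {s: 0 for s in STRATA} | {("F", "50-59"): 400, ("F", "60-69"): 250}
        )
        a = coverage_estimate(survey, pop, indicator=CSC)
        b = coverage_estimate(survey, pop.scaled(1000), indicator=CSC)
        assert b.value == pytest.approx(a.value, rel=1e-12)
        assert b.se == pytest.approx(a.se, rel=1e-12)

    def test_saturated_coverage_is_100_with_zero_se(self):
        people = [
            person(i, cluster=f"c{i % 3}", right=OPERATED_GOOD) for i in range(30)
        ]
        survey = make_survey(people)
        est = coverage_estimate(survey, uniform_population(survey), indicator=CSC)
        assert est.value == pytest.approx(100.0)
        assert est.se == pytest.approx(0.0, abs=1e-12)
        assert est.ci_high == 100.0

    def test_zero_denominator_is_undefined(self):
        people = [person(i, cluster=f"c{i % 3}") for i in range(10)]
        survey = make_survey(people)
        with pytest.raises(UndefinedEstimateError):
            coverage_estimate(survey, uniform_population(survey))

    def test_ecsc_never_exceeds_csc(self, small_pop):
        survey, pop = sample_survey(small_pop, replicate=2)
        for sex in ("ALL", "F", "M"):
            e = coverage_estimate(survey, pop, indicator=ECSC, sex=sex)
            c = coverage_estimate(survey, pop, indicator=CSC, sex=sex)
            assert e.value <= c.value + 1e-12

    def test_mean_estimate_recovers_truth(self, small_pop):
        """Parameter recovery: mean over 200 sampled surveys within 1 point."""
        true_ecsc = small_pop.truth().ecsc
        vals = []
        for k in range(200):
            survey, pop = sample_survey(small_pop, replicate=100 + k)
            vals.append(coverage_estimate(survey, pop).value)
        assert abs(np.mean(vals) - true_ecsc) < 1.0


class TestQualityGap:
    def test_smallest_observed_gap_worked_example(self):
        assert round(quality_gap(65.7, 58.6), 1) == 10.8

    def test_largest_observed_gap_worked_example(self):
        assert round(quality_gap(14.3, 3.8), 1) == 73.4

    @pytest.mark.parametrize("x", [0.5, 40.0, 100.0])
    def test_equal_coverage_means_zero_gap(self, x):
        assert quality_gap(x, x) == pytest.approx(0.0)

    def test_zero_csc_is_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            quality_gap(0.0, 0.0)

    def test_ecsc_above_csc_is_invariant_violation(self):
        with pytest.raises(ValueError):
            quality_gap(30.0, 35.0)


class TestThresholdMatrix:
    def test_default_cell_matches_standalone_estimate(self, small_pop):
        survey, pop = sample_survey(small_pop, replicate=3)
        grid = threshold_matrix(survey, pop)
        cell = grid[
            (grid["surgical_threshold"] == "6/18") & (grid["outcome_threshold"] == "6/18")
        ].iloc[0]
        standalone = coverage_estimate(survey, pop, IndicatorConfig())
        assert cell["value"] == pytest.approx(standalone.value, rel=1e-12)
        assert cell["se"] == pytest.approx(standalone.se, rel=1e-12)

    def test_row_monotone_in_surgical_threshold(self, small_pop):
        survey, pop = sample_survey(small_pop, replicate=4)
        grid = threshold_matrix(survey, pop, outcome_thresholds=("6/12",))
        vals = [
            grid[grid["surgical_threshold"] == st]["value"].iloc[0]
            for st in ("3/60", "6/60", "6/18", "6/12")
        ]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
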