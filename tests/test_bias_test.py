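"""The single-trial I² bias test, its estimator interface, and the
cohort-level driver."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from sctbias.bias_test import (
    SelectionBiasI2Test,
    classify,
    run_cohort,
    select_arm_pair,
    tally,
)
from sctbias.bias_test import test_arms as i2_for_arms
from sctbias.bias_test import test_trial as run_single_trial
from sctbias.meta_analysis import StudyEffect, fixed_effect_pool
from sctbias.sct_generator import SCTConfig, build_confirmed_sct_pair
from sctbias.trial_io import ArmSummary, CohortTable

from conftest import make_record


@pytest.fixture(scope="module")
def pair():
    return build_confirmed_sct_pair(SCTConfig(), np.random.default_rng(42))


class TestClassify:
    @pytest.mark.parametrize(
        "rob2,positive,expected",
        [
            ("high", True, "TP"),
            ("high", False, "FP"),
            ("low", False, "TN"),
            ("low", True, "FN"),
        ],
    )
    def test_mapping(self, rob2, positive, expected):
        assert classify(rob2, positive) == expected

    @pytest.mark.parametrize("rob2", ["some_concerns", "unknown"])
    def test_outside_dichotomy_is_skipped(self, rob2):
        assert classify(rob2, True) is None

    def test_tally(self):
        counts = tally(["TP", "TN", "FN", "FP", None, "TN"])
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (1, 1, 2, 1)
        assert tally([None, None]) is None


class TestSelectArmPair:
    def test_picks_most_significant_difference(self):
        arms = [
            ArmSummary(50, 10, 100),
            ArmSummary(51, 10, 100),   # z vs arm0 ~ 0.7
            ArmSummary(58, 10, 100),   # z vs arm0 ~ 5.7 (the winner)
        ]
        assert select_arm_pair(arms) == (0, 2)

    def test_tie_broken_by_first_occurrence(self):
        arms = [ArmSummary(50, 10, 100)] * 3  # all z = 0
        assert select_arm_pair(arms) == (0, 1)

    def test_needs_two_arms(self):
        with pytest.raises(ValueError, match="two arms"):
            select_arm_pair([ArmSummary(50, 10, 100)])


class TestTestArms:
    def test_large_imbalance_is_positive(self, pair):
        # md = 10 with var = 1 against near-zero SCT mean differences
        i2 = i2_for_arms(ArmSummary(60, 10, 200), ArmSummary(50, 10, 200), pair)
        assert i2 > 0
        # agrees with a direct evaluation of the three-study Q formula
        effects = [
            StudyEffect(pair.first.arm_a.mean - pair.first.arm_b.mean,
                        pair.first.arm_a.variance_of_mean
                        + pair.first.arm_b.variance_of_mean),
            StudyEffect(pair.second.arm_a.mean - pair.second.arm_b.mean,
                        pair.second.arm_a.variance_of_mean
                        + pair.second.arm_b.variance_of_mean),
            StudyEffect(10.0, 1.0),
        ]
        assert i2 == pytest.approx(fixed_effect_pool(effects).i2, rel=1e-12)

    def test_balanced_wide_variance_trial_is_negative(self, pair):
        # md 0 adds nothing to Q's numerator: I² stays 0
        i2 = i2_for_arms(ArmSummary(44, 21, 30), ArmSummary(44, 21, 30), pair)
        assert i2 == 0.0

    def test_duplicate_of_sct_effect_is_well_defined(self, pair):
        i2 = i2_for_arms(pair.first.arm_a, pair.first.arm_b, pair)
        assert 0.0 <= i2 < 100.0

    def test_trial_record_wrapper(self, pair):
        res = run_single_trial(make_record(mean_a=70.0, mean_b=50.0), pair, sct_seed=7)
        assert res.positive == (res.i2 > 0)
        assert res.trial_id == "T1" and res.sct_seed == 7


class TestEstimator:
    X = pd.DataFrame(
        [[65.2, 10.1, 50, 64.8, 9.7, 52], [70.0, 8.0, 120, 50.0, 9.0, 110]],
        columns=["mean_a", "sd_a", "n_a", "mean_b", "sd_b", "n_b"],
    )

    def test_predict_shapes_and_determinism(self):
        est = SelectionBiasI2Test(random_state=11).fit()
        i2 = est.decision_function(self.X)
        assert i2.shape == (2,)
        assert np.array_equal(i2, est.decision_function(self.X))  # repeatable
        flags = est.predict(self.X)
        assert flags.dtype == bool
        assert np.array_equal(flags, i2 > 0)

    def test_ndarray_input_equivalent(self):
        est = SelectionBiasI2Test(random_state=11).fit()
        assert np.array_equal(
            est.decision_function(self.X.to_numpy()),
            est.decision_function(self.X),
        )

    def test_gross_imbalance_flagged(self):
        est = SelectionBiasI2Test(random_state=0).fit()
        assert est.predict(self.X)[1]  # 20-year arm difference

    def test_shared_pair_reuses_anchor(self):
        est = SelectionBiasI2Test(shared_pair=True, random_state=5).fit()
        out = est.test(self.X)
        assert out["sct_seed"].nunique() == 1
        assert est.pair_ is not None

    def test_sklearn_protocol(self):
        est = SelectionBiasI2Test(random_state=3, upper=90)
        params = est.get_params()
        assert params["upper"] == 90 and params["random_state"] == 3
        cloned = clone(est)
        assert cloned.get_params() == params
        cloned.set_params(lower=10)
        assert cloned.lower == 10

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            SelectionBiasI2Test().predict(self.X)

    def test_bad_columns_rejected(self):
        est = SelectionBiasI2Test(random_state=0).fit()
        with pytest.raises(ValueError, match="missing arm-summary columns"):
            est.test(pd.DataFrame({"mean_a": [1.0]}))
        with pytest.raises(ValueError, match="expected shape"):
            est.test(np.ones((2, 3)))


class TestRunCohort:
    def test_tally_conservation_and_filters(self, small_cohort):
        report = run_cohort(small_cohort, seed=1)
        # T5 is median-converted and excluded from the main analysis
        assert report.n_tested == 4 and report.n_skipped_converted == 1
        c = report.confusion_overall
        assert c.total == 4  # every tested low/high trial lands in one cell
        # domain1: T4 is unknown, so only 3 tallied
        assert report.confusion_domain1.total == 3

    def test_include_converted_adds_median_trials(self, small_cohort):
        report = run_cohort(small_cohort, seed=1, include_converted=True)
        assert report.n_tested == 5
        assert report.results["converted"].sum() == 1

    def test_variable_whitelist(self, small_cohort):
        records = list(small_cohort.records) + [
            make_record("T6", variable="weight", overall="low")
        ]
        cohort = CohortTable(records)
        report = run_cohort(cohort, seed=1, variable_whitelist=["age"])
        assert report.n_skipped_variable == 1
        assert set(report.results["variable_name"]) == {"age"}

    def test_deterministic_per_trial_i2(self, small_cohort):
        a = run_cohort(small_cohort, seed=9)
        b = run_cohort(small_cohort, seed=9)
        pd.testing.assert_frame_equal(a.results, b.results)

    def test_empty_eligible_set(self, small_cohort):
        with pytest.raises(ValueError, match="no eligible trials"):
            run_cohort(small_cohort, variable_whitelist=["bmi"])

    def test_some_concerns_tested_but_not_tallied(self):
        cohort = CohortTable(
            [make_record("T1", overall="some_concerns", domain1="low"),
             make_record("T2", overall="low", domain1="low")]
        )
        report = run_cohort(cohort, seed=2)
        assert report.n_tested == 2
        assert report.n_unclassified_overall == 1
        assert report.confusion_overall.total == 1
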