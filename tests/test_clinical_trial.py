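"""Scoring-rule truth tables and the two-proportion non-inferiority test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gampk.clinical_trial import (
    Arm,
    ClinicalObservation,
    OutcomeStatus,
    TrialDataError,
    analyze_trial,
    classify_enrolment,
    classify_final_outcome,
    classify_removal,
    declaration_rate,
    dichotomize,
    noninferiority_analysis,
)


def obs(dep, resp, temp, day=0):
    return ClinicalObservation("s", "a", Arm.GAM, day, dep, resp, temp)


class TestClassificationRules:
    @pytest.mark.parametrize(
        ("dep", "resp", "temp", "eligible"),
        [
            (2, 2, 40.1, True),
            (2, 2, 40.0, False),  # fever must be strictly above 40.0
            (3, 1, 41.0, False),  # both scores must reach 2
            (1, 3, 41.0, False),
            (3, 3, 39.9, False),
            (2, 3, 40.1, True),
        ],
    )
    def test_enrolment_truth_table(self, dep, resp, temp, eligible):
        assert classify_enrolment(obs(dep, resp, temp)) is eligible

    @pytest.mark.parametrize(
        ("dep", "resp", "temp", "removed"),
        [
            (3, 0, 40.0, True),   # temperature boundary is inclusive here
            (0, 3, 41.0, True),   # either sign at 3 suffices
            (3, 3, 39.5, False),  # temperature gate
            (2, 2, 41.0, False),  # a score must reach 3
            (3, 3, 40.0, True),
            (0, 0, 40.1, False),
        ],
    )
    def test_removal_truth_table(self, dep, resp, temp, removed):
        assert classify_removal(obs(dep, resp, temp, day=3)) is removed

    def test_removal_threshold_configurable(self):
        o = obs(3, 0, 40.0, day=3)
        assert classify_removal(o)
        assert not classify_removal(o, temp_threshold=40.05)

    @pytest.mark.parametrize(
        ("dep", "resp", "temp", "outcome"),
        [
            (1, 0, 40.2, "failure"),
            (0, 1, 40.1, "failure"),
            (0, 2, 39.9, "success"),  # no fever, scores alone do not fail
            (0, 0, 41.0, "success"),  # fever with both scores zero
            (1, 1, 40.0, "success"),  # 40.0 is not > 40.0
            (3, 3, 40.1, "failure"),
            (0, 0, 39.0, "success"),
        ],
    )
    def test_day10_outcome_truth_table(self, dep, resp, temp, outcome):
        assert classify_final_outcome(obs(dep, resp, temp, day=10)) == outcome

    def test_final_outcome_requires_day10(self):
        with pytest.raises(TrialDataError):
            classify_final_outcome(obs(0, 0, 39.0, day=9))

    @pytest.mark.parametrize(
        ("dep", "resp", "temp", "expected"),
        [
            (1, 1, 40.0, (True, True, True)),
            (2, 1, 40.1, (False, True, False)),
            (1, 2, 39.0, (True, False, True)),
            (0, 3, 40.0, (True, False, True)),
        ],
    )
    def test_dichotomization(self, dep, resp, temp, expected):
        assert dichotomize(obs(dep, resp, temp, day=10)) == expected

    @given(
        st.integers(0, 3), st.integers(0, 3),
        st.floats(35.0, 43.0, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_rules_total_and_consistent(self, dep, resp, temp):
        o = obs(dep, resp, temp)
        enrol = classify_enrolment(o)
        removal = classify_removal(o)
        assert isinstance(enrol, bool) and isinstance(removal, bool)
        # an animal that merely meets the inclusion rule (scores of 2) is
        # not automatically a removal: removal needs a score of 3
        if enrol and dep < 3 and resp < 3:
            assert not removal

    def test_score_and_temperature_validation(self):
        with pytest.raises(ValueError):
            obs(4, 0, 39.0)
        with pytest.raises(ValueError):
            obs(0, 0, 34.0)


class TestNonInferiority:
    def test_field_study_counts_reproduce_published_intervals(self):
        expected = {
            (145, 150, 141, 151): (-0.02, 0.08),
            (143, 150, 144, 151): (-0.05, 0.05),
            (139, 150, 142, 151): (-0.07, 0.04),
            (139, 150, 137, 151): (-0.04, 0.08),
        }
        for (x1, n1, x2, n2), (lo, hi) in expected.items():
            res = noninferiority_analysis(x1, n1, x2, n2)
            assert round(res.ci_lower, 2) == lo
            assert round(res.ci_upper, 2) == hi
            assert res.non_inferior

    def test_hand_evaluated_symmetric_case(self):
        res = noninferiority_analysis(50, 100, 50, 100)
        assert res.diff == 0.0
        half = 1.960 * np.sqrt((1 / 100 + 1 / 100) * 0.25)
        assert res.ci_lower == pytest.approx(-half, rel=1e-12)
        assert res.ci_upper == pytest.approx(half, rel=1e-12)
        assert res.ci_lower == pytest.approx(-0.1386, abs=5e-5)
        assert not res.non_inferior  # lower limit falls below -0.10

    def test_degenerate_pooled_proportion_warns(self):
        with pytest.warns(RuntimeWarning):
            res = noninferiority_analysis(10, 10, 10, 10)
        assert res.ci_lower == res.ci_upper == 0.0

    def test_input_guards(self):
        with pytest.raises(ValueError):
            noninferiority_analysis(1, 0, 1, 2)
        with pytest.raises(ValueError):
            noninferiority_analysis(5, 4, 1, 2)

    @given(
        st.integers(1, 200).flatmap(
            lambda n1: st.tuples(
                st.integers(0, n1), st.just(n1),
                st.integers(1, 200).flatmap(
                    lambda n2: st.tuples(st.integers(0, n2), st.just(n2))
                ),
            )
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_swap_symmetry_and_ci_contains_diff(self, packed):
        x1, n1, (x2, n2) = packed
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = noninferiority_analysis(x1, n1, x2, n2)
            b = noninferiority_analysis(x2, n2, x1, n1)
        assert a.ci_lower <= a.diff <= a.ci_upper
        assert a.diff == pytest.approx(-b.diff)
        assert a.ci_lower == pytest.approx(-b.ci_upper)
        assert a.ci_upper == pytest.approx(-b.ci_lower)

    def test_ci_width_decreasing_in_n(self):
        small = noninferiority_analysis(90, 100, 85, 100)
        large = noninferiority_analysis(360, 400, 340, 400)
        assert (large.ci_upper - large.ci_lower) < (small.ci_upper - small.ci_lower)

    def test_margin_changes_decision_not_interval(self):
        tight = noninferiority_analysis(50, 100, 50, 100, margin=0.10)
        loose = noninferiority_analysis(50, 100, 50, 100, margin=0.20)
        assert (tight.ci_lower, tight.ci_upper) == (loose.ci_lower, loose.ci_upper)
        assert not tight.non_inferior and loose.non_inferior


class TestAnalyzeTrial:
    def test_reconstructed_field_study(self, trial_tables):
        observations, exits = trial_tables
        report = analyze_trial(observations, exits)
        assert report.n_analyzed == {"GAM": 150, "TIL": 151}
        assert report.n_removed_srd == {"GAM": 3, "TIL": 5}
        assert report.n_removed_non_srd == {"GAM": 3, "TIL": 1}
        expected = {
            "overall": (145, 141, -0.02, 0.08),
            "depression": (143, 144, -0.05, 0.05),
            "respiration": (139, 142, -0.07, 0.04),
            "temperature": (139, 137, -0.04, 0.08),
        }
        for name, (x1, x2, lo, hi) in expected.items():
            res = report.endpoints[name]
            assert report.successes[name] == {"GAM": x1, "TIL": x2}
            assert round(res.ci_lower, 2) == lo
            assert round(res.ci_upper, 2) == hi
            assert res.non_inferior
        assert round(report.endpoints["overall"].p1 * 100) == 97
        assert round(report.endpoints["overall"].p2 * 100) == 93

    def test_all_success_degenerate(self):
        import pandas as pd

        rows = []
        for i, arm in enumerate(["GAM", "TIL"] * 4):
            rows.append(dict(site="s", animal_id=f"x{i}", arm=arm, day=10,
                             depression=0, respiratory=0, temp_c=39.0))
        with pytest.warns(RuntimeWarning):
            report = analyze_trial(pd.DataFrame(rows))
        res = report.endpoints["overall"]
        assert res.diff == 0.0 and res.non_inferior

    def test_missing_day10_named(self, trial_tables):
        observations, exits = trial_tables
        broken = observations[
            ~((observations["animal_id"] == "T010") & (observations["day"] == 10))
        ]
        with pytest.raises(TrialDataError, match="T010"):
            analyze_trial(broken, exits)

    def test_outcome_statuses_recorded(self, trial_tables):
        observations, exits = trial_tables
        report = analyze_trial(observations, exits)
        statuses = {o.status for o in report.outcomes}
        assert statuses == {
            OutcomeStatus.SUCCESS,
            OutcomeStatus.FAILURE_DAY10,
            OutcomeStatus.REMOVED_SRD,
            OutcomeStatus.REMOVED_NON_SRD,
        }


class TestOperatingCharacteristics:
    def test_equal_proportions_declared_noninferior_about_97_5_pct(self):
        rng = np.random.default_rng(99)
        rate = declaration_rate(0.95, 0.95, 150, 151, replicates=2000, rng=rng)
        assert 0.95 <= rate <= 1.0
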