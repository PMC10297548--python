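import numpy as np
import pytest

from aeburden import (
    AEEpisode,
    PatientRecord,
    StudyWeekGrid,
    ValidationError,
    WeightMap,
    arm_series,
    at_risk,
    burden_matrix,
    cumulative_auc,
    effective_grade,
    patient_week_burden,
    per_patient_auc,
    series_to_tidy,
    weeks_covered,
)
from aeburden.engine import ArmBurdenSeries

import pandas as pd

from _oracle import (
    day_level_arm_auc,
    day_level_at_risk,
    day_level_burden,
    day_level_patient_auc,
    day_level_term_grades,
)
from conftest import random_study


def ep(pid, term, grade, start, end):
    return AEEpisode(pid, term, grade, start, end)


class TestWeeksCovered:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(5, 9, {1, 2}), (8, 8, {2}), (1, 7, {1}), (7, 8, {1, 2}), (15, 30, {3, 4, 5})],
    )
    def test_matches_day_enumeration(self, grid, start, end, expected):
        episode = ep("P", "x", 1, start, end)
        assert weeks_covered(episode, grid) == expected
        by_days = {grid.week_of_day(d) for d in range(start, end + 1)}
        assert weeks_covered(episode, grid) == by_days

    def test_requires_imputed_end(self, grid):
        episode = AEEpisode("P", "x", 1, 5, None, ongoing=True)
        with pytest.raises(ValidationError):
            weeks_covered(episode, grid)


class TestEffectiveGrade:
    @pytest.mark.parametrize("grades,expected", [([1, 3], 3), ([2], 2), ([2, 2, 2], 2)])
    def test_max_severity_rule(self, grades, expected):
        assert effective_grade(grades) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            effective_grade([])


class TestPatientWeekBurden:
    def test_grade_times_presence_sum(self, grid, worked_example):
        _, episodes = worked_example
        assert patient_week_burden("P01", 2, episodes, grid) == 3

    def test_no_active_episodes_is_zero(self, grid, worked_example):
        _, episodes = worked_example
        assert patient_week_burden("P01", 5, episodes, grid) == 0

    def test_repeated_term_uses_max_then_sums(self, grid):
        episodes = [
            ep("P01", "diarrhea", 1, 8, 10),
            ep("P01", "diarrhea", 3, 12, 13),
            ep("P01", "neutropenia", 2, 9, 14),
        ]
        assert patient_week_burden("P01", 2, episodes, grid) == 5

    def test_term_weights_scale_contributions(self, grid, worked_example):
        _, episodes = worked_example
        weights = WeightMap({"diarrhea": 2.0})
        assert patient_week_burden("P01", 2, episodes, grid, weights) == 2 * 2 + 1

    def test_term_filter_zeroes_other_terms(self, grid, worked_example):
        _, episodes = worked_example
        assert patient_week_burden(
            "P01", 2, episodes, grid, term_filter=["skin rash"]
        ) == 1


class TestAtRisk:
    @pytest.mark.parametrize(
        "last,week,expected", [(52, 8, True), (52, 9, False), (7, 1, True), (1, 1, True)]
    )
    def test_one_on_study_day_suffices(self, grid, last, week, expected):
        patient = PatientRecord("P", "a", last)
        assert at_risk(patient, week, grid) is expected
        assert at_risk(patient, week, grid) == day_level_at_risk(patient, week)


class TestArmSeries:
    def test_total_and_normalized(self, grid):
        patients = [PatientRecord("P1", "a", 14), PatientRecord("P2", "a", 14),
                    PatientRecord("P3", "b", 14)]
        episodes = [ep("P1", "diarrhea", 2, 1, 7), ep("P1", "skin rash", 1, 2, 5),
                    ep("P2", "nausea", 1, 3, 4)]
        series = arm_series("a", patients, episodes, grid)
        week1 = series.table.iloc[0]
        assert week1["total_burden"] == 4
        assert week1["n_at_risk"] == 2
        assert week1["normalized_burden"] == 2.0

    def test_worked_example_single_patient_normalizes_to_its_burden(
        self, grid, worked_example
    ):
        patient, episodes = worked_example
        other = PatientRecord("P02", "arm_b", 28)
        series = arm_series("arm_a", [patient, other], episodes, grid)
        assert series.table.loc[series.table["week"] == 2, "normalized_burden"].item() == 3.0

    def test_empty_risk_set_week_flagged_and_zero(self, grid):
        patients = [PatientRecord("P1", "a", 7), PatientRecord("P2", "b", 21)]
        series = arm_series("a", patients, [], grid)
        assert len(series.table) == 3  # shared axis spans the other arm's follow-up
        late = series.table.iloc[2]
        assert late["empty"] and late["normalized_burden"] == 0.0

    def test_unknown_arm_rejected(self, grid):
        with pytest.raises(ValidationError, match="no patients"):
            arm_series("zzz", [PatientRecord("P1", "a", 7)], [], grid)

    def test_min_risk_set_truncates_series(self, grid):
        patients = [PatientRecord("P1", "a", 7), PatientRecord("P2", "a", 28),
                    PatientRecord("P3", "b", 28)]
        series = arm_series("a", patients, [], grid, min_risk_set=2)
        assert list(series.table["week"]) == [1]

    def test_grade_decomposition_sums_to_total(self, grid):
        rng = np.random.default_rng(11)
        patients, episodes = random_study(rng, max_patients=8, max_episodes=20)
        for arm in ("arm_a", "arm_b"):
            series = arm_series(arm, patients, episodes, grid)
            parts = series.grade_components().to_numpy().sum(axis=1)
            np.testing.assert_allclose(parts, series.table["total_burden"], atol=1e-12)


class TestAUC:
    def test_rectangular_rule_sums_bars(self):
        table = pd.DataFrame(
            {"week": [1, 2, 3], "total_burden": [2, 1, 0.5],
             "n_at_risk": [2, 2, 2], "normalized_burden": [1.0, 0.5, 0.25],
             "empty": [False] * 3}
        )
        assert cumulative_auc(ArmBurdenSeries("a", table)) == 1.75

    def test_zero_series(self, grid):
        patients = [PatientRecord("P1", "a", 14), PatientRecord("P2", "b", 14)]
        assert cumulative_auc(arm_series("a", patients, [], grid)) == 0.0

    def test_matches_day_level_oracle_on_simulated_arm(self, grid):
        rng = np.random.default_rng(5)
        for _ in range(10):
            patients, episodes = random_study(rng, max_patients=10, max_episodes=25)
            for arm in ("arm_a", "arm_b"):
                series = arm_series(arm, patients, episodes, grid)
                assert cumulative_auc(series) == pytest.approx(
                    day_level_arm_auc(arm, patients, episodes), abs=1e-9
                )


class TestPerPatientAUC:
    def test_single_worked_example_week(self, grid, worked_example):
        patient, episodes = worked_example
        # diarrhea spans weeks 2-3, rash week 2: AUC = 3 + 2
        assert per_patient_auc(patient, episodes, grid) == 5
        only_week2 = [e for e in episodes if e.end_day <= 14]
        assert per_patient_auc(patient, only_week2, grid) == 1

    def test_ae_free_patient_is_zero(self, grid):
        assert per_patient_auc(PatientRecord("P", "a", 30), [], grid) == 0

    def test_matches_day_level_oracle(self, grid):
        rng = np.random.default_rng(9)
        for _ in range(10):
            patients, episodes = random_study(rng)
            for patient in patients:
                assert per_patient_auc(patient, episodes, grid) == pytest.approx(
                    day_level_patient_auc(patient, episodes), abs=1e-9
                )

    def test_unknown_patient_id_rejected(self, grid):
        with pytest.raises(ValidationError, match="unknown"):
            per_patient_auc("P99", [], grid, patients=[PatientRecord("P1", "a", 7)])


class TestOracleEquivalence:
    """The interval-arithmetic engine against full day-level expansion."""

    def test_burden_matrix_matches_oracle_entrywise(self, grid):
        rng = np.random.default_rng(123)
        for _ in range(25):
            patients, episodes = random_study(rng, max_patients=10, max_weeks=8,
                                              max_episodes=30)
            matrix = burden_matrix(episodes, grid)
            assert matrix.term_entries() == day_level_term_grades(episodes)
            assert matrix.entries() == pytest.approx(day_level_burden(episodes))


class TestAlgebraicProperties:
    def test_adding_episode_never_decreases_burden(self, grid):
        rng = np.random.default_rng(21)
        for _ in range(10):
            patients, episodes = random_study(rng)
            target = patients[0]
            extra = AEEpisode(target.patient_id, "fatigue", 3, 1,
                              min(10, target.last_study_day))
            before = day_level_burden(episodes)
            after = burden_matrix(episodes + [extra], grid).entries()
            for key, value in before.items():
                assert after.get(key, 0.0) >= value - 1e-12

    def test_raising_grade_never_decreases_burden(self, grid):
        episodes = [ep("P", "diarrhea", 2, 3, 10), ep("P", "diarrhea", 4, 5, 6)]
        low = burden_matrix(episodes, grid).entries()
        episodes_hi = [ep("P", "diarrhea", 3, 3, 10), ep("P", "diarrhea", 4, 5, 6)]
        high = burden_matrix(episodes_hi, grid).entries()
        for key in low:
            assert high[key] >= low[key]

    def test_term_additivity_under_unit_weights(self, grid):
        rng = np.random.default_rng(31)
        for _ in range(10):
            patients, episodes = random_study(rng)
            terms = sorted({e.term for e in episodes})
            overall = burden_matrix(episodes, grid).entries()
            summed: dict = {}
            for term in terms:
                for key, val in burden_matrix(episodes, grid, term_filter=[term]).entries().items():
                    summed[key] = summed.get(key, 0.0) + val
            assert summed == pytest.approx(overall)

    def test_full_term_filter_reproduces_unfiltered(self, grid):
        rng = np.random.default_rng(41)
        patients, episodes = random_study(rng, max_episodes=25)
        terms = {e.term for e in episodes}
        unfiltered = burden_matrix(episodes, grid).entries()
        filtered = burden_matrix(episodes, grid, term_filter=terms).entries()
        assert filtered == unfiltered

    def test_normalized_burden_bounded(self, grid):
        rng = np.random.default_rng(51)
        for _ in range(5):
            patients, episodes = random_study(rng, max_episodes=30)
            n_terms = max(1, len({e.term for e in episodes}))
            for arm in ("arm_a", "arm_b"):
                series = arm_series(arm, patients, episodes, grid)
                assert (series.normalized >= 0).all()
                assert (series.normalized <= 5 * n_terms).all()


def test_series_to_tidy_long_format(grid):
    patients = [PatientRecord("P1", "a", 14), PatientRecord("P2", "b", 7)]
    episodes = [ep("P1", "diarrhea", 2, 1, 3)]
    tidy = series_to_tidy({
        arm: arm_series(arm, patients, episodes, grid) for arm in ("a", "b")
    })
    assert list(tidy.columns[:5]) == ["arm", "week", "total_burden", "n_at_risk",
                                      "normalized_burden"]
    assert set(tidy["arm"]) == {"a", "b"}
    assert len(tidy) == 4  # 2 arms x 2 weeks
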