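"""Weekly burden-of-therapy computation.

The weekly burden for a patient is the sum, over distinct AE terms active
that week, of ``weight(term) x grade`` — the grade-times-presence rule.
When the same term is reported more than once in a week (possibly at
different severities), only the highest grade counts. Arm-level weekly
burden is the total over the arm's patients divided by the number of
patients at risk that week, and the cumulative burden of an arm is the
area under that weekly curve by the rectangular (sum-of-bars) rule, so
the AUC equals the sum of the bars displayed on the burden chart.

Implementation notes
--------------------
An episode contributes to every week its closed day interval intersects
(the weekly estimate has no sub-week resolution, so presence any single
day counts for the whole week). A patient is at risk in a week when their
last study day falls on or after the week's first day. All episodes must
have concrete end days — run :func:`aeburden.model.impute_end_dates`
first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    MAX_GRADE,
    AEEpisode,
    PatientRecord,
    StudyWeekGrid,
    ValidationError,
    normalize_term,
    patients_by_id,
)

__all__ = [
    "WeightMap",
    "BurdenMatrix",
    "ArmBurdenSeries",
    "weeks_covered",
    "effective_grade",
    "burden_matrix",
    "patient_week_burden",
    "at_risk",
    "arm_series",
    "cumulative_auc",
    "per_patient_auc",
]


class WeightMap:
    """Per-term positive weights with a unit default.

    Severity weighting is the grade itself and is always applied; a
    WeightMap adds an optional clinical-relevance weight on top of it.
    Term keys are normalized the same way episode terms are.
    """

    def __init__(self, weights: Mapping[str, float] | None = None, default: float = 1.0):
        if default <= 0:
            raise ValidationError(f"default weight must be > 0, got {default}")
        self.default = float(default)
        self._weights: dict[str, float] = {}
        for term, weight in (weights or {}).items():
            w = float(weight)
            if w <= 0:
                raise ValidationError(f"weight for {term!r} must be > 0, got {w}")
            self._weights[normalize_term(term)] = w

    def __call__(self, term: str) -> float:
        return self._weights.get(term, self.default)

    def __repr__(self) -> str:  # pragma: no cover
        return f"WeightMap({self._weights!r}, default={self.default})"


def _normalize_filter(term_filter: Iterable[str] | None) -> frozenset[str] | None:
    if term_filter is None:
        return None
    return frozenset(normalize_term(t) for t in term_filter)


def weeks_covered(episode: AEEpisode, grid: StudyWeekGrid) -> set[int]:
    """Week indices whose day range intersects the episode's interval."""
    if episode.end_day is None:
        raise ValidationError(
            "episode has no end day; run impute_end_dates before weekly expansion"
        )
    first = grid.week_of_day(episode.start_day)
    last = grid.week_of_day(episode.end_day)
    return set(range(first, last + 1))


def effective_grade(grades: Sequence[int]) -> int:
    """Severity of one term in one week: the highest reported grade."""
    if len(grades) == 0:
        raise ValidationError("effective_grade requires at least one grade")
    return max(grades)


def at_risk(patient: PatientRecord, week: int, grid: StudyWeekGrid) -> bool:
    """True when the patient is on study for at least one day of the week."""
    first_day, _ = grid.week_days(week)
    return patient.last_study_day >= first_day


@dataclass(frozen=True)
class BurdenMatrix:
    """Per-(patient, week, term) effective grades and derived burden scores.

    ``table`` is a tidy frame with columns ``patient_id``, ``week``,
    ``term``, ``grade`` (the week's effective = maximum grade for that
    term) and ``weight``; one row per active (patient, week, term).
    """

    table: pd.DataFrame

    _COLUMNS = ("patient_id", "week", "term", "grade", "weight")

    def entries(self) -> dict[tuple[str, int], float]:
        """Mapping (patient_id, week) -> burden score."""
        if self.table.empty:
            return {}
        burden = self.table["grade"] * self.table["weight"]
        grouped = burden.groupby(
            [self.table["patient_id"], self.table["week"]]
        ).sum()
        return {(pid, int(week)): float(v) for (pid, week), v in grouped.items()}

    def term_entries(self) -> dict[tuple[str, int, str], int]:
        """Mapping (patient_id, week, term) -> effective grade."""
        return {
            (row.patient_id, int(row.week), row.term): int(row.grade)
            for row in self.table.itertuples(index=False)
        }


def burden_matrix(
    episodes: Iterable[AEEpisode],
    grid: StudyWeekGrid,
    weights: WeightMap | None = None,
    term_filter: Iterable[str] | None = None,
) -> BurdenMatrix:
    """Expand episodes to weeks and reduce to per-(patient, week, term)
    effective grades."""
    weights = weights or WeightMap()
    selected = _normalize_filter(term_filter)
    rows: list[tuple[str, int, str, int]] = []
    for ep in episodes:
        if selected is not None and ep.term not in selected:
            continue
        for week in weeks_covered(ep, grid):
            rows.append((ep.patient_id, week, ep.term, ep.grade))
    frame = pd.DataFrame(rows, columns=["patient_id", "week", "term", "grade"])
    if not frame.empty:
        frame = (
            frame.groupby(["patient_id", "week", "term"], as_index=False)["grade"]
            .max()
            .sort_values(["patient_id", "week", "term"], ignore_index=True)
        )
    frame["weight"] = [weights(t) for t in frame["term"]] if not frame.empty else []
    return BurdenMatrix(frame)


def patient_week_burden(
    patient_id: str,
    week: int,
    episodes: Iterable[AEEpisode],
    grid: StudyWeekGrid,
    weights: WeightMap | None = None,
    term_filter: Iterable[str] | None = None,
) -> float:
    """Burden score of one patient in one week.

    Sum over distinct active terms of ``weight(term) x`` highest grade of
    that term in the week; with unit weights this is an integer.
    """
    weights = weights or WeightMap()
    selected = _normalize_filter(term_filter)
    best: dict[str, int] = {}
    for ep in episodes:
        if ep.patient_id != patient_id:
            continue
        if selected is not None and ep.term not in selected:
            continue
        if week in weeks_covered(ep, grid):
            best[ep.term] = max(best.get(ep.term, 0), ep.grade)
    return float(sum(weights(term) * grade for term, grade in best.items()))


@dataclass(frozen=True)
class ArmBurdenSeries:
    """Weekly burden of one treatment arm.

    ``table`` columns: ``week``, ``total_burden``, ``n_at_risk``,
    ``normalized_burden`` (0 and flagged ``empty`` when nobody is at
    risk), and ``grade_1`` ... ``grade_5`` decomposing the total burden
    by severity for the stacked chart.
    """

    arm: str
    table: pd.DataFrame
    week_length_days: int = 7

    @property
    def weeks(self) -> np.ndarray:
        return self.table["week"].to_numpy()

    @property
    def normalized(self) -> np.ndarray:
        return self.table["normalized_burden"].to_numpy()

    def grade_components(self, normalized: bool = False) -> pd.DataFrame:
        """Per-grade weekly burden, optionally divided by the risk set."""
        cols = [f"grade_{g}" for g in range(1, MAX_GRADE + 1)]
        comp = self.table[cols].copy()
        if normalized:
            denom = self.table["n_at_risk"].replace(0, np.nan)
            comp = comp.div(denom, axis=0).fillna(0.0)
        return comp


def _burden_pivots(
    patients: Sequence[PatientRecord],
    episodes: Iterable[AEEpisode],
    grid: StudyWeekGrid,
    weights: WeightMap | None,
    term_filter: Iterable[str] | None,
    n_weeks: int | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Dense per-patient-by-week arrays used by arm aggregation and the
    permutation test.

    Returns ``(patient_ids, B, R, G, weeks)`` where ``B[i, w]`` is patient
    i's burden in week w+1, ``R[i, w]`` their at-risk indicator and
    ``G[g-1, i, w]`` the grade-g component of ``B``.
    """
    ids = [p.patient_id for p in patients]
    patients_by_id(patients)  # duplicate check
    if n_weeks is None:
        n_weeks = grid.n_weeks(patients)
    row_of = {pid: i for i, pid in enumerate(ids)}
    B = np.zeros((len(ids), n_weeks))
    G = np.zeros((MAX_GRADE, len(ids), n_weeks))
    matrix = burden_matrix(episodes, grid, weights, term_filter)
    for row in matrix.table.itertuples(index=False):
        i = row_of.get(row.patient_id)
        if i is None:
            raise ValidationError(
                f"episode references unknown patient {row.patient_id!r}"
            )
        w = int(row.week) - 1
        if w >= n_weeks:
            continue
        contribution = row.weight * row.grade
        B[i, w] += contribution
        G[int(row.grade) - 1, i, w] += contribution
    last_days = np.array([p.last_study_day for p in patients])
    week_first_days = np.arange(n_weeks) * grid.week_length_days + 1
    R = last_days[:, None] >= week_first_days[None, :]
    return ids, B, R, G, np.arange(1, n_weeks + 1)


def arm_series(
    arm_label: str,
    patients: Sequence[PatientRecord],
    episodes: Iterable[AEEpisode],
    grid: StudyWeekGrid,
    weights: WeightMap | None = None,
    term_filter: Iterable[str] | None = None,
    n_weeks: int | None = None,
    min_risk_set: int | None = None,
) -> ArmBurdenSeries:
    """Weekly total / at-risk / normalized burden for one arm.

    ``n_weeks`` defaults to the span of the longest-followed patient in
    ``patients`` (pass all study patients to share a week axis between
    arms). ``min_risk_set`` truncates the series at the first week whose
    risk set falls below the cutoff, guarding against the small-denominator
    instability of late weeks.
    """
    arm_patients = [p for p in patients if p.arm == arm_label]
    if not arm_patients:
        raise ValidationError(f"no patients in arm {arm_label!r}")
    if n_weeks is None:
        n_weeks = grid.n_weeks(patients)
    arm_ids = {p.patient_id for p in arm_patients}
    arm_episodes = [ep for ep in episodes if ep.patient_id in arm_ids]
    _, B, R, G, weeks = _burden_pivots(
        arm_patients, arm_episodes, grid, weights, term_filter, n_weeks
    )
    # burden only counts for at-risk patients; truncation at last_study_day
    # already guarantees B == B * R, enforced here for safety
    B = B * R
    G = G * R[None, :, :]
    total = B.sum(axis=0)
    n_at_risk = R.sum(axis=0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(n_at_risk > 0, total / np.maximum(n_at_risk, 1), 0.0)
    frame = pd.DataFrame(
        {
            "week": weeks,
            "total_burden": total,
            "n_at_risk": n_at_risk,
            "normalized_burden": normalized,
            "empty": n_at_risk == 0,
        }
    )
    for g in range(1, MAX_GRADE + 1):
        frame[f"grade_{g}"] = G[g - 1].sum(axis=0)
    if min_risk_set is not None:
        below = np.nonzero(n_at_risk < min_risk_set)[0]
        if below.size:
            frame = frame.iloc[: below[0]].reset_index(drop=True)
    return ArmBurdenSeries(arm=arm_label, table=frame, week_length_days=grid.week_length_days)


def cumulative_auc(series: ArmBurdenSeries) -> float:
    """Total accumulated burden: sum of weekly normalized burden x 1 week.

    Rectangular rule, so the AUC equals the sum of the chart's bars; weeks
    with an empty risk set contribute 0.
    """
    if series.table.empty:
        raise ValidationError("cannot integrate an empty burden series")
    return float(series.table["normalized_burden"].sum())


def per_patient_auc(
    patient: PatientRecord | str,
    episodes: Iterable[AEEpisode],
    grid: StudyWeekGrid,
    weights: WeightMap | None = None,
    term_filter: Iterable[str] | None = None,
    patients: Sequence[PatientRecord] | None = None,
) -> float:
    """Sum of one patient's weekly burdens over their at-risk weeks.

    A per-patient summary used by the resampling comparison; dividing each
    week's contribution by that week's arm risk-set size and summing over
    an arm reconstructs the arm AUC.
    """
    if isinstance(patient, str):
        if patients is None:
            raise ValidationError("pass PatientRecord or provide the patients list")
        index = patients_by_id(patients)
        if patient not in index:
            raise ValidationError(f"unknown patient {patient!r}")
        patient = index[patient]
    own = [ep for ep in episodes if ep.patient_id == patient.patient_id]
    matrix = burden_matrix(own, grid, weights, term_filter)
    total = 0.0
    for (pid, week), score in matrix.entries().items():
        if at_risk(patient, week, grid):
            total += score
    return total


def series_to_tidy(series_by_arm: Mapping[str, ArmBurdenSeries]) -> pd.DataFrame:
    """Long-format export: one row per (arm, week) with totals, risk set,
    normalized burden and per-grade columns."""
    frames = []
    for arm, series in series_by_arm.items():
        frame = series.table.copy()
        frame.insert(0, "arm", arm)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
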