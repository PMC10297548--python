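"""Domain types for adverse-event burden analysis.

The units of analysis are treatment-emergent adverse-event (TEAE) episodes
recorded as closed study-day intervals with a CTCAE-style severity grade
(1 mild ... 5 death), and a per-patient disposition record giving arm
membership and the last day on study.

Conventions
-----------
* Study days are 1-based; day 1 is the first treatment day.
* AE intervals are inclusive on both ends.
* Study week ``w`` covers days ``[(w-1)*L + 1, w*L]`` where ``L`` is the
  week length in days (default 7). The grid is anchored to study day 1
  globally, not to per-patient enrollment; because start days are already
  relative to first treatment, the two coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AEEpisode",
    "PatientRecord",
    "StudyWeekGrid",
    "ValidationError",
    "impute_end_dates",
    "normalize_term",
]

MIN_GRADE = 1
MAX_GRADE = 5


class ValidationError(ValueError):
    """A record violates a domain invariant."""


def normalize_term(term: str) -> str:
    """Case-fold and trim an AE term; no synonym or dictionary mapping."""
    normalized = " ".join(str(term).split()).casefold()
    if not normalized:
        raise ValidationError("AE term is empty after whitespace normalization")
    return normalized


@dataclass(frozen=True)
class AEEpisode:
    """One reported TEAE interval with severity grade.

    ``end_day`` may be ``None`` only when ``ongoing`` is set, meaning the
    event had no recorded resolution; :func:`impute_end_dates` replaces it
    with the patient's last study day.
    """

    patient_id: str
    term: str
    grade: int
    start_day: int
    end_day: int | None = None
    ongoing: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "term", normalize_term(self.term))
        if not isinstance(self.grade, int) or isinstance(self.grade, bool):
            raise ValidationError(f"grade must be an integer, got {self.grade!r}")
        if not MIN_GRADE <= self.grade <= MAX_GRADE:
            raise ValidationError(
                f"grade must be in [{MIN_GRADE}, {MAX_GRADE}], got {self.grade}"
            )
        if self.start_day < 1:
            raise ValidationError(f"start_day must be >= 1, got {self.start_day}")
        if self.end_day is None:
            if not self.ongoing:
                raise ValidationError(
                    "end_day absent but episode not flagged ongoing "
                    f"(patient {self.patient_id!r}, term {self.term!r})"
                )
        else:
            if self.end_day < self.start_day:
                raise ValidationError(
                    f"end_day {self.end_day} precedes start_day {self.start_day}"
                )

    @property
    def closed(self) -> bool:
        return self.end_day is not None


@dataclass(frozen=True)
class PatientRecord:
    """Arm membership and on-study interval for one patient.

    ``last_study_day`` is the final study day the patient contributes
    observation time; it defines risk-set membership and is the imputed
    end date of ongoing AEs.
    """

    patient_id: str
    arm: str
    last_study_day: int

    def __post_init__(self) -> None:
        if self.last_study_day < 1:
            raise ValidationError(
                f"last_study_day must be >= 1, got {self.last_study_day}"
            )
        if not str(self.arm).strip():
            raise ValidationError(f"empty arm label for patient {self.patient_id!r}")


@dataclass(frozen=True)
class StudyWeekGrid:
    """Mapping between study days and 1-based study weeks."""

    week_length_days: int = 7

    def __post_init__(self) -> None:
        if self.week_length_days < 1:
            raise ValidationError("week_length_days must be >= 1")

    def week_of_day(self, day: int) -> int:
        if day < 1:
            raise ValidationError(f"study day must be >= 1, got {day}")
        return (day - 1) // self.week_length_days + 1

    def week_days(self, week: int) -> tuple[int, int]:
        """Inclusive (first, last) study day of a week."""
        if week < 1:
            raise ValidationError(f"week index must be >= 1, got {week}")
        first = (week - 1) * self.week_length_days + 1
        return first, first + self.week_length_days - 1

    def n_weeks(self, patients: Iterable[PatientRecord]) -> int:
        """Number of weeks spanned by the latest last_study_day."""
        last = max((p.last_study_day for p in patients), default=0)
        if last == 0:
            return 0
        return math.ceil(last / self.week_length_days)


def patients_by_id(patients: Iterable[PatientRecord]) -> dict[str, PatientRecord]:
    index: dict[str, PatientRecord] = {}
    for p in patients:
        if p.patient_id in index:
            raise ValidationError(f"duplicate patient_id {p.patient_id!r}")
        index[p.patient_id] = p
    return index


def arm_labels(patients: Sequence[PatientRecord]) -> tuple[str, str]:
    """The study's two arm labels, sorted; errors if there are not exactly two."""
    labels = sorted({p.arm for p in patients})
    if len(labels) != 2:
        raise ValidationError(
            f"expected exactly 2 arm labels, found {len(labels)}: {labels}"
        )
    return labels[0], labels[1]


def impute_end_dates(
    episodes: Iterable[AEEpisode],
    patients: Iterable[PatientRecord] | Mapping[str, PatientRecord],
) -> list[AEEpisode]:
    """Resolve ongoing episodes and truncate intervals to the on-study window.

    Ongoing episodes receive ``end_day = last_study_day`` of their patient.
    Closed episodes extending past the patient's last study day are truncated
    to it, so no burden is ever counted after observation stops.
    """
    index = patients if isinstance(patients, Mapping) else patients_by_id(patients)
    out: list[AEEpisode] = []
    for ep in episodes:
        patient = index.get(ep.patient_id)
        if patient is None:
            raise ValidationError(
                f"episode references unknown patient {ep.patient_id!r}"
            )
        last = patient.last_study_day
        if ep.start_day > last:
            raise ValidationError(
                f"episode for patient {ep.patient_id!r} starts on day "
                f"{ep.start_day}, after last study day {last}"
            )
        if ep.end_day is None:
            out.append(replace(ep, end_day=last, ongoing=False))
        elif ep.end_day > last:
            out.append(replace(ep, end_day=last))
        else:
            out.append(ep)
    return out
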