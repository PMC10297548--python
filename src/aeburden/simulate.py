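"""Synthetic two-arm trial generator with controllable burden structure.

Emulates the AE listing and disposition tables of a two-arm oncology
trial: per patient, time on study follows a weekly dropout process; per
on-study week and AE term, episode onset is Bernoulli with a (possibly
time-varying) weekly hazard, severity is drawn from a per-term grade
distribution over 1-5, and episode duration is geometric in days.
Episodes running past the patient's last study day are either truncated
or flagged ongoing, exercising the end-date imputation path downstream.

Grade transitions within an episode are not simulated; varying severity
of one term within a week arises from overlapping episodes, which
exercises the max-severity rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .model import AEEpisode, PatientRecord, ValidationError

__all__ = [
    "ArmSimConfig",
    "TrialSimConfig",
    "simulate_trial",
    "preset_rash_like",
    "symmetric_null_config",
    "DEFAULT_TERMS",
]

#: common solid-tumour chemotherapy TEAE terms used by the presets
DEFAULT_TERMS = ("diarrhea", "neutropenia", "alopecia", "skin rash", "sensory neuropathy")


def _check_prob(p: float, what: str) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"{what} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class ArmSimConfig:
    """AE-generating process of one arm.

    ``onset_hazard`` maps term -> weekly onset probability, either a
    scalar or a per-week vector (cycled/truncated to the trial length)
    for time-varying hazards. ``grade_dist`` maps term -> probability
    vector over grades 1-5. ``mean_duration_days`` maps term -> mean of
    the geometric episode duration (>= 1 day).
    """

    label: str
    n_patients: int
    onset_hazard: Mapping[str, float | Sequence[float]]
    grade_dist: Mapping[str, Sequence[float]]
    mean_duration_days: Mapping[str, float]
    weekly_dropout: float = 0.05

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError(f"arm {self.label!r}: n_patients must be >= 1")
        _check_prob(self.weekly_dropout, f"arm {self.label!r} weekly_dropout")
        for term, hazard in self.onset_hazard.items():
            values = np.atleast_1d(np.asarray(hazard, dtype=float))
            for v in values:
                _check_prob(float(v), f"arm {self.label!r} onset hazard for {term!r}")
            dist = np.asarray(self.grade_dist[term], dtype=float)
            if dist.shape != (5,) or (dist < 0).any() or abs(dist.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"arm {self.label!r}: grade distribution for {term!r} must be "
                    f"a length-5 probability vector summing to 1"
                )
            if self.mean_duration_days[term] < 1:
                raise ValidationError(
                    f"arm {self.label!r}: mean duration for {term!r} must be >= 1 day"
                )

    def hazard_for_week(self, term: str, week: int, max_weeks: int) -> float:
        """Weekly onset probability of ``term`` in 1-based ``week``."""
        hazard = self.onset_hazard[term]
        values = np.atleast_1d(np.asarray(hazard, dtype=float))
        if values.size == 1:
            return float(values[0])
        return float(values[min(week - 1, values.size - 1)])

    def scaled_hazards(self, factor: float) -> "ArmSimConfig":
        """Copy of this arm with every onset hazard multiplied by ``factor``
        (clipped to 1); used for power/monotonicity experiments."""
        scaled = {
            term: np.clip(np.atleast_1d(np.asarray(h, dtype=float)) * factor, 0, 1)
            for term, h in self.onset_hazard.items()
        }
        return replace(self, onset_hazard=scaled)


@dataclass(frozen=True)
class TrialSimConfig:
    """Full two-arm trial configuration.

    Defaults echo a 150-patient study split 123 / 27 between arms.
    ``ongoing_prob`` is the probability that an episode still active at
    the patient's last study day is recorded as ongoing (end date blank)
    rather than truncated by the data-entry process.
    """

    arms: tuple[ArmSimConfig, ArmSimConfig]
    max_weeks: int = 24
    week_length_days: int = 7
    ongoing_prob: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if len(self.arms) != 2 or self.arms[0].label == self.arms[1].label:
            raise ValidationError("exactly two distinctly labelled arms required")
        if self.max_weeks < 1:
            raise ValidationError("max_weeks must be >= 1")
        _check_prob(self.ongoing_prob, "ongoing_prob")
        for arm in self.arms:
            arm.validate()


def _simulate_patient(
    rng: np.random.Generator,
    pid: str,
    arm: ArmSimConfig,
    config: TrialSimConfig,
) -> tuple[PatientRecord, list[AEEpisode]]:
    L = config.week_length_days
    # weekly dropout: patient leaves during week w with prob q after each week
    weeks_on = config.max_weeks
    for w in range(1, config.max_weeks):
        if rng.random() < arm.weekly_dropout:
            weeks_on = w
            break
    if weeks_on == config.max_weeks:
        last_day = config.max_weeks * L
    else:  # mid-week departure: last day uniform within the dropout week
        first, lastd = (weeks_on - 1) * L + 1, weeks_on * L
        last_day = int(rng.integers(first, lastd + 1))
    record = PatientRecord(pid, arm.label, last_day)

    episodes: list[AEEpisode] = []
    for week in range(1, weeks_on + 1):
        week_first = (week - 1) * L + 1
        week_last_onstudy = min(week * L, last_day)
        if week_first > last_day:
            break
        for term in arm.onset_hazard:
            hazard = arm.hazard_for_week(term, week, config.max_weeks)
            if rng.random() >= hazard:
                continue
            start = int(rng.integers(week_first, week_last_onstudy + 1))
            grade = int(rng.choice(5, p=np.asarray(arm.grade_dist[term], float)) + 1)
            mean = arm.mean_duration_days[term]
            duration = int(rng.geometric(1.0 / mean))
            end = start + duration - 1
            if end > last_day:
                if rng.random() < config.ongoing_prob:
                    episodes.append(AEEpisode(pid, term, grade, start, None, ongoing=True))
                else:
                    episodes.append(AEEpisode(pid, term, grade, start, last_day))
            else:
                episodes.append(AEEpisode(pid, term, grade, start, end))
    return record, episodes


def simulate_trial(
    config: TrialSimConfig, seed: int | None = None
) -> tuple[list[PatientRecord], list[AEEpisode]]:
    """Draw one trial: disposition records and a TEAE listing.

    Reproducible given the seed (``seed`` overrides ``config.seed``).
    No episode starts after its patient's last study day, and ongoing
    flags appear only on episodes reaching the end of follow-up.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    patients: list[PatientRecord] = []
    episodes: list[AEEpisode] = []
    for arm_idx, arm in enumerate(config.arms):
        prefix = chr(ord("A") + arm_idx)
        for i in range(arm.n_patients):
            pid = f"{prefix}{i + 1:03d}"
            record, eps = _simulate_patient(rng, pid, arm, config)
            patients.append(record)
            episodes.extend(eps)
    return patients, episodes


def _ramp(start: float, stop: float, n: int) -> np.ndarray:
    return np.linspace(start, stop, n)


def preset_rash_like(
    n_arm_a: int = 123,
    n_arm_b: int = 27,
    max_weeks: int = 24,
    seed: int = 0,
) -> TrialSimConfig:
    """A two-arm preset with the qualitative toxicity-over-time structure
    of an EGFR-inhibitor arm versus an oxaliplatin-based arm.

    Arm A ("gem/erlotinib"-like): skin rash concentrated here with a
    stable hazard; diarrhea hazard roughly stable; negligible neuropathy.
    Arm B ("FOLFIRINOX"-like): sensory neuropathy hazard ramping up with
    cumulative exposure; diarrhea and neutropenia hazards decaying over
    time (emulating dose reductions); rash essentially absent.
    """
    w = max_weeks
    mild = np.array([0.6, 0.3, 0.08, 0.02, 0.0])
    moderate = np.array([0.35, 0.40, 0.20, 0.05, 0.0])
    severe = np.array([0.20, 0.35, 0.30, 0.14, 0.01])
    arm_a = ArmSimConfig(
        label="gem/erlotinib",
        n_patients=n_arm_a,
        onset_hazard={
            "diarrhea": 0.14,
            "neutropenia": 0.12,
            "alopecia": 0.05,
            "skin rash": 0.30,
            "sensory neuropathy": 0.01,
        },
        grade_dist={
            "diarrhea": mild,
            "neutropenia": moderate,
            "alopecia": mild,
            "skin rash": moderate,
            "sensory neuropathy": mild,
        },
        mean_duration_days={
            "diarrhea": 5.0,
            "neutropenia": 7.0,
            "alopecia": 60.0,
            "skin rash": 21.0,
            "sensory neuropathy": 14.0,
        },
        weekly_dropout=0.04,
    )
    arm_b = ArmSimConfig(
        label="FOLFIRINOX",
        n_patients=n_arm_b,
        onset_hazard={
            "diarrhea": _ramp(0.30, 0.05, w),
            "neutropenia": _ramp(0.25, 0.06, w),
            "alopecia": 0.08,
            "skin rash": 0.01,
            "sensory neuropathy": _ramp(0.02, 0.40, w),
        },
        grade_dist={
            "diarrhea": moderate,
            "neutropenia": severe,
            "alopecia": mild,
            "skin rash": mild,
            "sensory neuropathy": moderate,
        },
        mean_duration_days={
            "diarrhea": 5.0,
            "neutropenia": 7.0,
            "alopecia": 60.0,
            "skin rash": 10.0,
            "sensory neuropathy": 28.0,
        },
        weekly_dropout=0.04,
    )
    config = TrialSimConfig(
        arms=(arm_a, arm_b), max_weeks=max_weeks, seed=seed
    )
    config.validate()
    return config


def symmetric_null_config(
    n_per_arm: int = 30,
    max_weeks: int = 12,
    onset: float = 0.15,
    weekly_dropout: float = 0.05,
    seed: int = 0,
) -> TrialSimConfig:
    """Two arms with an identical AE-generating process — the null
    configuration for type-I-error experiments."""
    grade = np.array([0.4, 0.3, 0.2, 0.08, 0.02])
    def make(label: str) -> ArmSimConfig:
        return ArmSimConfig(
            label=label,
            n_patients=n_per_arm,
            onset_hazard={t: onset for t in DEFAULT_TERMS},
            grade_dist={t: grade for t in DEFAULT_TERMS},
            mean_duration_days={t: 7.0 for t in DEFAULT_TERMS},
            weekly_dropout=weekly_dropout,
        )
    config = TrialSimConfig(arms=(make("arm_a"), make("arm_b")),
                            max_weeks=max_weeks, seed=seed)
    config.validate()
    return config
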