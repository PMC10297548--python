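from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from aeburden import AEEpisode, PatientRecord, StudyWeekGrid, impute_end_dates

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

TERMS = ("diarrhea", "neutropenia", "skin rash")


@pytest.fixture
def grid():
    return StudyWeekGrid()


@pytest.fixture
def worked_example():
    """One patient with grade-2 diarrhea and grade-1 skin rash overlapping
    study week 2 (days 8-14)."""
    patient = PatientRecord("P01", "arm_a", last_study_day=28)
    episodes = [
        AEEpisode("P01", "diarrhea", 2, start_day=8, end_day=21),
        AEEpisode("P01", "skin rash", 1, start_day=10, end_day=12),
    ]
    return patient, episodes


def random_study(rng: np.random.Generator, max_patients=8, max_weeks=6,
                 max_episodes=15, terms=TERMS, min_patients=2):
    """A small random two-arm study with imputed episodes (shared helper
    for oracle-equivalence checks)."""
    n = int(rng.integers(min_patients, max_patients + 1))
    patients = [
        PatientRecord(
            f"P{i:02d}",
            "arm_a" if i % 2 == 0 else "arm_b",
            int(rng.integers(1, max_weeks * 7 + 1)),
        )
        for i in range(n)
    ]
    episodes = []
    for _ in range(int(rng.integers(0, max_episodes + 1))):
        p = patients[int(rng.integers(0, n))]
        start = int(rng.integers(1, p.last_study_day + 1))
        if rng.random() < 0.2:
            ep = AEEpisode(
                p.patient_id, terms[int(rng.integers(0, len(terms)))],
                int(rng.integers(1, 6)), start, None, ongoing=True,
            )
        else:
            end = start + int(rng.integers(0, 21))
            ep = AEEpisode(
                p.patient_id, terms[int(rng.integers(0, len(terms)))],
                int(rng.integers(1, 6)), start, end,
            )
        episodes.append(ep)
    return patients, impute_end_dates(episodes, patients)
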