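"""Brute-force day-level reference implementation.

Independent of the interval-arithmetic engine: every episode is expanded
to its individual study days, grades are reduced per (patient, day, term)
by max, days are collapsed to weeks by per-term max, and weekly burdens
are the weighted sum over terms. Deliberately simple and slow.
"""

from __future__ import annotations

from collections import defaultdict


def day_level_term_grades(episodes, week_length=7):
    """(patient_id, week, term) -> effective grade by full day expansion."""
    per_day: dict = {}
    for ep in episodes:
        assert ep.end_day is not None, "oracle requires imputed episodes"
        for day in range(ep.start_day, ep.end_day + 1):
            key = (ep.patient_id, day, ep.term)
            per_day[key] = max(per_day.get(key, 0), ep.grade)
    per_week: dict = {}
    for (pid, day, term), grade in per_day.items():
        week = (day - 1) // week_length + 1
        key = (pid, week, term)
        per_week[key] = max(per_week.get(key, 0), grade)
    return per_week


def day_level_burden(episodes, weights=None, week_length=7):
    """(patient_id, week) -> burden score."""
    entries: dict = defaultdict(float)
    for (pid, week, term), grade in day_level_term_grades(episodes, week_length).items():
        w = weights(term) if weights is not None else 1.0
        entries[(pid, week)] += w * grade
    return dict(entries)


def day_level_at_risk(patient, week, week_length=7):
    """Patient contributes the week iff any of its days is on study."""
    days = range((week - 1) * week_length + 1, week * week_length + 1)
    return any(day <= patient.last_study_day for day in days)


def day_level_arm_auc(arm, patients, episodes, weights=None, week_length=7,
                      n_weeks=None):
    """Arm AUC: sum over weeks of (arm burden total / arm risk set)."""
    if n_weeks is None:
        last = max(p.last_study_day for p in patients)
        n_weeks = -(-last // week_length)
    arm_patients = [p for p in patients if p.arm == arm]
    arm_ids = {p.patient_id for p in arm_patients}
    burdens = day_level_burden(
        [ep for ep in episodes if ep.patient_id in arm_ids], weights, week_length
    )
    auc = 0.0
    for week in range(1, n_weeks + 1):
        at_risk = [p for p in arm_patients if day_level_at_risk(p, week, week_length)]
        if not at_risk:
            continue
        total = sum(
            burdens.get((p.patient_id, week), 0.0)
            for p in at_risk
        )
        auc += total / len(at_risk)
    return auc


def day_level_patient_auc(patient, episodes, weights=None, week_length=7):
    """Sum of the patient's weekly burdens over their at-risk weeks."""
    own = [ep for ep in episodes if ep.patient_id == patient.patient_id]
    burdens = day_level_burden(own, weights, week_length)
    return sum(
        score for (pid, week), score in burdens.items()
        if day_level_at_risk(patient, week, week_length)
    )
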