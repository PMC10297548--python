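"""Score a single patient-week by the grade-times-presence rule.

A patient has grade-2 diarrhea (study days 8-21) and a grade-1 skin rash
(days 10-12). Both are active in study week 2 (days 8-14), so the weekly
burden is (2 x 1) + (1 x 1) = 3: each distinct term contributes its
severity grade once, regardless of how many days of the week it covers.
"""

from aeburden import AEEpisode, StudyWeekGrid, patient_week_burden

grid = StudyWeekGrid()
episodes = [
    AEEpisode("P01", "diarrhea", grade=2, start_day=8, end_day=21),
    AEEpisode("P01", "skin rash", grade=1, start_day=10, end_day=12),
]

for week in (1, 2, 3):
    score = patient_week_burden("P01", week, episodes, grid)
    print(f"week {week}: burden = {score:g}")

# week 2 scores 3 (both terms active); week 3 scores 2 (diarrhea only,
# days 15-21); week 1 scores 0 (nothing active before day 8).
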