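"""Render the mirrored severity-stacked weekly burden chart.

One horizontal bar per study week and arm: the first arm extends left,
the second right, each stacked by CTCAE grade (light = grade 1, dark =
grade 5). Bar lengths are the weekly burden per patient at risk, so the
chart's total bar area per side equals that arm's burden AUC.
"""

from aeburden import (
    BOThChartSpec,
    StudyWeekGrid,
    arm_series,
    impute_end_dates,
    preset_rash_like,
    render_both_chart,
    simulate_trial,
)

grid = StudyWeekGrid()
patients, episodes = simulate_trial(preset_rash_like(), seed=2)
episodes = impute_end_dates(episodes, patients)

spec = BOThChartSpec(
    left=arm_series("gem/erlotinib", patients, episodes, grid),
    right=arm_series("FOLFIRINOX", patients, episodes, grid),
    mode="normalized",
    annotate_risk_set=True,
    title="overall weekly burden",
)
render_both_chart(spec, "burden_chart.svg")
print("wrote burden_chart.svg")
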