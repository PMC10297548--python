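# Methods

## The weekly burden model

Input is an AE listing (one row per reported TEAE episode: patient, term,
CTCAE grade 1–5, start study day, end study day or ongoing flag) and a
disposition table (patient, arm, last study day). Study days are 1-based
with day 1 = first treatment day; AE intervals are inclusive on both
ends. The week grid is anchored globally at study day 1 — week *w*
covers days `[(w−1)·L+1, w·L]` with `L = 7` by default — which coincides
with per-patient anchoring because start days are already relative to
first treatment.

Preprocessing resolves every episode to a concrete interval: an ongoing
episode's end date is imputed as the patient's last study day, and a
closed episode recorded as ending after the last study day is truncated
to it rather than rejected — conservative, and it keeps all burden
inside the observed on-study window. An episode that *starts* after the
patient's last study day is a data error and is rejected.

The per-patient weekly score is

* presence: a term is active in a week if its interval overlaps any day
  of the week (the weekly estimate has no sub-week resolution, so one
  day counts for the full week);
* severity: if a term is reported more than once in a week, only the
  highest grade counts (max-severity rule);
* aggregation: the week's score is the sum over distinct active terms of
  `weight(term) × effective grade`. Weights default to 1, giving integer
  scores; a `WeightMap` lets analysts up- or down-weight terms by
  clinical relevance.

A patient is **at risk** in a week when their last study day falls on or
after the week's first day (≥ 1 on-study day). The alternative —
requiring full-week residence — was rejected because it would discard
every patient's final partial week. Arm-level weekly burden is the arm
total divided by the arm's risk-set size; the denominator is per-arm,
not study-wide, which is the only reading that lets arms of different
follow-up lengths keep sensible curves. Weeks with an empty risk set
report 0 and are flagged `empty`.

The accumulated burden of an arm is the AUC of its weekly normalized
series by the **rectangular rule** (sum of the bars), not the trapezoid:
the weekly series is a bar chart, and the AUC must equal the sum of the
displayed bars. Late weeks have small risk sets and noisy normalized
values; the `n_at_risk` column is always reported alongside, and an
optional `min_risk_set` cutoff truncates the series at the first week
whose risk set falls below it (default: no cutoff). Grade-5 (fatal)
events contribute over their recorded interval only; no persistent
ceiling is imposed afterward.

## Two-arm comparison

The comparison statistic is `AUC_a − AUC_b` (arms in sorted label
order). Burden scores are non-negative, skewed and zero-inflated, so the
test is a two-sided **label-permutation test**: patient arm labels are
shuffled (preserving arm sizes), both AUCs — including each week's risk
set — are recomputed per relabeling, and the p-value uses the add-one
correction `p = (1 + #{|Δ*| ≥ |Δ|}) / (1 + n_perm)`, so the smallest
attainable p is `1/(n_perm+1)` and p never equals 0. The permutation
loop is vectorized: per-patient-by-week burden and at-risk matrices are
built once, and each batch of relabelings reduces them by matrix
products. A Mann–Whitney rank-sum test on per-patient AUC summaries is
available (`method="wilcoxon"`) as a sensitivity check; per-term reports
are unadjusted by default with Holm step-down available by flag, since
per-term toxicity comparisons are conventionally reported unadjusted.

Degenerate inputs: if both arms have zero burden everywhere the
comparison returns p = 1 with a warning; arms with fewer than 2 patients
and permutation counts below 99 are rejected; a seed is mandatory.

## The trial simulator

The simulator emulates the data-generating structure of a two-arm
oncology trial AE listing, defaulting to a 150-patient study split
123/27. Per patient: weeks on study follow a weekly Bernoulli dropout
process (default 4–5%/week) capped at `max_weeks`, with a uniform last
day inside the dropout week so partial final weeks occur. Per on-study
week and term: episode onset is Bernoulli with a scalar or per-week
hazard vector (time-varying toxicity), severity is drawn from a per-term
grade distribution over 1–5, and duration is geometric in days (chosen,
with Bernoulli onsets, for analytic tractability: the expected episode
count has the closed form `n · Σ_w S(w) · Σ_t h_t(w)` with `S` the
on-study survival curve, which the tests check by Monte Carlo). Episodes
running past the last study day are flagged ongoing with probability 0.5
(exercising end-date imputation) and truncated otherwise. Grade
transitions within an episode are not simulated; overlapping episodes of
one term produce within-week severity variation and exercise the
max-severity rule.

`preset_rash_like()` encodes the qualitative toxicity-over-time shapes
of an EGFR-inhibitor arm versus an oxaliplatin-based arm: sensory
neuropathy hazard ramping 0.02 → 0.40/week with cumulative exposure in
the FOLFIRINOX-like arm, skin rash concentrated in the gem/erlotinib-like
arm (0.30 vs 0.01/week), and diarrhea/neutropenia hazards decaying over
time in the FOLFIRINOX-like arm (emulating dose reductions). Hazard
levels were chosen once to give realistic episode counts (≈ 10 episodes
per patient over 24 weeks) and clearly separated per-term burdens; they
are study conditions, not tuning knobs.

What the simulator does *not* model — correlated AE onsets, grade
evolution within episodes, informative dropout (dropout is independent
of burden), seriousness/causality, term dictionaries — bounds what
passing tests show about real data: they validate the arithmetic,
calibration and qualitative behavior of the method, not its clinical
operating characteristics under real toxicity processes.

## Verification design

* **Oracle equivalence.** An independent brute-force implementation
  (tests/_oracle.py) expands every episode to individual days, reduces
  per (patient, day, term) by max, collapses days to weeks by per-term
  max, and sums. The interval-arithmetic engine must match it entrywise
  on simulated studies (≤ 50 patients, ≤ 30 weeks, 50 random seeds).
* **Calibration.** Under a null simulator with identical arms (30/arm,
  12 weeks), 200 trials × 999 permutations must give a rejection rate at
  α = 0.05 inside the exact binomial 95% interval [0.024, 0.088];
  rejection means p ≤ α (the add-one p is discrete).
* **Power/monotonicity.** Doubling one arm's onset hazards must raise
  that arm's mean AUC and the rejection rate above the null rate.
* **Additivity.** With unit weights, per-term AUCs decompose the overall
  AUC exactly (tolerance 1e-9) — a structural identity of the linear
  scoring rule.
* **Determinism.** Same inputs + seed ⇒ byte-identical CLI reports; the
  run log carries seed, version and config hash, and no timestamps enter
  the statistical outputs.

Experiment sizes (50 oracle studies, 200 + 2×100 Monte-Carlo trials at
30 patients/arm and 12 weeks, 999 permutations) were chosen to give
tight checks at interactive runtimes; the vectorized permutation test
makes each trial a few milliseconds.

## Plotting

The mirrored chart draws one horizontal bar row per week: the left arm's
values are sign-flipped with absolute-value tick formatting, bars are
stacked by grade with a sequential 5-step light→dark colormap, week 1 at
the top (clinical AE-plot convention). Both total and risk-set-normalized
modes are provided, since either may be the quantity of interest;
normalized is the default because it matches the AUC statistic. Tests
verify the plotted geometry (bar coordinates) against the series values
rather than diffing images.

## Known limitations

* Term matching is case-fold/trim only; no MedDRA or synonym mapping.
* The risk set is not adjusted for competing risks; dropout simply
  shrinks the denominator.
* Weekly resolution floors the timescale: a 1-day and a 7-day episode in
  one week contribute identically.
* The permutation test assumes exchangeability of patients across arms
  under the null; strong prognostic imbalance between arms would violate
  it.
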