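"""Between-arm comparison of accumulated burden.

The comparison statistic is the difference of the two arms' burden AUCs
(sum over weeks of risk-set-normalized weekly burden). Its null
distribution is obtained by permuting arm labels over patients and
recomputing both AUCs — including each week's risk sets — for every
relabeling; burden scores are highly skewed, and the permutation test
needs no distributional assumption. A Wilcoxon rank-sum test on
per-patient AUCs is available as a sensitivity check.

P-values carry the add-one correction ``p = (1 + #{perm >= obs}) / (1 +
n_permutations)``, so the smallest attainable value is
``1/(n_permutations+1)`` and p can never be exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .engine import WeightMap, _burden_pivots
from .model import (
    AEEpisode,
    PatientRecord,
    StudyWeekGrid,
    ValidationError,
    arm_labels,
    normalize_term,
)

__all__ = ["BOThComparison", "compare_arms", "term_report", "report_frame"]


@dataclass(frozen=True)
class BOThComparison:
    """Result of a two-arm burden comparison.

    ``observed_diff = auc_arm_a - auc_arm_b`` (arms in sorted label
    order); it is antisymmetric under exchanging the arm labels while the
    p-value is invariant.
    """

    arm_a: str
    arm_b: str
    auc_arm_a: float
    auc_arm_b: float
    observed_diff: float
    p_value: float
    n_permutations: int
    seed: int
    term_filter: tuple[str, ...] | None = None
    method: str = "permutation"
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "term": "overall" if self.term_filter is None else "|".join(self.term_filter),
            "arm_a": self.arm_a,
            "arm_b": self.arm_b,
            "auc_arm_a": self.auc_arm_a,
            "auc_arm_b": self.auc_arm_b,
            "observed_diff": self.observed_diff,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "method": self.method,
        }


def _arm_aucs(mask_a: np.ndarray, B: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """AUCs of both arms for a batch of arm-A membership masks.

    ``mask_a``: (n_batch, n_patients) booleans; returns two (n_batch,)
    arrays. Weeks with an empty risk set contribute 0.
    """
    masks = mask_a.astype(float)
    out = []
    for m in (masks, 1.0 - masks):
        total = m @ B  # (n_batch, n_weeks)
        n_risk = m @ R
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(n_risk > 0, total / np.where(n_risk > 0, n_risk, 1.0), 0.0)
        out.append(norm.sum(axis=1))
    return out[0], out[1]


def compare_arms(
    patients: Sequence[PatientRecord],
    episodes: Iterable[AEEpisode],
    grid: StudyWeekGrid,
    weights: WeightMap | None = None,
    term_filter: Iterable[str] | None = None,
    n_permutations: int = 9999,
    seed: int | None = None,
    method: str = "permutation",
) -> BOThComparison:
    """Two-sided comparison of arm-level burden AUCs.

    ``method='permutation'`` (default) permutes arm labels over patients;
    ``method='wilcoxon'`` runs a Mann-Whitney rank-sum test on per-patient
    AUC summaries instead (no resampling).
    """
    arm_a, arm_b = arm_labels(patients)
    episodes = list(episodes)
    labels = np.array([p.arm == arm_a for p in patients])
    n_a = int(labels.sum())
    n_b = len(patients) - n_a
    if min(n_a, n_b) < 2:
        raise ValidationError(
            f"each arm needs >= 2 patients, got {n_a} ({arm_a!r}) / {n_b} ({arm_b!r})"
        )
    if method == "permutation" and n_permutations < 99:
        raise ValidationError(f"n_permutations must be >= 99, got {n_permutations}")
    if seed is None:
        raise ValidationError("a seed is required for reproducible resampling")

    selected = None if term_filter is None else tuple(sorted(
        normalize_term(t) for t in term_filter
    ))
    _, B, R, _, _ = _burden_pivots(patients, episodes, grid, weights, selected)
    B = B * R

    auc_a, auc_b = _arm_aucs(labels[None, :], B, R)
    observed = float(auc_a[0] - auc_b[0])

    warning = None
    if B.sum() == 0:
        warning = "all burdens are zero in both arms"
        warnings.warn(warning, stacklevel=2)

    if method == "wilcoxon":
        # per-patient AUC = row sum of at-risk weekly burdens
        per_patient = (B * R).sum(axis=1)
        if warning:
            p_value = 1.0
        else:
            p_value = float(
                sps.mannwhitneyu(
                    per_patient[labels], per_patient[~labels], alternative="two-sided"
                ).pvalue
            )
        return BOThComparison(
            arm_a, arm_b, float(auc_a[0]), float(auc_b[0]), observed, p_value,
            n_permutations=0, seed=seed, term_filter=selected, method="wilcoxon",
            warning=warning,
        )
    if method != "permutation":
        raise ValidationError(f"unknown method {method!r}")

    if warning:
        p_value = 1.0
    else:
        rng = np.random.default_rng(seed)
        n = len(patients)
        # each row is a permuted arm-A membership mask with n_a members
        order = np.argsort(rng.random((n_permutations, n)), axis=1)
        perm_masks = order < n_a
        perm_a, perm_b = _arm_aucs(perm_masks, B, R)
        extreme = np.abs(perm_a - perm_b) >= abs(observed) - 1e-12
        p_value = (1 + int(extreme.sum())) / (1 + n_permutations)

    return BOThComparison(
        arm_a, arm_b, float(auc_a[0]), float(auc_b[0]), observed, float(p_value),
        n_permutations=n_permutations, seed=seed, term_filter=selected,
        warning=warning,
    )


def term_report(
    patients: Sequence[PatientRecord],
    episodes: Iterable[AEEpisode],
    grid: StudyWeekGrid,
    weights: WeightMap | None = None,
    terms: Sequence[str] | None = None,
    n_permutations: int = 9999,
    seed: int | None = None,
    holm: bool = False,
) -> list[BOThComparison]:
    """One comparison per term plus one overall (unfiltered) comparison.

    ``terms`` defaults to every distinct term in the episode list. No
    multiplicity adjustment by default; ``holm=True`` replaces the
    per-term p-values by Holm step-down adjusted ones (the overall
    comparison is left unadjusted).
    """
    episodes = list(episodes)
    if terms is None:
        terms = sorted({ep.term for ep in episodes})
    if not terms:
        raise ValidationError("no terms to report on")
    results: list[BOThComparison] = []
    for term in terms:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # re-raised below with the term named
            comp = compare_arms(
                patients, episodes, grid, weights, term_filter=[term],
                n_permutations=n_permutations, seed=seed,
            )
        if comp.warning:
            warnings.warn(f"term {term!r}: {comp.warning}", stacklevel=2)
        results.append(comp)
    if holm and results:
        adjusted = multipletests([c.p_value for c in results], method="holm")[1]
        results = [
            BOThComparison(
                c.arm_a, c.arm_b, c.auc_arm_a, c.auc_arm_b, c.observed_diff,
                float(p), c.n_permutations, c.seed, c.term_filter,
                method=c.method + "+holm", warning=c.warning,
            )
            for c, p in zip(results, adjusted)
        ]
    overall = compare_arms(
        patients, episodes, grid, weights, term_filter=None,
        n_permutations=n_permutations, seed=seed,
    )
    return results + [overall]


def report_frame(comparisons: Iterable[BOThComparison]) -> pd.DataFrame:
    """Tabular report: term, per-arm AUCs, difference, p-value, metadata."""
    return pd.DataFrame([c.to_dict() for c in comparisons])
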