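"""Mirrored severity-stacked bar chart of weekly burden.

One horizontal bar row per study week, the left arm extending in the
negative x direction and the right arm in the positive direction, each
bar stacked by CTCAE grade with a sequential 5-step colormap
(light -> dark for grades 1 -> 5). Tick labels show absolute values so
both sides read as magnitudes. Bar lengths equal the plotted statistic
exactly (total or risk-set-normalized burden).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.ticker import FuncFormatter

from .engine import ArmBurdenSeries
from .model import MAX_GRADE, ValidationError

__all__ = ["BOThChartSpec", "default_grade_colors", "render_both_chart"]


def default_grade_colors() -> dict[int, tuple]:
    """Sequential light-to-dark colors for grades 1-5."""
    cmap = plt.get_cmap("YlOrRd")
    return {g: cmap(0.25 + 0.75 * (g - 1) / (MAX_GRADE - 1)) for g in range(1, MAX_GRADE + 1)}


@dataclass
class BOThChartSpec:
    """Configuration of a mirrored two-arm burden chart.

    ``mode`` selects the bar statistic: ``"normalized"`` plots weekly
    burden per patient at risk, ``"total"`` the raw weekly burden sum.
    """

    left: ArmBurdenSeries
    right: ArmBurdenSeries
    mode: str = "normalized"
    grade_colors: dict[int, tuple] = field(default_factory=default_grade_colors)
    annotate_risk_set: bool = False
    title: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("normalized", "total"):
            raise ValidationError(f"mode must be 'normalized' or 'total', got {self.mode!r}")
        if self.left.table.empty or self.right.table.empty:
            raise ValidationError("both burden series must be non-empty")
        if not np.array_equal(self.left.weeks, self.right.weeks):
            raise ValidationError("both series must share the same week axis")


def _stacked_components(series: ArmBurdenSeries, mode: str) -> np.ndarray:
    comp = series.grade_components(normalized=(mode == "normalized"))
    return comp.to_numpy().T  # (grade, week)


def render_both_chart(
    spec: BOThChartSpec,
    path: str | Path | None = None,
    dpi: int = 150,
):
    """Render the mirrored chart; returns ``(fig, ax)``.

    When ``path`` is given the figure is also written there (format from
    the file extension, e.g. ``.svg`` or ``.png``) and closed.
    """
    weeks = spec.left.weeks
    left = _stacked_components(spec.left, spec.mode)
    right = _stacked_components(spec.right, spec.mode)

    fig, ax = plt.subplots(figsize=(8, max(3, 0.28 * len(weeks) + 1.5)))
    for components, sign in ((left, -1.0), (right, 1.0)):
        offset = np.zeros(len(weeks))
        for g in range(1, MAX_GRADE + 1):
            widths = sign * components[g - 1]
            ax.barh(
                weeks, widths, left=sign * offset, height=0.8,
                color=spec.grade_colors[g], edgecolor="none",
                label=f"grade {g}" if sign > 0 else None,
            )
            offset = offset + components[g - 1]

    ax.axvline(0.0, color="black", linewidth=0.8)
    ax.invert_yaxis()  # week 1 at the top, clinical convention
    ax.set_ylabel("study week")
    unit = "burden / patient at risk" if spec.mode == "normalized" else "total burden"
    ax.set_xlabel(f"{spec.left.arm}  ←  {unit}  →  {spec.right.arm}")
    ax.xaxis.set_major_formatter(FuncFormatter(lambda x, _: f"{abs(x):g}"))
    ax.legend(loc="lower right", fontsize="small", frameon=False)
    if spec.title:
        ax.set_title(spec.title)
    if spec.annotate_risk_set:
        xmax = ax.get_xlim()[1]
        for week, n_l, n_r in zip(
            weeks, spec.left.table["n_at_risk"], spec.right.table["n_at_risk"]
        ):
            ax.annotate(
                f"{n_l}|{n_r}", xy=(xmax, week), fontsize=6,
                ha="right", va="center", color="gray",
            )
    fig.tight_layout()
    if path is not None:
        try:
            fig.savefig(path, dpi=dpi)
        except OSError as exc:
            plt.close(fig)
            raise OSError(f"cannot write chart to {path}: {exc}") from exc
        plt.close(fig)
    return fig, ax
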