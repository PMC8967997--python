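"""Stacked-area composite-outcome chart, proportion bars, survival plot and
the assembled markdown report.

The numeric layer feeding each figure (stacking order, cumulative partial
sums, mean time fractions) is exposed as plain arrays so tests assert on the
plotted data rather than on pixels.  Rendering never mutates its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .engine import STATE_ORDER, ClinicalState, DailyStateMatrix, JourneySummary

__all__ = [
    "PlotSpec",
    "stacked_arrays",
    "coherent_plot",
    "bar_fractions",
    "proportion_bars",
    "survival_plot",
    "write_report",
]

# qualitative palette close to the published chart: mortality black, index ED
# light green, index hospitalization brown, home light blue, outpatient light
# yellow, ED revisits dark green, readmissions light brown, day-hospital plum
DEFAULT_COLORS: dict[ClinicalState, str] = {
    ClinicalState.DEAD: "#000000",
    ClinicalState.IN_HOSPITAL_INDEX: "#8B5A2B",
    ClinicalState.IN_HOSPITAL_READMISSION: "#D2A679",
    ClinicalState.IN_ED_INDEX: "#90EE90",
    ClinicalState.IN_ED_REVISIT: "#006400",
    ClinicalState.DAY_HOSPITAL: "#DDA0DD",
    ClinicalState.OUTPATIENT_VISIT: "#FFF3A0",
    ClinicalState.AT_HOME: "#ADD8E6",
}


@dataclass
class PlotSpec:
    """Colors, title and output format of the stacked-area chart."""

    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    title: str = ""
    fmt: str = "png"

    def validate(self) -> None:
        missing = [s for s in ClinicalState if s not in self.colors]
        if missing:
            raise ValueError(f"states without a color: {[s.name for s in missing]}")
        if len(set(self.colors.values())) != len(self.colors):
            raise ValueError("state colors must be distinct")


def stacked_arrays(matrix: DailyStateMatrix) -> tuple[list[ClinicalState], np.ndarray]:
    """Stacking order (highest priority first, bottom of the stack) and the
    cumulative partial sums actually drawn, shape (n_states, horizon)."""
    matrix.validate()
    layers = np.stack([matrix.values[:, int(s)] for s in STATE_ORDER])
    return list(STATE_ORDER), np.cumsum(layers, axis=0)


def coherent_plot(
    matrix: DailyStateMatrix, spec: Optional[PlotSpec] = None, path=None
) -> Path:
    """Render cohort occupancy as a 100% stacked-area chart and write it."""
    spec = spec or PlotSpec()
    spec.validate()
    order, _ = stacked_arrays(matrix)  # validates the matrix
    days = np.arange(matrix.horizon)
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.stackplot(
        days,
        [100 * matrix.values[:, int(s)] for s in order],
        labels=[s.name for s in order],
        colors=[spec.colors[s] for s in order],
        step=None,
    )
    ax.set_xlim(0, matrix.horizon - 1)
    ax.set_ylim(0, 100)
    ax.set_xlabel("Day of follow-up")
    ax.set_ylabel("% of patients")
    if spec.title:
        ax.set_title(spec.title)
    ax.legend(loc="center left", bbox_to_anchor=(1.0, 0.5), fontsize=7)
    fig.tight_layout()
    path = Path(path) if path else Path(f"coherent.{spec.fmt}")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def bar_fractions(summaries: Sequence[JourneySummary]) -> dict[str, float]:
    """Mean fraction of the horizon spent in each state category."""
    if not summaries:
        raise ValueError("no journey summaries")
    h = summaries[0].horizon
    n = len(summaries)
    return {
        "DEAD": sum(s.days_dead for s in summaries) / (n * h),
        "IN_HOSPITAL": sum(s.days_in_hospital for s in summaries) / (n * h),
        "ED": sum(s.days_with_ed_visit for s in summaries) / (n * h),
        "DAY_HOSPITAL": sum(s.days_in_day_hospital for s in summaries) / (n * h),
        "OUTPATIENT": sum(s.days_with_outpatient_visit for s in summaries) / (n * h),
        "AT_HOME": sum(s.days_at_home for s in summaries) / (n * h),
    }


_BAR_COLORS = {
    "DEAD": "#000000",
    "IN_HOSPITAL": "#8B5A2B",
    "ED": "#006400",
    "DAY_HOSPITAL": "#DDA0DD",
    "OUTPATIENT": "#FFF3A0",
    "AT_HOME": "#ADD8E6",
}


def proportion_bars(
    summaries_by_group: Mapping[str, Sequence[JourneySummary]], path=None
) -> Path:
    """One horizontal 100%-stacked bar of mean time fractions per group."""
    fracs = {g: bar_fractions(s) for g, s in summaries_by_group.items()}
    groups = list(fracs)
    fig, ax = plt.subplots(figsize=(8, 0.6 + 0.5 * len(groups)))
    left = np.zeros(len(groups))
    for cat, color in _BAR_COLORS.items():
        vals = np.array([100 * fracs[g][cat] for g in groups])
        ax.barh(groups, vals, left=left, color=color, label=cat)
        left += vals
    ax.set_xlim(0, 100)
    ax.set_xlabel("% of follow-up time")
    ax.legend(loc="center left", bbox_to_anchor=(1.0, 0.5), fontsize=7)
    fig.tight_layout()
    path = Path(path) if path else Path("proportion_bars.png")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def survival_plot(survival_by_group: Mapping[str, object], path=None) -> Path:
    """Kaplan-Meier step curves, one per group."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for g, curve in survival_by_group.items():
        ax.step(curve.times, curve.survival, where="post", label=g)
    ax.set_xlabel("Days since index discharge")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    path = Path(path) if path else Path("survival.png")
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def write_report(results_by_horizon: Mapping[int, object], out_dir, fmt: str = "png") -> Path:
    """Assemble a markdown report from fitted results at each horizon.

    Expects :class:`~coherent.model.CoherentResults` values; raises naming the
    missing stage if occupancy, survival or the cost table is absent.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# Composite-outcome report", ""]
    for horizon, res in sorted(results_by_horizon.items()):
        if not res.occupancy:
            raise ValueError(f"missing stage output: occupancy (horizon {horizon})")
        if not res.survival:
            raise ValueError(f"missing stage output: survival (horizon {horizon})")
        lines.append(f"## Horizon {horizon} days")
        lines.append("")
        for group, matrix in res.occupancy.items():
            fig_path = out / f"coherent_{group}_{horizon}d.{fmt}"
            coherent_plot(matrix, PlotSpec(title=f"{group}, {horizon}-day", fmt=fmt), fig_path)
            lines.append(f"![COHERENT {group} {horizon}d]({fig_path.name})")
        bars_path = out / f"proportion_bars_{horizon}d.{fmt}"
        proportion_bars(res.summaries, bars_path)
        lines.append(f"![Time fractions]({bars_path.name})")
        lines.append("")
        lines.append("```")
        lines.append(res.summary())
        lines.append("```")
        lines.append("")
    # survival figure from the longest horizon fit
    res_long = results_by_horizon[max(results_by_horizon)]
    km_path = out / f"survival.{fmt}"
    survival_plot(res_long.survival, km_path)
    lines.append(f"![Survival]({km_path.name})")
    lines.append("")
    if res_long.cost_summary:
        frames = [c.to_frame().set_index("quantity") for c in res_long.cost_summary.values()]
        table = pd.concat(frames, axis=1)
        lines.append("## Cost table")
        lines.append("")
        lines.append("```")
        lines.append(table.to_string())
        lines.append("```")
        table.to_csv(out / "cost_table.csv")
    else:
        raise ValueError("missing stage output: cost summary")
    path = out / "report.md"
    path.write_text("\n".join(lines), encoding="utf-8")
    return path
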