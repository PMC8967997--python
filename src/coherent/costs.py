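"""Episode, clinical-status and patient-journey costing.

Costing follows a full-cost scheme: each episode's cost is the sum of its
directly imputable items (DIRECT), its unit-priced service-catalog items
(CATALOG) and a share of the hospital's non-imputable costs (RESIDUAL)
transferred to episodes through an imputation weight — here per-diem, i.e.
proportional to occupied hospital days.

All monetary arithmetic is carried out at cent precision.  Residual pools are
split with largest-remainder rounding so that allocations reconcile exactly,
and conservation holds at every roll-up level: item amounts = episode totals
= clinical-status totals = journey totals = group total.

Journey aggregates mirror a cost table per HF group over a fixed follow-up
horizon: total cost, patient-days (= n x horizon), mean cost per patient
journey and per patient-day, totals and percentages per clinical status
(ED, index hospitalization, readmissions, day-hospital) and per episode kind
with mean cost per episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import (
    ClinicalState,
    PatientJourney,
    assign_daily_states,
    episode_days,
    length_of_stay,
)
from .records import CostCategory, CostItem, EpisodeKind, EpisodeRecord

__all__ = [
    "EpisodeCost",
    "JourneyCostSummary",
    "DailyCostCurve",
    "episode_cost",
    "build_episode_costs",
    "allocate_residual",
    "journey_cost_summary",
    "daily_cost_curve",
    "pct_diff",
]


def _cents(x: float) -> int:
    return int(round(x * 100))


@dataclass
class EpisodeCost:
    """Cost of one episode split into the three full-costing components."""

    episode_id: str
    direct: float = 0.0
    catalog: float = 0.0
    residual: float = 0.0
    kind: Optional[EpisodeKind] = None

    @property
    def total(self) -> float:
        return round(self.direct + self.catalog + self.residual, 2)


def episode_cost(items: Sequence[CostItem], kind: Optional[EpisodeKind] = None) -> EpisodeCost:
    """Sum one episode's cost items by category.

    All items must share one episode id; an empty list yields a zero cost
    (episode id ``""``).
    """
    ids = {it.episode_id for it in items}
    if len(ids) > 1:
        raise ValueError(f"items span multiple episodes: {sorted(ids)}")
    by_cat = {c: 0 for c in CostCategory}
    for it in items:
        it.validate()
        by_cat[it.category] += _cents(it.amount)
    return EpisodeCost(
        episode_id=next(iter(ids)) if ids else "",
        direct=by_cat[CostCategory.DIRECT] / 100,
        catalog=by_cat[CostCategory.CATALOG] / 100,
        residual=by_cat[CostCategory.RESIDUAL] / 100,
        kind=kind,
    )


def build_episode_costs(
    items: Iterable[CostItem], episodes: Optional[Iterable[EpisodeRecord]] = None
) -> dict[str, EpisodeCost]:
    """Group a cost ledger by episode; optionally tag each cost with its kind."""
    kind_by_id = {e.episode_id: e.kind for e in episodes} if episodes is not None else {}
    grouped: dict[str, list[CostItem]] = {}
    for it in items:
        grouped.setdefault(it.episode_id, []).append(it)
    return {
        eid: episode_cost(its, kind=kind_by_id.get(eid))
        for eid, its in grouped.items()
    }


def allocate_residual(
    pool: float, episodes: Sequence[EpisodeRecord], weight: str = "LOS_DAYS"
) -> list[CostItem]:
    """Split a residual cost pool across episodes, proportional to a weight.

    The only implemented weight is ``LOS_DAYS`` (per-diem: hospital days for
    hospitalizations, calendar dates touched for other kinds).  Cent amounts
    are reconciled with largest-remainder rounding so the allocations sum to
    the pool exactly.
    """
    if pool < 0:
        raise ValueError("residual pool must be >= 0")
    if weight != "LOS_DAYS":
        raise ValueError(f"unknown weight {weight!r}")
    weights = []
    for ep in episodes:
        if ep.kind is EpisodeKind.HOSPITALIZATION:
            w = max(length_of_stay(ep), 1)  # same-day discharge still occupies a day
        else:
            w = (ep.end_date - ep.start_date).days + 1
        weights.append(w)
    total_w = sum(weights)
    if total_w <= 0:
        raise ValueError("all allocation weights are zero")
    pool_cents = _cents(pool)
    raw = [pool_cents * w / total_w for w in weights]
    floors = [int(np.floor(r)) for r in raw]
    shortfall = pool_cents - sum(floors)
    # hand the leftover cents to the largest fractional remainders
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - floors[i], -i), reverse=True)
    for i in order[:shortfall]:
        floors[i] += 1
    return [
        CostItem(
            episode_id=ep.episode_id,
            category=CostCategory.RESIDUAL,
            description="residual cost (per-diem imputation)",
            amount=c / 100,
        )
        for ep, c in zip(episodes, floors)
    ]


@dataclass
class JourneyCostSummary:
    """Cost table of one HF group over the journey horizon."""

    group: str
    n_patients: int
    horizon: int
    total_cost: float
    status_totals: dict  # clinical status label -> euros
    episode_counts: dict  # episode class label -> count
    episode_means: dict  # episode class label -> mean cost per episode
    mean_days_ed: float
    mean_days_hospital: float

    @property
    def patient_days(self) -> int:
        return self.n_patients * self.horizon

    @property
    def mean_cost_per_journey(self) -> float:
        return self.total_cost / self.n_patients

    @property
    def mean_cost_per_patient_day(self) -> float:
        return self.total_cost / self.patient_days

    @property
    def n_episodes(self) -> int:
        return (
            self.episode_counts["ED"]
            + self.episode_counts["DAY_HOSPITAL"]
            + self.episode_counts["INDEX_HOSPITALIZATION"]
            + self.episode_counts["READMISSION"]
        )

    @property
    def mean_cost_per_episode(self) -> float:
        return self.total_cost / self.n_episodes

    def status_percentages(self) -> dict:
        return {k: 100 * v / self.total_cost for k, v in self.status_totals.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Total patient-days, n", self.patient_days),
            ("Total cost", round(self.total_cost, 2)),
            ("Mean cost per patient journey", round(self.mean_cost_per_journey, 2)),
            ("Mean cost per patient per day", round(self.mean_cost_per_patient_day, 2)),
            ("Mean days spent at ED", round(self.mean_days_ed, 2)),
            ("Mean days spent in-hospital", round(self.mean_days_hospital, 2)),
            ("Mean cost per episode", round(self.mean_cost_per_episode, 2)),
            ("Number of episodes", self.n_episodes),
        ]
        for k, v in self.status_totals.items():
            rows.append((f"Cost: {k}", round(v, 2)))
        for k in self.episode_counts:
            rows.append((f"Episodes: {k} (n)", self.episode_counts[k]))
            rows.append((f"Episodes: {k} (mean cost)", round(self.episode_means[k], 2)))
        return pd.DataFrame(rows, columns=["quantity", self.group])


_STATUS_OF_KIND = {
    EpisodeKind.ED: "ED",
    EpisodeKind.DAY_HOSPITAL: "DAY_HOSPITAL",
}


def journey_cost_summary(
    journeys: Sequence[PatientJourney],
    episode_costs: Mapping[str, EpisodeCost],
    group: str = "",
    include_outpatient: bool = False,
) -> JourneyCostSummary:
    """Aggregate episode costs over a group of journeys.

    Every costed episode inside a journey window is attributed to one clinical
    status: ED (index visit and revisits pooled), index hospitalization,
    readmission, or day-hospital.  Outpatient visits carry no cost in the
    ledger and are excluded unless ``include_outpatient`` is set.  Episodes
    must all be costed (a missing episode id raises).
    """
    journeys = list(journeys)
    if not journeys:
        raise ValueError("journey_cost_summary of an empty group is undefined")
    horizon = journeys[0].horizon
    cents_status = {"ED": 0, "INDEX_HOSPITALIZATION": 0, "READMISSION": 0, "DAY_HOSPITAL": 0}
    counts = dict.fromkeys(cents_status, 0)
    days_ed = 0
    days_hosp = 0
    for j in journeys:
        states = assign_daily_states(j)
        days_ed += int(
            np.count_nonzero(
                (states == ClinicalState.IN_ED_INDEX) | (states == ClinicalState.IN_ED_REVISIT)
            )
        )
        days_hosp += int(
            np.count_nonzero(
                (states == ClinicalState.IN_HOSPITAL_INDEX)
                | (states == ClinicalState.IN_HOSPITAL_READMISSION)
            )
        )
        for ep in j.episodes:
            if ep.kind is EpisodeKind.OUTPATIENT and not include_outpatient:
                continue
            if episode_days(ep, j.anchor_date, j.horizon).size == 0:
                continue  # episode entirely outside the window
            if ep.kind is EpisodeKind.HOSPITALIZATION:
                status = (
                    "INDEX_HOSPITALIZATION"
                    if ep.episode_id == j.index_hosp_episode_id
                    else "READMISSION"
                )
            else:
                status = _STATUS_OF_KIND.get(ep.kind, "ED")
            if ep.episode_id not in episode_costs:
                raise KeyError(f"episode {ep.episode_id} has no cost")
            cents_status[status] += _cents(episode_costs[ep.episode_id].total)
            counts[status] += 1
    status_totals = {k: v / 100 for k, v in cents_status.items()}
    total = round(sum(status_totals.values()), 2)
    if total <= 0:
        raise ValueError("group has zero total cost")
    episode_means = {
        k: (status_totals[k] / counts[k] if counts[k] else 0.0) for k in counts
    }
    return JourneyCostSummary(
        group=group,
        n_patients=len(journeys),
        horizon=horizon,
        total_cost=total,
        status_totals=status_totals,
        episode_counts=counts,
        episode_means=episode_means,
        mean_days_ed=days_ed / len(journeys),
        mean_days_hospital=days_hosp / len(journeys),
    )


@dataclass
class DailyCostCurve:
    """Estimated cost per journey day and its running sum."""

    daily: np.ndarray

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.daily)

    @property
    def total(self) -> float:
        return float(round(self.daily.sum(), 2))


def daily_cost_curve(
    journey: PatientJourney, episode_costs: Mapping[str, EpisodeCost]
) -> DailyCostCurve:
    """Spread each episode's total uniformly over its occupied in-window days.

    Point episodes charge their single day; an episode with no day inside the
    window contributes nothing.  The final cumulative value equals the sum of
    the charged episode totals by construction.
    """
    daily = np.zeros(journey.horizon, dtype=float)
    for ep in journey.episodes:
        ec = episode_costs.get(ep.episode_id)
        if ec is None or ec.total == 0:
            continue
        days = episode_days(ep, journey.anchor_date, journey.horizon)
        if days.size == 0:
            continue
        daily[days] += ec.total / days.size
    return DailyCostCurve(daily=daily)


def pct_diff(a: float, b: float) -> float:
    """Relative difference (a - b) / b, as a fraction (0.34 = 34% higher)."""
    if b == 0:
        raise ZeroDivisionError("reference value is zero")
    return (a - b) / b
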