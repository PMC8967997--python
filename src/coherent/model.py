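"""Model/Results surface tying the pipeline together.

:class:`CoherentModel` is built from the three record tables (episodes,
vitals, optional costs).  ``fit`` runs the whole analysis for one disposition
arm and follow-up horizon — cohort construction, daily clinical states and
occupancy, journey summaries, crude event rates, Kaplan-Meier survival with a
log-rank contrast, and (when a cost ledger is supplied) the per-group cost
table — and returns a :class:`CoherentResults` carrying every artefact, with
a ``summary()`` text table.

>>> model = CoherentModel(episodes, vitals, cost_items, year=2018)
>>> res = model.fit(horizon=365, arm="HOSPITALIZED")
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cohort import Arm, CohortStrata, build_strata
from .costs import JourneyCostSummary, build_episode_costs, journey_cost_summary
from .engine import (
    DailyStateMatrix,
    JourneySummary,
    PatientJourney,
    build_journeys,
    occupancy,
    summarize_journey,
)
from .records import (
    CostItem,
    EpisodeRecord,
    VitalRecord,
    read_costs,
    read_episodes,
    read_vitals,
)
from .stats import (
    EventType,
    SurvivalCurve,
    TestResult,
    build_followups,
    event_rate,
    in_hospital_mortality,
    km_estimate,
    log_rank,
    survival_from_followups,
)

__all__ = ["CoherentModel", "CoherentResults"]

_GROUPS = ("pHF", "sHF")


@dataclass
class CoherentResults:
    """Fitted artefacts of one arm x horizon analysis."""

    arm: str
    horizon: int
    strata: CohortStrata
    journeys: dict[str, list[PatientJourney]]
    occupancy: dict[str, DailyStateMatrix]
    summaries: dict[str, list[JourneySummary]]
    event_rates: pd.DataFrame
    survival: dict[str, SurvivalCurve]
    logrank: Optional[TestResult]
    cost_summary: dict[str, JourneyCostSummary] = field(default_factory=dict)

    @property
    def groups(self) -> list[str]:
        return list(self.journeys)

    def median_days_at_home(self, group: str) -> float:
        return float(np.median([s.days_at_home for s in self.summaries[group]]))

    def summary(self) -> str:
        """Plain-text summary of cohort sizes, rates and cost aggregates."""
        lines = []
        lines.append(f"COHERENT composite-outcome analysis — arm {self.arm}, "
                     f"horizon {self.horizon} days")
        lines.append("=" * 72)
        ns = {g: len(self.journeys[g]) for g in self.groups}
        lines.append("Patients: " + ", ".join(f"{g} n={n}" for g, n in ns.items()))
        lines.append("")
        lines.append(f"{'event / cut-off':<34}" + "".join(f"{g:>12}" for g in self.groups))
        er = self.event_rates
        for (event, cutoff), sub in er.groupby(["event", "cutoff_days"], sort=True):
            label = f"{event.lower()} at {cutoff} d" if cutoff else f"{event.lower()} in hospital"
            vals = {r.group: r.rate for r in sub.itertuples(index=False)}
            lines.append(
                f"{label:<34}"
                + "".join(f"{100 * vals.get(g, float('nan')):>11.1f}%" for g in self.groups)
            )
        lines.append("")
        med = {g: self.median_days_at_home(g) for g in self.groups}
        lines.append(
            f"{'median days at home':<34}" + "".join(f"{med[g]:>12.0f}" for g in self.groups)
        )
        pct = {
            g: 100
            * float(np.mean([s.pct_home_of_alive_out_of_hospital for s in self.summaries[g]]))
            for g in self.groups
        }
        lines.append(
            f"{'home share of alive out-of-hosp':<34}"
            + "".join(f"{pct[g]:>11.1f}%" for g in self.groups)
        )
        if self.logrank is not None:
            lines.append("")
            lines.append(
                f"log-rank (survival, {' vs '.join(self.groups)}): "
                f"chi2={self.logrank.statistic:.2f}, p={self.logrank.p_value:.4f}"
            )
        if self.cost_summary:
            lines.append("")
            lines.append(f"{'cost aggregate':<34}" + "".join(f"{g:>14}" for g in self.groups))
            rows = [
                ("total patient-days", lambda c: f"{c.patient_days:,}"),
                ("total cost (EUR)", lambda c: f"{c.total_cost:,.0f}"),
                ("mean cost / journey (EUR)", lambda c: f"{c.mean_cost_per_journey:,.1f}"),
                ("mean cost / patient-day (EUR)", lambda c: f"{c.mean_cost_per_patient_day:,.2f}"),
                ("mean cost / episode (EUR)", lambda c: f"{c.mean_cost_per_episode:,.2f}"),
                ("episodes (n)", lambda c: f"{c.n_episodes:,}"),
            ]
            for label, fn in rows:
                lines.append(
                    f"{label:<34}"
                    + "".join(f"{fn(self.cost_summary[g]):>14}" for g in self.groups)
                )
        return "\n".join(lines)


class CoherentModel:
    """Composite-outcome analysis of an ED-anchored cohort.

    Parameters
    ----------
    episodes, vitals : record lists (see :mod:`coherent.records`)
    cost_items : optional cost ledger; without it ``fit`` skips the cost table
    year : calendar year whose ED visits anchor the cohort
    """

    def __init__(
        self,
        episodes: Iterable[EpisodeRecord],
        vitals: Iterable[VitalRecord],
        cost_items: Optional[Iterable[CostItem]] = None,
        year: int = 2018,
    ):
        self.episodes = list(episodes)
        self.vitals = list(vitals)
        self.cost_items = list(cost_items) if cost_items is not None else None
        self.year = year
        self._strata: Optional[CohortStrata] = None

    @classmethod
    def from_csv(
        cls, episodes_path, vitals_path, costs_path=None, year: int = 2018
    ) -> "CoherentModel":
        return cls(
            episodes=read_episodes(episodes_path),
            vitals=read_vitals(vitals_path),
            cost_items=read_costs(costs_path) if costs_path else None,
            year=year,
        )

    @property
    def strata(self) -> CohortStrata:
        if self._strata is None:
            self._strata = build_strata(self.episodes, self.vitals, self.year)
        return self._strata

    def fit(self, horizon: int = 365, arm: str = "HOSPITALIZED") -> CoherentResults:
        arm = str(getattr(arm, "value", arm))
        strata = self.strata
        journeys: dict[str, list[PatientJourney]] = {}
        occ: dict[str, DailyStateMatrix] = {}
        summaries: dict[str, list[JourneySummary]] = {}
        survival: dict[str, SurvivalCurve] = {}
        rate_rows = []
        surv_inputs = {}
        for group in _GROUPS:
            sub = strata.select(arm=arm, hf_group=group)
            if len(sub) == 0:
                continue
            js = build_journeys(sub, self.episodes, self.vitals, horizon=horizon)
            journeys[group] = js
            m = occupancy(js)
            m.validate()
            occ[group] = m
            summaries[group] = [summarize_journey(j) for j in js]
            fus = build_followups(sub, self.episodes, self.vitals)
            events = [EventType.DEATH, EventType.READMISSION, EventType.RE_ED_VISIT]
            if arm == Arm.DISCHARGED_HOME_FROM_ED.value:
                events = [EventType.DEATH, EventType.FIRST_HOSPITALIZATION, EventType.RE_ED_VISIT]
            for ev in events:
                for cutoff in (30, 365):
                    r = event_rate(fus, ev, cutoff)
                    rate_rows.append(
                        {
                            "group": group,
                            "event": r.event.value,
                            "cutoff_days": r.cutoff_days,
                            "numerator": r.numerator,
                            "denominator": r.denominator,
                            "rate": r.rate,
                        }
                    )
            if arm == Arm.HOSPITALIZED.value:
                r = in_hospital_mortality(sub, self.episodes)
                rate_rows.append(
                    {
                        "group": group,
                        "event": "IN_HOSPITAL_DEATH",
                        "cutoff_days": 0,
                        "numerator": r.numerator,
                        "denominator": r.denominator,
                        "rate": r.rate,
                    }
                )
            dur, obs = survival_from_followups(fus, horizon=horizon)
            surv_inputs[group] = (dur, obs)
            survival[group] = km_estimate(dur, obs)
        if not journeys:
            raise ValueError(f"no included patients in arm {arm}")
        logrank = None
        if len(surv_inputs) == 2:
            (da, oa), (db, ob) = (surv_inputs[g] for g in self.groups_present(surv_inputs))
            if oa.sum() + ob.sum() > 0:
                logrank = log_rank(da, oa, db, ob)
        cost_summary: dict[str, JourneyCostSummary] = {}
        if self.cost_items is not None:
            ec = build_episode_costs(self.cost_items, self.episodes)
            for group, js in journeys.items():
                cost_summary[group] = journey_cost_summary(js, ec, group=group)
        return CoherentResults(
            arm=arm,
            horizon=horizon,
            strata=strata,
            journeys=journeys,
            occupancy=occ,
            summaries=summaries,
            event_rates=pd.DataFrame(rate_rows),
            survival=survival,
            logrank=logrank,
            cost_summary=cost_summary,
        )

    @staticmethod
    def groups_present(d: dict) -> list[str]:
        return [g for g in _GROUPS if g in d]
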