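"""Daily clinical-state engine: the computational core of the COHERENT model.

Each patient-day of a fixed follow-up window (30 or 365 days, anchored at the
index ED arrival) is assigned exactly one state from a mutually exclusive,
hierarchically ordered list: dead, in hospital (index stay or readmission),
in the ED (index visit or revisit), day-hospital, outpatient visit, at home.
When several situations share a day the highest-ranked one wins — a same-day
ED visit and admission renders as hospital, an outpatient visit during a
readmission renders as readmission, and death dominates everything from the
death day onward.

Day-count conventions
---------------------
* A hospitalization occupies days ``start .. end-1`` (half-open, minimum one
  day), so that occupied days equal length of stay = discharge - admission.
* ED, day-hospital and outpatient episodes occupy every calendar date they
  touch (a same-day ED visit is one ED day).
* The dead state persists to the end of the window; days after death count as
  days dead, never as utilization.

Cohort occupancy — the fraction of patients in each state on each day — is
the data behind the stacked-area composite-outcome chart.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .records import Disposition, EpisodeKind, EpisodeRecord, VitalRecord

__all__ = [
    "ClinicalState",
    "STATE_ORDER",
    "PatientJourney",
    "DailyStateMatrix",
    "JourneySummary",
    "assign_daily_states",
    "occupancy",
    "summarize_journey",
    "length_of_stay",
    "build_journeys",
]


class ClinicalState(enum.IntEnum):
    """Mutually exclusive daily states; larger value = higher priority."""

    AT_HOME = 0
    OUTPATIENT_VISIT = 1
    DAY_HOSPITAL = 2
    IN_ED_REVISIT = 3
    IN_ED_INDEX = 4
    IN_HOSPITAL_READMISSION = 5
    IN_HOSPITAL_INDEX = 6
    DEAD = 7


#: States ordered from highest to lowest priority (stacking order of the chart).
STATE_ORDER: tuple[ClinicalState, ...] = tuple(
    sorted(ClinicalState, key=lambda s: -s.value)
)


@dataclass
class PatientJourney:
    """One patient's episodes anchored at the index ED arrival (day 0).

    ``death_day`` is the day index of death if it falls inside the window,
    else ``None`` (alive or died beyond the horizon).  ``discharge_day`` is
    the day index of the index discharge (hospital discharge if admitted,
    ED discharge otherwise): the anchor for post-discharge event rates.
    """

    patient_id: str
    anchor_date: date
    horizon: int
    episodes: list[EpisodeRecord] = field(default_factory=list)
    death_day: Optional[int] = None
    index_episode_id: str = ""
    index_hosp_episode_id: str = ""
    discharge_day: int = 0

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.death_day is not None and self.death_day < 0:
            raise ValueError("death_day must be >= 0")
        self.episodes = sorted(
            self.episodes, key=lambda e: (e.start_date, e.episode_id)
        )


def episode_days(episode: EpisodeRecord, anchor: date, horizon: int) -> np.ndarray:
    """Day indices (within [0, horizon)) occupied by an episode.

    Hospitalizations are half-open on dates (minimum one day); all other
    episode kinds occupy each calendar date touched.
    """
    start = (episode.start_date - anchor).days
    if episode.kind is EpisodeKind.HOSPITALIZATION:
        end = (episode.end_date - anchor).days  # exclusive
        if end <= start:
            end = start + 1  # same-day discharge still occupies the admission day
    else:
        end = (episode.end_date - anchor).days + 1
    lo, hi = max(start, 0), min(end, horizon)
    return np.arange(lo, hi)


_EPISODE_STATE = {
    EpisodeKind.DAY_HOSPITAL: ClinicalState.DAY_HOSPITAL,
    EpisodeKind.OUTPATIENT: ClinicalState.OUTPATIENT_VISIT,
}


def _state_of(episode: EpisodeRecord, journey: PatientJourney) -> ClinicalState:
    if episode.kind is EpisodeKind.HOSPITALIZATION:
        if episode.episode_id == journey.index_hosp_episode_id:
            return ClinicalState.IN_HOSPITAL_INDEX
        return ClinicalState.IN_HOSPITAL_READMISSION
    if episode.kind is EpisodeKind.ED:
        if episode.episode_id == journey.index_episode_id:
            return ClinicalState.IN_ED_INDEX
        return ClinicalState.IN_ED_REVISIT
    return _EPISODE_STATE[episode.kind]


def assign_daily_states(journey: PatientJourney) -> np.ndarray:
    """One state per day of the journey window (dtype int8, values ClinicalState).

    Episode order is irrelevant: each day takes the maximum-priority state
    among the episodes covering it, with DEAD overriding from death day on.
    """
    states = np.full(journey.horizon, int(ClinicalState.AT_HOME), dtype=np.int8)
    for ep in journey.episodes:
        days = episode_days(ep, journey.anchor_date, journey.horizon)
        if days.size == 0:
            continue
        s = int(_state_of(ep, journey))
        np.maximum.at(states, days, np.int8(s))
    if journey.death_day is not None and journey.death_day < journey.horizon:
        states[max(journey.death_day, 0):] = int(ClinicalState.DEAD)
    return states


@dataclass
class DailyStateMatrix:
    """Cohort occupancy: fraction of patients in each state on each day.

    ``values`` has shape (horizon, n_states) indexed by day and by
    ``ClinicalState`` integer value; every row sums to 1 and the DEAD
    fraction is non-decreasing over days.
    """

    values: np.ndarray
    n: int

    @property
    def horizon(self) -> int:
        return self.values.shape[0]

    def validate(self) -> None:
        if not np.allclose(self.values.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("occupancy rows must each sum to 1")
        dead = self.values[:, int(ClinicalState.DEAD)]
        if np.any(np.diff(dead) < -1e-12):
            raise ValueError("DEAD fraction must be non-decreasing")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValueError("occupancy entries must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[s.name for s in ClinicalState]
        )
        df.insert(0, "day", np.arange(self.horizon))
        return df


def occupancy(journeys: Sequence[PatientJourney]) -> DailyStateMatrix:
    """Aggregate per-patient daily states into cohort occupancy fractions."""
    journeys = list(journeys)
    if not journeys:
        raise ValueError("occupancy of an empty cohort is undefined")
    horizon = journeys[0].horizon
    if any(j.horizon != horizon for j in journeys):
        raise ValueError("all journeys must share one horizon")
    counts = np.zeros((horizon, len(ClinicalState)), dtype=np.int64)
    day_idx = np.arange(horizon)
    for j in journeys:
        counts[day_idx, assign_daily_states(j)] += 1
    return DailyStateMatrix(values=counts / len(journeys), n=len(journeys))


@dataclass
class JourneySummary:
    """Per-patient day counts by state category over the journey window."""

    patient_id: str
    horizon: int
    days_at_home: int
    days_in_hospital: int
    days_with_ed_visit: int
    days_in_day_hospital: int
    days_with_outpatient_visit: int
    days_dead: int
    pct_home_of_alive_out_of_hospital: float

    def total_days(self) -> int:
        return (
            self.days_at_home
            + self.days_in_hospital
            + self.days_with_ed_visit
            + self.days_in_day_hospital
            + self.days_with_outpatient_visit
            + self.days_dead
        )


def summarize_journey(journey: PatientJourney) -> JourneySummary:
    """Day counts per category; the home share of time alive out of hospital.

    The share is days at home over (horizon - days dead - days in hospital),
    i.e. the denominator is time alive and not hospitalized; it is 1 by
    convention when that denominator is 0 (e.g. death on day 0).
    """
    states = assign_daily_states(journey)
    count = np.bincount(states, minlength=len(ClinicalState))
    days_home = int(count[ClinicalState.AT_HOME])
    days_hosp = int(
        count[ClinicalState.IN_HOSPITAL_INDEX] + count[ClinicalState.IN_HOSPITAL_READMISSION]
    )
    days_ed = int(count[ClinicalState.IN_ED_INDEX] + count[ClinicalState.IN_ED_REVISIT])
    days_dh = int(count[ClinicalState.DAY_HOSPITAL])
    days_op = int(count[ClinicalState.OUTPATIENT_VISIT])
    days_dead = int(count[ClinicalState.DEAD])
    denom = journey.horizon - days_dead - days_hosp
    pct = days_home / denom if denom > 0 else 1.0
    return JourneySummary(
        patient_id=journey.patient_id,
        horizon=journey.horizon,
        days_at_home=days_home,
        days_in_hospital=days_hosp,
        days_with_ed_visit=days_ed,
        days_in_day_hospital=days_dh,
        days_with_outpatient_visit=days_op,
        days_dead=days_dead,
        pct_home_of_alive_out_of_hospital=pct,
    )


def length_of_stay(episode: EpisodeRecord) -> int:
    """Length of stay in days.

    Hospitalization: discharge date minus admission date (0 for a same-day
    discharge).  ED: number of calendar dates touched (a same-day visit is
    1 day, a visit crossing one midnight is 2).
    """
    if episode.kind is EpisodeKind.HOSPITALIZATION:
        return (episode.end_date - episode.start_date).days
    if episode.kind is EpisodeKind.ED:
        return (episode.end_date - episode.start_date).days + 1
    raise ValueError(f"length_of_stay is defined for ED/hospitalization, got {episode.kind}")


def build_journeys(
    strata_table: pd.DataFrame,
    episodes: Iterable[EpisodeRecord],
    vitals: Iterable[VitalRecord],
    horizon: int = 365,
) -> list[PatientJourney]:
    """Assemble one journey per included patient from the strata table.

    Day 0 is the index ED arrival; episodes overlapping the window are kept
    (the engine clips them to the window day-by-day).
    """
    eps_by_patient: dict[str, list[EpisodeRecord]] = {}
    for ep in episodes:
        eps_by_patient.setdefault(ep.patient_id, []).append(ep)
    death_by_patient = {
        v.patient_id: v.death_date for v in vitals if v.death_date is not None
    }
    journeys = []
    for row in strata_table.itertuples(index=False):
        anchor = row.index_admission_date
        window_end = anchor + timedelta(days=horizon)
        eps = [
            e
            for e in eps_by_patient.get(row.patient_id, [])
            if e.start_date < window_end and e.end_date >= anchor
        ]
        death_date = death_by_patient.get(row.patient_id)
        death_day = None
        if death_date is not None:
            d = (death_date - anchor).days
            if 0 <= d < horizon:
                death_day = d
        journeys.append(
            PatientJourney(
                patient_id=row.patient_id,
                anchor_date=anchor,
                horizon=horizon,
                episodes=eps,
                death_day=death_day,
                index_episode_id=row.index_episode_id,
                index_hosp_episode_id=row.index_hosp_episode_id,
                discharge_day=(row.index_discharge_date - anchor).days,
            )
        )
    return journeys
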