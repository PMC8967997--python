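"""Clinical-outcome statistics: crude event rates, Kaplan-Meier survival and
two-group tests.

Event rates are crude cumulative incidences — patients with at least one
qualifying event by the cut-off divided by all patients in the stratum, with
no competing-risk adjustment.  Cut-offs (30 and 365 days) are anchored at the
index discharge date: readmissions and ED revisits count events strictly
after discharge, mortality counts any death on or before discharge + cutoff
(so in-hospital deaths are included in the 30-day and 1-year figures, and are
additionally available as a separate in-hospital rate).

Survival curves use the Kaplan-Meier product-limit estimator and groups are
compared with the two-sample log-rank test (both via lifelines); baseline
comparisons dispatch to Student's t, Mann-Whitney U or the chi-square test
without continuity correction, with the scale chosen by the caller.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import timedelta
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .records import Disposition, EpisodeKind, EpisodeRecord, VitalRecord

__all__ = [
    "EventType",
    "EventRateResult",
    "SurvivalCurve",
    "TestResult",
    "FollowUp",
    "build_followups",
    "event_rate",
    "in_hospital_mortality",
    "km_estimate",
    "survival_from_followups",
    "log_rank",
    "compare_groups",
]


class EventType(str, enum.Enum):
    DEATH = "DEATH"
    READMISSION = "READMISSION"
    RE_ED_VISIT = "RE_ED_VISIT"
    FIRST_HOSPITALIZATION = "FIRST_HOSPITALIZATION"


@dataclass
class EventRateResult:
    event: EventType
    cutoff_days: int
    numerator: int
    denominator: int

    @property
    def rate(self) -> float:
        return self.numerator / self.denominator

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("need 0 <= numerator <= denominator")


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function on the event-day grid."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t): survival at time t (right-continuous step function)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")


@dataclass
class FollowUp:
    """Post-discharge follow-up of one patient, on real calendar dates.

    Events beyond the journey window are visible here (cut-offs run from the
    index discharge, not from the ED arrival), so follow-ups are built from
    the raw episode table rather than from clipped journeys.
    """

    patient_id: str
    discharge_date: object  # datetime.date
    death_date: Optional[object] = None
    hospitalization_starts: tuple = ()
    ed_starts: tuple = ()
    index_episode_ids: frozenset = frozenset()


def build_followups(
    strata_table: pd.DataFrame,
    episodes: Iterable[EpisodeRecord],
    vitals: Iterable[VitalRecord],
) -> list[FollowUp]:
    eps_by_patient: dict[str, list[EpisodeRecord]] = {}
    for ep in episodes:
        eps_by_patient.setdefault(ep.patient_id, []).append(ep)
    death = {v.patient_id: v.death_date for v in vitals if v.death_date is not None}
    out = []
    for row in strata_table.itertuples(index=False):
        eps = eps_by_patient.get(row.patient_id, [])
        index_ids = frozenset(
            x for x in (row.index_episode_id, row.index_hosp_episode_id) if x
        )
        out.append(
            FollowUp(
                patient_id=row.patient_id,
                discharge_date=row.index_discharge_date,
                death_date=death.get(row.patient_id),
                hospitalization_starts=tuple(
                    e.start_date
                    for e in eps
                    if e.kind is EpisodeKind.HOSPITALIZATION
                    and e.episode_id not in index_ids
                ),
                ed_starts=tuple(
                    e.start_date
                    for e in eps
                    if e.kind is EpisodeKind.ED and e.episode_id not in index_ids
                ),
                index_episode_ids=index_ids,
            )
        )
    return out


def event_rate(
    followups: Sequence[FollowUp], event: EventType, cutoff_days: int
) -> EventRateResult:
    """Crude cumulative incidence of an event by ``cutoff_days`` post-discharge.

    Deaths do not remove patients from the denominator.  Utilization events
    (readmission, re-ED visit, first hospitalization) count episode starts in
    the half-open window (discharge, discharge + cutoff]; mortality counts any
    death on or before discharge + cutoff.
    """
    followups = list(followups)
    if not followups:
        raise ValueError("event_rate of an empty cohort is undefined")
    if cutoff_days <= 0:
        raise ValueError("cutoff_days must be positive")
    n_event = 0
    for fu in followups:
        limit = fu.discharge_date + timedelta(days=cutoff_days)
        if event is EventType.DEATH:
            hit = fu.death_date is not None and fu.death_date <= limit
        elif event is EventType.READMISSION:
            hit = any(fu.discharge_date < d <= limit for d in fu.hospitalization_starts)
        elif event is EventType.RE_ED_VISIT:
            hit = any(fu.discharge_date < d <= limit for d in fu.ed_starts)
        elif event is EventType.FIRST_HOSPITALIZATION:
            hit = any(fu.discharge_date < d <= limit for d in fu.hospitalization_starts)
        else:  # pragma: no cover - exhaustive enum
            raise ValueError(event)
        n_event += bool(hit)
    return EventRateResult(
        event=event, cutoff_days=cutoff_days, numerator=n_event, denominator=len(followups)
    )


def in_hospital_mortality(
    strata_table: pd.DataFrame, episodes: Iterable[EpisodeRecord]
) -> EventRateResult:
    """Deaths during the index hospitalization (disposition DIED), over all
    patients in the stratum."""
    if len(strata_table) == 0:
        raise ValueError("empty stratum")
    by_id = {e.episode_id: e for e in episodes}
    n = 0
    for row in strata_table.itertuples(index=False):
        hosp = by_id.get(row.index_hosp_episode_id)
        if hosp is not None and hosp.disposition is Disposition.DIED:
            n += 1
    return EventRateResult(
        event=EventType.DEATH, cutoff_days=0, numerator=n, denominator=len(strata_table)
    )


def km_estimate(
    durations: Sequence[float], observed: Sequence[bool]
) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate.

    ``durations`` are days to death or censoring; ``observed`` flags deaths
    (False = censored at that duration).
    """
    durations = np.asarray(durations, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if np.any(durations < 0):
        raise ValueError("durations must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(dtype=float)
    )
    return SurvivalCurve(times=times, survival=surv, at_risk=at_risk)


def survival_from_followups(
    followups: Sequence[FollowUp], horizon: int = 365
) -> tuple[np.ndarray, np.ndarray]:
    """(durations, observed) post-discharge, censored at ``horizon`` days.

    In-hospital deaths enter with duration 0 so curves include the initial
    drop.
    """
    dur, obs = [], []
    for fu in followups:
        if fu.death_date is not None:
            d = (fu.death_date - fu.discharge_date).days
            if d <= horizon:
                dur.append(max(d, 0))
                obs.append(True)
                continue
        dur.append(horizon)
        obs.append(False)
    return np.asarray(dur, dtype=float), np.asarray(obs, dtype=bool)


def log_rank(
    durations_a: Sequence[float],
    observed_a: Sequence[bool],
    durations_b: Sequence[float],
    observed_b: Sequence[bool],
) -> TestResult:
    """Two-group log-rank test (chi-square with 1 df)."""
    observed_a = np.asarray(observed_a, dtype=bool)
    observed_b = np.asarray(observed_b, dtype=bool)
    if observed_a.sum() + observed_b.sum() == 0:
        raise ValueError("log-rank test undefined without any event")
    res = logrank_test(durations_a, durations_b, observed_a, observed_b)
    return TestResult(
        test_name="log_rank", statistic=float(res.test_statistic), p_value=float(res.p_value)
    )


def compare_groups(
    a, b=None, scale: str = "continuous_normal"
) -> TestResult:
    """Two-group comparison dispatched on the declared measurement scale.

    * ``continuous_normal`` — Student's t-test (equal variances) on samples
      ``a`` and ``b``.
    * ``continuous_skewed`` — two-sided Mann-Whitney U on ``a`` and ``b``.
    * ``categorical`` — chi-square without continuity correction; ``a`` is
      the full contingency table (rows = groups), ``b`` is ignored.

    The scale is declared by the caller; no normality test is run.
    """
    if scale == "categorical":
        table = np.asarray(a, dtype=float)
        if table.ndim != 2:
            raise ValueError("categorical comparison expects a contingency table")
        if (table.sum(axis=1) == 0).any():
            raise ValueError("empty group in contingency table")
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        return TestResult("chi_square", float(stat), float(p))
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if scale == "continuous_normal":
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        return TestResult("t", float(stat), float(p))
    if scale == "continuous_skewed":
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        return TestResult("mann_whitney", float(stat), float(p))
    raise ValueError(f"unknown scale {scale!r}")
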