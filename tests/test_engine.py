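"""Daily state assignment, occupancy aggregation and journey summaries."""

from __future__ import annotations

import random
from datetime import date, timedelta

import numpy as np
import pytest

from coherent.engine import (
    ClinicalState,
    PatientJourney,
    assign_daily_states,
    length_of_stay,
    occupancy,
    summarize_journey,
)
from coherent.records import Disposition, EpisodeKind, EpisodeRecord

ANCHOR = date(2018, 3, 1)
S = ClinicalState


def ep(kind, eid, start, end, dispo=Disposition.HOME):
    return EpisodeRecord(
        "p", eid, kind,
        ANCHOR + timedelta(days=start), ANCHOR + timedelta(days=end),
        disposition=dispo,
    )


def journey(episodes, horizon=30, death_day=None, index_ed="e-idx", index_hosp=""):
    return PatientJourney(
        patient_id="p", anchor_date=ANCHOR, horizon=horizon, episodes=episodes,
        death_day=death_day, index_episode_id=index_ed, index_hosp_episode_id=index_hosp,
    )


def test_ed_index_then_home_then_death():
    j = journey([ep(EpisodeKind.ED, "e-idx", 0, 1)], horizon=30, death_day=10)
    states = assign_daily_states(j)
    assert list(states[:2]) == [S.IN_ED_INDEX] * 2
    assert list(states[2:10]) == [S.AT_HOME] * 8
    assert list(states[10:]) == [S.DEAD] * 20


def test_same_day_admission_renders_as_hospital():
    j = journey(
        [
            ep(EpisodeKind.ED, "e-idx", 0, 0, Disposition.ADMITTED),
            ep(EpisodeKind.HOSPITALIZATION, "h-idx", 0, 8),
        ],
        horizon=30,
        index_hosp="h-idx",
    )
    states = assign_daily_states(j)
    assert states[0] == S.IN_HOSPITAL_INDEX  # hierarchy beats the ED visit
    assert list(states[1:8]) == [S.IN_HOSPITAL_INDEX] * 7
    assert states[8] == S.AT_HOME  # discharge day is not a hospital day
    assert all(s == S.AT_HOME for s in states[8:])


def test_outpatient_visit_during_readmission_is_masked():
    j = journey(
        [
            ep(EpisodeKind.HOSPITALIZATION, "h2", 3, 10),
            ep(EpisodeKind.OUTPATIENT, "o1", 5, 5),
        ],
        horizon=30,
    )
    states = assign_daily_states(j)
    assert states[5] == S.IN_HOSPITAL_READMISSION


def test_states_invariant_to_episode_order():
    eps = [
        ep(EpisodeKind.ED, "e-idx", 0, 1, Disposition.ADMITTED),
        ep(EpisodeKind.HOSPITALIZATION, "h-idx", 1, 9),
        ep(EpisodeKind.ED, "e2", 15, 15),
        ep(EpisodeKind.OUTPATIENT, "o1", 20, 20),
        ep(EpisodeKind.DAY_HOSPITAL, "d1", 25, 25),
    ]
    base = assign_daily_states(journey(eps, index_hosp="h-idx"))
    for seed in range(5):
        shuffled = list(eps)
        random.Random(seed).shuffle(shuffled)
        got = assign_daily_states(journey(shuffled, index_hosp="h-idx"))
        assert np.array_equal(base, got)


def test_occupancy_trivial_cases():
    all_home = occupancy([journey([], horizon=10)])
    assert np.all(all_home.values[:, S.AT_HOME] == 1.0)
    two = occupancy([journey([], horizon=10), journey([], horizon=10, death_day=0)])
    assert np.all(two.values[:, S.DEAD] == 0.5)
    with pytest.raises(ValueError):
        occupancy([])


def _brute_force_state(j, day):
    """Independent day-by-day membership check, straight from the definitions."""
    if j.death_day is not None and day >= j.death_day:
        return S.DEAD
    best = S.AT_HOME
    d = j.anchor_date + timedelta(days=day)
    for e in j.episodes:
        if e.kind is EpisodeKind.HOSPITALIZATION:
            covered = e.start_date <= d < max(e.end_date, e.start_date + timedelta(days=1))
            s = S.IN_HOSPITAL_INDEX if e.episode_id == j.index_hosp_episode_id else S.IN_HOSPITAL_READMISSION
        else:
            covered = e.start_date <= d <= e.end_date
            if e.kind is EpisodeKind.ED:
                s = S.IN_ED_INDEX if e.episode_id == j.index_episode_id else S.IN_ED_REVISIT
            elif e.kind is EpisodeKind.DAY_HOSPITAL:
                s = S.DAY_HOSPITAL
            else:
                s = S.OUTPATIENT_VISIT
        if covered and s > best:
            best = s
    return best


def test_occupancy_equals_brute_force_tally(hosp_journeys):
    journeys = hosp_journeys[:120]
    matrix = occupancy(journeys)
    matrix.validate()
    states = np.array([assign_daily_states(j) for j in journeys])
    # engine vs definition-level oracle on a grid of (journey, day) points
    rng = np.random.default_rng(0)
    for ji in rng.choice(len(journeys), 40, replace=False):
        for day in rng.choice(365, 15, replace=False):
            assert states[ji, day] == _brute_force_state(journeys[ji], int(day))
    # aggregated fractions equal the naive per-day tally
    for day in (0, 1, 30, 180, 364):
        counts = np.bincount(states[:, day], minlength=len(ClinicalState))
        assert np.allclose(matrix.values[day], counts / len(journeys))


def test_column_sums_and_dead_monotone(hosp_journeys):
    matrix = occupancy(hosp_journeys)
    assert np.allclose(matrix.values.sum(axis=1), 1.0, atol=1e-9)
    dead = matrix.values[:, S.DEAD]
    assert np.all(np.diff(dead) >= 0)


def test_summary_arithmetic():
    eps = [
        ep(EpisodeKind.ED, "e-idx", 0, 1, Disposition.ADMITTED),
        ep(EpisodeKind.HOSPITALIZATION, "h-idx", 1, 13),  # 12 hospital days
        ep(EpisodeKind.OUTPATIENT, "o1", 20, 20),
    ]
    j = journey(eps, horizon=365, index_hosp="h-idx")
    s = summarize_journey(j)
    assert s.days_with_ed_visit == 1  # day 1 masked by the admission
    assert s.days_in_hospital == 12
    assert s.days_with_outpatient_visit == 1
    assert s.days_at_home == 365 - 1 - 12 - 1
    assert s.total_days() == 365


def test_summary_death_day_zero_convention():
    s = summarize_journey(journey([], horizon=365, death_day=0))
    assert s.days_dead == 365
    assert s.pct_home_of_alive_out_of_hospital == 1.0


def test_home_share_of_time_alive_out_of_hospital():
    # alive 300 days of 365; 20 in hospital; 10 in ED/day-hospital/outpatient
    eps = [
        ep(EpisodeKind.HOSPITALIZATION, "h2", 0, 20),
        ep(EpisodeKind.ED, "e2", 30, 31),
        ep(EpisodeKind.DAY_HOSPITAL, "d1", 40, 40),
    ] + [ep(EpisodeKind.OUTPATIENT, f"o{i}", 50 + i, 50 + i) for i in range(7)]
    j = journey(eps, horizon=365, death_day=300, index_ed="none")
    s = summarize_journey(j)
    assert s.days_in_hospital == 20 and s.days_dead == 65
    assert s.days_with_ed_visit + s.days_in_day_hospital + s.days_with_outpatient_visit == 10
    assert s.days_at_home == 270
    assert s.pct_home_of_alive_out_of_hospital == pytest.approx(270 / 280)


def test_day_count_conservation(hosp_journeys):
    for j in hosp_journeys[:200]:
        assert summarize_journey(j).total_days() == j.horizon


def test_length_of_stay_conventions():
    h = ep(EpisodeKind.HOSPITALIZATION, "h", 0, 8)
    assert length_of_stay(h) == 8  # 2018-03-01 -> 2018-03-09
    assert length_of_stay(ep(EpisodeKind.ED, "e", 0, 0)) == 1  # same-day ED visit
    assert length_of_stay(ep(EpisodeKind.HOSPITALIZATION, "h0", 0, 0)) == 0
    with pytest.raises(ValueError):
        length_of_stay(ep(EpisodeKind.OUTPATIENT, "o", 0, 0))
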