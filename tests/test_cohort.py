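"""HF code matching, episode classification and strata construction."""

from __future__ import annotations

import random
from datetime import date

import pytest

from coherent.cohort import (
    Arm,
    HFLabel,
    OverlapError,
    build_strata,
    classify_episode,
    match_hf_code,
)
from coherent.records import (
    CodingSystem,
    DiagnosisCode,
    Disposition,
    EpisodeKind,
    EpisodeRecord,
    VitalRecord,
)

ICD = CodingSystem.ICD10CM
ICPC = CodingSystem.ICPC2


def dx(code, pos=1, poa=None, system=ICD):
    return DiagnosisCode(system, code, pos, poa)


@pytest.mark.parametrize(
    "system, code, expected",
    [
        (ICD, "I50.9", True),
        (ICD, "I509", True),  # dotless dialect
        (ICD, "I11.0", True),
        (ICD, "I110", True),
        (ICD, "I13.0", True),
        (ICD, "I13.2", True),
        (ICD, "I13.10", False),  # prefix I13.1 is not an HF code
        (ICD, "I10", False),
        (ICD, "K77", False),  # K77 is only HF in ICPC-2
        (ICPC, "K77", True),
        (ICPC, "K78", False),
    ],
)
def test_match_hf_code(system, code, expected):
    assert match_hf_code(DiagnosisCode(system, code)) is expected


def hosp(dxs, pid="p", eid="h1", start=date(2018, 3, 1), end=date(2018, 3, 9), dispo=Disposition.HOME):
    return EpisodeRecord(pid, eid, EpisodeKind.HOSPITALIZATION, start, end,
                         disposition=dispo, diagnoses=dxs)


def ed(dxs, pid="p", eid="e1", day=date(2018, 3, 1), dispo=Disposition.HOME, end=None):
    return EpisodeRecord(pid, eid, EpisodeKind.ED, day, end or day,
                         disposition=dispo, diagnoses=dxs)


@pytest.mark.parametrize(
    "episode, label",
    [
        (hosp([dx("I50.9", 1, True)]), HFLabel.PRIMARY_HF),
        (hosp([dx("J18.9", 1, True), dx("I50.9", 2, True)]), HFLabel.SECONDARY_HF),
        (hosp([dx("I50.9", 1, False)]), HFLabel.EXCLUDED_NEW_ONSET),
        (hosp([dx("J18.9", 1, True)]), HFLabel.NO_HF),
        (ed([dx("K77", 1, system=ICPC)]), HFLabel.PRIMARY_HF),
        (ed([dx("K77", None, system=ICPC)]), HFLabel.UNCLASSIFIABLE),
        (ed([dx("R02", 1, system=ICPC), dx("K77", 3, system=ICPC)]), HFLabel.SECONDARY_HF),
    ],
)
def test_classify_episode(episode, label):
    assert classify_episode(episode) is label


def test_classify_requires_diagnoses():
    with pytest.raises(ValueError):
        classify_episode(ed([]))


def test_home_discharge_primary_hf_stratum():
    strata = build_strata([ed([dx("K77", 1, system=ICPC)], pid="p1")], [], 2018)
    row = strata.table.iloc[0]
    assert row["arm"] == Arm.DISCHARGED_HOME_FROM_ED.value
    assert row["hf_group"] == "pHF"
    assert row["index_discharge_date"] == date(2018, 3, 1)


def test_admitted_without_ed_hf_code_classified_from_hospitalization():
    """ED visit with a non-HF code, admission with HF present on admission at
    a secondary position: the patient enters the hospitalized sHF stratum."""
    episodes = [
        ed([dx("R06", 1, system=ICPC)], pid="p1", eid="e1",
           day=date(2018, 5, 1), dispo=Disposition.ADMITTED),
        hosp([dx("J18.9", 1, True), dx("I50.9", 3, True)], pid="p1", eid="h1",
             start=date(2018, 5, 1), end=date(2018, 5, 9)),
    ]
    strata = build_strata(episodes, [], 2018)
    row = strata.table.iloc[0]
    assert (row["arm"], row["hf_group"]) == (Arm.HOSPITALIZED.value, "sHF")
    assert row["index_hosp_episode_id"] == "h1"
    assert row["index_discharge_date"] == date(2018, 5, 9)


def test_linkage_window_is_one_day():
    base = [
        ed([dx("K77", 1, system=ICPC)], pid="p1", eid="e1",
           day=date(2018, 5, 1), dispo=Disposition.ADMITTED),
    ]
    next_day = hosp([dx("I50.9", 1, True)], pid="p1", eid="h1",
                    start=date(2018, 5, 2), end=date(2018, 5, 9))
    late = hosp([dx("I50.9", 1, True)], pid="p1", eid="h1",
                start=date(2018, 5, 3), end=date(2018, 5, 9))
    linked = build_strata(base + [next_day], [], 2018).table.iloc[0]
    assert linked["arm"] == Arm.HOSPITALIZED.value
    unlinked = build_strata(base + [late], [], 2018).table.iloc[0]
    assert unlinked["arm"] == Arm.DISCHARGED_HOME_FROM_ED.value


def test_new_onset_and_unclassifiable_are_excluded_with_counts():
    episodes = [
        ed([dx("R06", 1, system=ICPC)], pid="p1", eid="e1",
           day=date(2018, 5, 1), dispo=Disposition.ADMITTED),
        hosp([dx("I50.9", 1, False)], pid="p1", eid="h1",
             start=date(2018, 5, 1), end=date(2018, 5, 9)),
        ed([dx("K77", None, system=ICPC)], pid="p2", eid="e2"),
    ]
    strata = build_strata(episodes, [], 2018)
    assert strata.n_included == 0
    assert strata.excluded_new_onset == ["p1"]
    assert strata.excluded_unclassifiable == ["p2"]


def test_died_in_ed_detected_by_disposition():
    strata = build_strata(
        [ed([dx("K77", 1, system=ICPC)], pid="p1", dispo=Disposition.DIED)],
        [VitalRecord("p1", date(2018, 3, 1))],
        2018,
    )
    assert strata.table.iloc[0]["arm"] == Arm.DIED_IN_ED.value


def test_first_qualifying_ed_visit_anchors_the_journey():
    episodes = [
        ed([dx("R02", 1, system=ICPC)], pid="p1", eid="e0", day=date(2018, 1, 5)),
        ed([dx("K77", 1, system=ICPC)], pid="p1", eid="e1", day=date(2018, 2, 10)),
        ed([dx("K77", 1, system=ICPC)], pid="p1", eid="e2", day=date(2018, 6, 1)),
    ]
    strata = build_strata(episodes, [], 2018)
    assert strata.table.iloc[0]["index_episode_id"] == "e1"


def test_overlapping_hospitalizations_rejected():
    episodes = [
        ed([dx("K77", 1, system=ICPC)], pid="p1", eid="e1", dispo=Disposition.ADMITTED),
        hosp([dx("I50.9", 1, True)], pid="p1", eid="h1",
             start=date(2018, 3, 1), end=date(2018, 3, 9)),
        hosp([dx("J18.9", 1, True)], pid="p1", eid="h2",
             start=date(2018, 3, 5), end=date(2018, 3, 12)),
    ]
    with pytest.raises(OverlapError, match="h1"):
        build_strata(episodes, [], 2018)


def test_strata_invariant_to_row_order(small_cohort):
    shuffled = list(small_cohort.episodes)
    random.Random(0).shuffle(shuffled)
    a = build_strata(small_cohort.episodes, small_cohort.vitals, 2018)
    b = build_strata(shuffled, small_cohort.vitals, 2018)
    assert a.table.equals(b.table)


def test_planted_labels_recovered_exactly(small_cohort, small_strata):
    """The partition of generated data equals the generator's ground truth."""
    got = (
        small_strata.table[["patient_id", "arm", "hf_group"]]
        .sort_values("patient_id")
        .reset_index(drop=True)
    )
    want = (
        small_cohort.labels[["patient_id", "arm", "hf_group"]]
        .sort_values("patient_id")
        .reset_index(drop=True)
    )
    assert got.equals(want)
    assert small_strata.n_included == len(small_cohort.labels)
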