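"""Cohort construction: heart-failure code matching, pHF/sHF classification
and partition of an ED-anchored cohort into analysis strata.

A patient enters the cohort through a qualifying emergency-department (ED)
visit in the target calendar year.  Heart failure (HF) is recognised either
in the ED record itself (ICPC-2 code K77) or — for patients admitted from the
ED — in the discharge diagnoses of the linked hospitalization (ICD-10-CM
codes I11.0*, I13.0*, I13.2*, I50*), counted only when flagged present on
admission (POA).  HF coded at position 1 defines the primary-HF (pHF) group;
HF at any later position, with a different principal diagnosis, defines the
secondary-HF (sHF) group.

Hospitalized patients whose only HF codes are not present on admission are
new-onset HF and excluded; ED K77 codes whose position is undefined make the
patient unclassifiable and excluded.  Each included patient lands in exactly
one cell of the 3 x 2 grid: disposition arm (discharged home from the ED,
hospitalized, died in the ED) x HF group (pHF, sHF).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Optional

import pandas as pd

from .records import (
    CodingSystem,
    DiagnosisCode,
    Disposition,
    EpisodeKind,
    EpisodeRecord,
    VitalRecord,
)

__all__ = [
    "HFLabel",
    "Arm",
    "CohortStrata",
    "normalize_code",
    "match_hf_code",
    "classify_episode",
    "build_strata",
    "OverlapError",
]

# ICD-10-CM prefixes counted as heart failure, compared after dot-stripping.
HF_ICD10_PREFIXES = ("I110", "I130", "I132", "I50")
HF_ICPC2_CODE = "K77"

# An ED visit with disposition ADMITTED links to a hospitalization starting
# on, or within one calendar day after, the ED end date (midnight-crossing
# admissions).
LINKAGE_WINDOW_DAYS = 1


class HFLabel(str, enum.Enum):
    PRIMARY_HF = "PRIMARY_HF"
    SECONDARY_HF = "SECONDARY_HF"
    NO_HF = "NO_HF"
    UNCLASSIFIABLE = "UNCLASSIFIABLE"
    EXCLUDED_NEW_ONSET = "EXCLUDED_NEW_ONSET"


class Arm(str, enum.Enum):
    DISCHARGED_HOME_FROM_ED = "DISCHARGED_HOME_FROM_ED"
    HOSPITALIZED = "HOSPITALIZED"
    DIED_IN_ED = "DIED_IN_ED"


class OverlapError(ValueError):
    """A patient has overlapping hospitalizations; carries the episode ids."""

    def __init__(self, patient_id: str, episode_ids: list[str]):
        self.patient_id = patient_id
        self.episode_ids = episode_ids
        super().__init__(
            f"patient {patient_id}: overlapping hospitalizations {episode_ids}"
        )


def normalize_code(code: str) -> str:
    """Uppercase and strip dots, so both ICD-10-CM dialects (I50.9 / I509) match."""
    return code.replace(".", "").upper().strip()


def match_hf_code(code: DiagnosisCode) -> bool:
    """True iff the code denotes heart failure under either coding system."""
    norm = normalize_code(code.code)
    if code.system is CodingSystem.ICD10CM:
        return norm.startswith(HF_ICD10_PREFIXES)
    return norm == HF_ICPC2_CODE


def classify_episode(episode: EpisodeRecord) -> HFLabel:
    """Classify one episode's diagnosis list into an HF label.

    For hospitalizations only POA diagnoses count as HF; an episode whose only
    HF codes lack POA is new-onset HF (excluded).  For ED episodes an HF code
    without a defined position makes the episode unclassifiable.
    """
    if not episode.diagnoses:
        raise ValueError(f"episode {episode.episode_id} has no diagnoses")
    hf = [d for d in episode.diagnoses if match_hf_code(d)]
    if not hf:
        return HFLabel.NO_HF
    if episode.kind is EpisodeKind.HOSPITALIZATION:
        hf_poa = [d for d in hf if d.present_on_admission]
        if not hf_poa:
            return HFLabel.EXCLUDED_NEW_ONSET
        hf = hf_poa
    positioned = [d for d in hf if d.position is not None]
    if not positioned:
        # ED K77 with undefined position: primary vs secondary cannot be told.
        return HFLabel.UNCLASSIFIABLE
    if any(d.position == 1 for d in positioned):
        return HFLabel.PRIMARY_HF
    return HFLabel.SECONDARY_HF


@dataclass
class CohortStrata:
    """Partition of the included cohort plus the exclusion tally.

    ``table`` has one row per included patient: patient_id, arm, hf_group,
    index_episode_id (the index ED visit), index_hosp_episode_id (linked
    hospitalization, empty for non-admitted patients), index_admission_date
    (ED arrival = journey day 0) and index_discharge_date (end of the index
    hospitalization, or of the ED visit if not admitted).
    """

    table: pd.DataFrame
    excluded_unclassifiable: list[str] = field(default_factory=list)
    excluded_new_onset: list[str] = field(default_factory=list)

    @property
    def n_included(self) -> int:
        return len(self.table)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_unclassifiable) + len(self.excluded_new_onset)

    def counts(self) -> pd.DataFrame:
        """Patient counts per (arm, hf_group) cell."""
        return (
            self.table.groupby(["arm", "hf_group"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )

    def select(self, arm: Optional[str] = None, hf_group: Optional[str] = None) -> pd.DataFrame:
        t = self.table
        if arm is not None:
            t = t[t["arm"] == str(getattr(arm, "value", arm))]
        if hf_group is not None:
            t = t[t["hf_group"] == str(getattr(hf_group, "value", hf_group))]
        return t


def _check_hospitalization_overlap(patient_id: str, hosps: list[EpisodeRecord]) -> None:
    hosps = sorted(hosps, key=lambda e: (e.start_date, e.end_date))
    for a, b in zip(hosps, hosps[1:]):
        # closed-date overlap: b starts strictly before a ends
        if b.start_date < a.end_date:
            raise OverlapError(patient_id, [a.episode_id, b.episode_id])


def link_hospitalization(
    ed: EpisodeRecord, hosps: Iterable[EpisodeRecord]
) -> Optional[EpisodeRecord]:
    """Hospitalization linked to an ED visit with disposition ADMITTED."""
    if ed.disposition is not Disposition.ADMITTED:
        return None
    lo = ed.end_date
    hi = ed.end_date + timedelta(days=LINKAGE_WINDOW_DAYS)
    candidates = [h for h in hosps if lo <= h.start_date <= hi]
    if not candidates:
        return None
    return min(candidates, key=lambda h: (h.start_date, h.episode_id))


def build_strata(
    episodes: Iterable[EpisodeRecord],
    vitals: Iterable[VitalRecord],
    year: int,
) -> CohortStrata:
    """Partition patients into the 3 x 2 strata from their index ED visit.

    The index episode is the first ED visit of the year carrying HF evidence:
    either an HF code in its own diagnoses, or (for admitted patients without
    an ED HF code) a POA HF diagnosis on the linked hospitalization.  When a
    patient is admitted, the hospitalization's classification takes precedence
    over the ED's when both define a group; ED-only patients are classified
    from the ED record.
    """
    episodes = list(episodes)
    by_patient: dict[str, list[EpisodeRecord]] = {}
    for ep in episodes:
        by_patient.setdefault(ep.patient_id, []).append(ep)

    rows = []
    excluded_unclassifiable: list[str] = []
    excluded_new_onset: list[str] = []

    for pid in sorted(by_patient):
        eps = sorted(by_patient[pid], key=lambda e: (e.start_date, e.episode_id))
        hosps = [e for e in eps if e.kind is EpisodeKind.HOSPITALIZATION]
        _check_hospitalization_overlap(pid, hosps)
        ed_visits = [
            e
            for e in eps
            if e.kind is EpisodeKind.ED and e.start_date.year == year
        ]
        resolved = None  # (label, ed, hosp)
        exclusion = None
        for ed in ed_visits:
            ed_label = classify_episode(ed) if ed.diagnoses else HFLabel.NO_HF
            hosp = link_hospitalization(ed, hosps)
            hosp_label = (
                classify_episode(hosp) if hosp is not None and hosp.diagnoses else HFLabel.NO_HF
            )
            if hosp_label in (HFLabel.PRIMARY_HF, HFLabel.SECONDARY_HF):
                resolved = (hosp_label, ed, hosp)
            elif ed_label in (HFLabel.PRIMARY_HF, HFLabel.SECONDARY_HF):
                resolved = (ed_label, ed, hosp)
            elif ed_label is HFLabel.UNCLASSIFIABLE:
                exclusion = exclusion or ("unclassifiable", ed)
            elif hosp_label is HFLabel.EXCLUDED_NEW_ONSET:
                exclusion = exclusion or ("new_onset", ed)
            if resolved:
                break
        if resolved is None:
            if exclusion is not None:
                if exclusion[0] == "unclassifiable":
                    excluded_unclassifiable.append(pid)
                else:
                    excluded_new_onset.append(pid)
            continue

        label, ed, hosp = resolved
        if ed.disposition is Disposition.DIED:
            arm = Arm.DIED_IN_ED
        elif hosp is not None:
            arm = Arm.HOSPITALIZED
        else:
            arm = Arm.DISCHARGED_HOME_FROM_ED
        discharge = hosp.end_date if hosp is not None else ed.end_date
        rows.append(
            {
                "patient_id": pid,
                "arm": arm.value,
                "hf_group": "pHF" if label is HFLabel.PRIMARY_HF else "sHF",
                "index_episode_id": ed.episode_id,
                "index_hosp_episode_id": hosp.episode_id if hosp is not None else "",
                "index_admission_date": ed.start_date,
                "index_discharge_date": discharge,
            }
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "arm",
            "hf_group",
            "index_episode_id",
            "index_hosp_episode_id",
            "index_admission_date",
            "index_discharge_date",
        ],
    )
    return CohortStrata(
        table=table,
        excluded_unclassifiable=excluded_unclassifiable,
        excluded_new_onset=excluded_new_onset,
    )
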