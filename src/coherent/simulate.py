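"""Seeded synthetic cohort generator.

Emulates one calendar year of ED-anchored heart-failure activity in a single
hospital: every simulated patient gets an index ED visit (with a linked
hospitalization in the hospitalized arm), planted pHF/sHF diagnosis codes
that the cohort builder recovers exactly, a death time, post-discharge
readmissions / ED revisits / outpatient and day-hospital visits stopped at
death, and a full-cost ledger per costed episode.

Statistical structure
---------------------
* **Death**: a two-piece constant hazard on (0, 30] and (30, 365] days after
  index discharge, solved analytically from the 30-day and 1-year cumulative
  mortalities; hospitalized patients additionally die in hospital with a
  separate probability.  This reproduces the "early divergence, then roughly
  parallel" survival shape without inventing a parametric family.
* **Readmission / re-ED processes**: time to first event follows its own
  two-piece hazard, calibrated *against the competing death hazard* so that
  the crude cumulative incidence (events realized before death) matches the
  target 30-day and 1-year probabilities; subsequent events recur with the
  late-piece hazard.
* **Length of stay**: log-normal matched on the log scale to the printed
  median and interquartile range, rounded to whole days (minimum 1).
* **Costs**: log-normal per episode class (ED, day-hospital, index
  hospitalization, readmission) moment-matched to the printed mean and SD,
  split into direct / catalog / residual items at cent precision.
* **Outpatient visits**: negative-binomial count per follow-up year
  (moment-matched mean/SD), spread uniformly over post-discharge days alive.

All randomness flows from one integer seed through per-patient
``numpy.random.SeedSequence(seed, spawn_key=(arm, group, i))`` streams, so
enlarging one group never perturbs another patient's draws and a fixed seed
reproduces the cohort byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

from .records import (
    CodingSystem,
    CostCategory,
    CostItem,
    DiagnosisCode,
    Disposition,
    EpisodeKind,
    EpisodeRecord,
    VitalRecord,
)

__all__ = [
    "GroupParams",
    "SyntheticParams",
    "SyntheticCohort",
    "default_params",
    "load_params",
    "save_params",
    "generate_cohort",
    "recover_params",
    "two_piece_hazard",
    "calibrate_competing_hazard",
    "lognormal_from_median_iqr",
    "lognormal_from_mean_sd",
]

_T1 = 30.0
_T2 = 365.0


# ---------------------------------------------------------------------------
# hazard calibration


def two_piece_hazard(p_early: float, p_late: float, t1: float = _T1, t2: float = _T2):
    """Constant hazards (h1 on (0, t1], h2 on (t1, t2]) hitting two cumulative
    probabilities exactly: P(T <= t1) = p_early, P(T <= t2) = p_late."""
    if not 0 <= p_early <= p_late < 1:
        raise ValueError("need 0 <= p_early <= p_late < 1")
    h1 = -np.log1p(-p_early) / t1
    h2 = -(np.log1p(-p_late) - np.log1p(-p_early)) / (t2 - t1)
    return float(h1), float(h2)


def _cif_piece(r: float, d: float, length: float) -> float:
    """P(event in piece, before death), both exponential, over ``length``."""
    tot = r + d
    if tot <= 0:
        return 0.0
    return r / tot * -np.expm1(-length * tot)


def calibrate_competing_hazard(
    q_early: float,
    q_late: float,
    death_h1: float,
    death_h2: float,
    t1: float = _T1,
    t2: float = _T2,
):
    """Two-piece event hazard whose *crude* cumulative incidence in the
    presence of an independent two-piece death hazard equals the targets.

    Solves P(T_e <= t1, T_e < T_d) = q_early and P(T_e <= t2, T_e < T_d) =
    q_late for the event hazards (r1, r2) by root finding piece by piece.
    """
    if not 0 <= q_early <= q_late < 1:
        raise ValueError("need 0 <= q_early <= q_late < 1")
    if q_early == 0:
        r1 = 0.0
    else:
        r1 = brentq(lambda r: _cif_piece(r, death_h1, t1) - q_early, 1e-12, 200.0)
    cif1 = _cif_piece(r1, death_h1, t1)
    surv1 = np.exp(-t1 * (r1 + death_h1))  # neither event nor death by t1
    residual = q_late - cif1
    if residual <= 0:
        r2 = 0.0
    else:
        if residual >= surv1:
            raise ValueError("late target infeasible given early incidence and mortality")
        r2 = brentq(
            lambda r: surv1 * _cif_piece(r, death_h2, t2 - t1) - residual, 1e-12, 200.0
        )
    return float(r1), float(r2)


def sample_two_piece(rng: np.random.Generator, h1: float, h2: float, t1: float = _T1) -> float:
    """Draw an event time from a two-piece exponential; inf if it never fires."""
    e = -np.log(rng.random())  # standard exponential
    if h1 > 0 and e <= h1 * t1:
        return e / h1
    rest = e - h1 * t1
    if h2 > 0:
        return t1 + rest / h2
    return np.inf


# ---------------------------------------------------------------------------
# distribution matching

_Z75 = norm.ppf(0.75)


def lognormal_from_median_iqr(median: float, iqr: tuple[float, float]):
    """(mu, sigma) of a log-normal with the given median and central IQR.

    sigma is matched to the IQR width on the log scale: log q75 - log q25 =
    2 * z_0.75 * sigma.
    """
    lo, hi = iqr
    if not 0 < lo <= median <= hi:
        raise ValueError("need 0 < q25 <= median <= q75")
    mu = np.log(median)
    sigma = (np.log(hi) - np.log(lo)) / (2 * _Z75)
    return float(mu), float(sigma)


def lognormal_from_mean_sd(mean: float, sd: float):
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return float(mu), float(np.sqrt(sigma2))


# ---------------------------------------------------------------------------
# parameters


@dataclass
class GroupParams:
    """Generating parameters of one (disposition arm, HF group) cell.

    Probabilities are crude cumulative probabilities over all patients of the
    cell; for the hospitalized arm the 30-day and 1-year mortalities include
    in-hospital deaths, and cut-offs run from the index discharge.
    """

    n: int
    p_inhosp_death: float = 0.0
    p_death_30d: float = 0.0
    p_death_1y: float = 0.0
    los_median: float = 8.0
    los_iqr: tuple[float, float] = (6.0, 12.0)
    readmit_p30: float = 0.0
    readmit_p365: float = 0.0
    reed_p30: float = 0.0
    reed_p365: float = 0.0
    outpatient_mean: float = 12.0
    outpatient_sd: float = 11.0
    day_hospital_rate: float = 0.4
    p_no_ed_hf_code: float = 0.0
    ed_extra_day_p: float = 0.33  # index/revisit ED spans 1 + Binomial(2, p) dates
    cost_ed: tuple[float, float] = (343.2, 141.8)
    cost_day_hospital: tuple[float, float] = (543.4, 944.9)
    cost_index_hosp: tuple[float, float] = (3907.7, 6323.2)
    cost_readmission: tuple[float, float] = (4465.1, 7057.2)

    def validate(self) -> None:
        probs = [
            self.p_inhosp_death,
            self.p_death_30d,
            self.p_death_1y,
            self.readmit_p30,
            self.readmit_p365,
            self.reed_p30,
            self.reed_p365,
            self.p_no_ed_hf_code,
            self.ed_extra_day_p,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not self.p_inhosp_death <= self.p_death_30d <= self.p_death_1y:
            raise ValueError(
                "need p_inhosp_death <= p_death_30d <= p_death_1y (cumulative)"
            )
        if self.readmit_p30 > self.readmit_p365 or self.reed_p30 > self.reed_p365:
            raise ValueError("30-day probabilities cannot exceed 1-year probabilities")
        if self.n <= 0:
            raise ValueError("n must be positive")


@dataclass
class SyntheticParams:
    """Full generator configuration: one GroupParams per cohort cell."""

    hospitalized: dict[str, GroupParams] = field(default_factory=dict)
    ed_home: dict[str, GroupParams] = field(default_factory=dict)
    n_died_in_ed: dict[str, int] = field(default_factory=dict)
    year: int = 2018
    horizon: int = 365

    def validate(self) -> None:
        for cell in (*self.hospitalized.values(), *self.ed_home.values()):
            cell.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticParams":
        def mk(g: dict) -> GroupParams:
            g = dict(g)
            for key in ("los_iqr", "cost_ed", "cost_day_hospital", "cost_index_hosp", "cost_readmission"):
                if key in g and g[key] is not None:
                    g[key] = tuple(g[key])
            return GroupParams(**g)

        return cls(
            hospitalized={k: mk(v) for k, v in d.get("hospitalized", {}).items()},
            ed_home={k: mk(v) for k, v in d.get("ed_home", {}).items()},
            n_died_in_ed=dict(d.get("n_died_in_ed", {})),
            year=d.get("year", 2018),
            horizon=d.get("horizon", 365),
        )


def default_params() -> SyntheticParams:
    """Defaults calibrated to the published single-centre 2018 cohort.

    Hospitalized arm: n 1029/1257 (pHF/sHF), in-hospital mortality 6.4/10.9%,
    30-day 6.7/12.1%, 1-year 25.8/32%, LOS median 8 (IQR 6-12), 30-day
    readmission 13.4/13.3%, 1-year 47.4/43.6%, re-ED 16.8/15.6% and
    61.4/56.4%, outpatient visits per year 12.6 +/- 11.1 / 11.4 +/- 11.7,
    day-hospital episodes 427/1029 and 812/1257 per patient-year, patients
    whose HF evidence appears only in the hospital record 134/1029 and
    589/1257, episode cost means/SDs per the published cost table.
    ED-home arm: n 434/363 with the corresponding printed rates.
    """
    hospitalized = {
        "pHF": GroupParams(
            n=1029,
            p_inhosp_death=0.064,
            p_death_30d=0.067,
            p_death_1y=0.258,
            readmit_p30=0.134,
            readmit_p365=0.474,
            reed_p30=0.168,
            reed_p365=0.614,
            outpatient_mean=12.6,
            outpatient_sd=11.1,
            day_hospital_rate=427 / 1029,
            p_no_ed_hf_code=134 / 1029,
            cost_ed=(343.2, 141.8),
            cost_day_hospital=(543.4, 944.9),
            cost_index_hosp=(3907.7, 6323.2),
            cost_readmission=(4465.1, 7057.2),
        ),
        "sHF": GroupParams(
            n=1257,
            p_inhosp_death=0.109,
            p_death_30d=0.121,
            p_death_1y=0.32,
            readmit_p30=0.133,
            readmit_p365=0.436,
            reed_p30=0.156,
            reed_p365=0.564,
            outpatient_mean=11.4,
            outpatient_sd=11.7,
            day_hospital_rate=812 / 1257,
            p_no_ed_hf_code=589 / 1257,
            cost_ed=(343.5, 141.7),
            cost_day_hospital=(737.5, 1298.1),
            cost_index_hosp=(4656.1, 6532.3),
            cost_readmission=(4700.6, 7440.7),
        ),
    }
    ed_home = {
        "pHF": GroupParams(
            n=434,
            p_death_30d=0.018,
            p_death_1y=0.166,
            readmit_p30=0.118,  # first hospitalization after ED discharge
            readmit_p365=0.509,
            reed_p30=0.242,
            reed_p365=0.739,
            outpatient_mean=12.6,
            outpatient_sd=11.1,
            day_hospital_rate=0.2,
        ),
        "sHF": GroupParams(
            n=363,
            p_death_30d=0.033,
            p_death_1y=0.204,
            readmit_p30=0.088,
            readmit_p365=0.407,
            reed_p30=0.212,
            reed_p365=0.652,
            outpatient_mean=11.4,
            outpatient_sd=11.7,
            day_hospital_rate=0.2,
        ),
    }
    return SyntheticParams(
        hospitalized=hospitalized,
        ed_home=ed_home,
        n_died_in_ed={"pHF": 8, "sHF": 7},
    )


def load_params(path) -> SyntheticParams:
    with open(path, encoding="utf-8") as fh:
        return SyntheticParams.from_dict(yaml.safe_load(fh))


def save_params(params: SyntheticParams, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# generation


@dataclass
class SyntheticCohort:
    """Generated tables plus the ground-truth stratum labels."""

    episodes: list[EpisodeRecord]
    vitals: list[VitalRecord]
    cost_items: list[CostItem]
    labels: pd.DataFrame

    def write(self, out_dir) -> None:
        from pathlib import Path

        from .records import write_costs, write_episodes, write_vitals

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_episodes(self.episodes, out / "episodes.csv")
        write_vitals(self.vitals, out / "vitals.csv")
        write_costs(self.cost_items, out / "costs.csv")
        self.labels.to_csv(out / "labels.csv", index=False)


_ED_HF_PRIMARY = [DiagnosisCode(CodingSystem.ICPC2, "K77", 1)]
_ED_HF_SECONDARY = [
    DiagnosisCode(CodingSystem.ICPC2, "R02", 1),
    DiagnosisCode(CodingSystem.ICPC2, "K77", 2),
]
_ED_NO_HF = [DiagnosisCode(CodingSystem.ICPC2, "R02", 1)]
_HOSP_HF_PRIMARY = [
    DiagnosisCode(CodingSystem.ICD10CM, "I50.9", 1, True),
    DiagnosisCode(CodingSystem.ICD10CM, "E11.9", 2, True),
]
_HOSP_HF_SECONDARY = [
    DiagnosisCode(CodingSystem.ICD10CM, "J18.9", 1, True),
    DiagnosisCode(CodingSystem.ICD10CM, "I50.9", 2, True),
]
_READMIT_DX = [DiagnosisCode(CodingSystem.ICD10CM, "J18.9", 1, True)]
_REED_DX = [DiagnosisCode(CodingSystem.ICPC2, "R74", 1)]
_POINT_DX = [DiagnosisCode(CodingSystem.ICD10CM, "I50.9", 1)]


def _round_los(rng: np.random.Generator, mu: float, sigma: float) -> int:
    return max(1, int(round(float(rng.lognormal(mu, sigma)))))


def _cost_items_for(
    rng: np.random.Generator, episode_id: str, mean_sd: tuple[float, float]
) -> list[CostItem]:
    """Draw an episode total and split it into direct/catalog/residual items."""
    mu, sigma = lognormal_from_mean_sd(*mean_sd)
    total = round(float(rng.lognormal(mu, sigma)), 2)
    total = max(total, 0.03)
    direct = round(0.45 * total, 2)
    qty = int(rng.integers(1, 6))
    unit = round(0.30 * total / qty, 2)
    catalog = round(qty * unit, 2)
    residual = round(total - direct - catalog, 2)
    if residual < 0:  # tiny totals where rounding overshoots
        residual = 0.0
        direct = round(total - catalog, 2)
    items = [
        CostItem(episode_id, CostCategory.DIRECT, "direct (housing, diets, drugs)", direct),
        CostItem(
            episode_id,
            CostCategory.CATALOG,
            "catalog services",
            catalog,
            quantity=qty,
            unit_cost=unit,
        ),
        CostItem(
            episode_id, CostCategory.RESIDUAL, "residual (indirect imputation)", residual
        ),
    ]
    return [it for it in items if it.amount > 0 or it.category is CostCategory.DIRECT]


def _nb_count(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Overdispersed count: negative binomial moment-matched to mean/SD,
    falling back to Poisson when the variance is not overdispersed."""
    if mean <= 0:
        return 0
    var = sd**2
    if var <= mean:
        return int(rng.poisson(mean))
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _simulate_patient(
    rng: np.random.Generator,
    pid: str,
    arm: str,
    group: str,
    gp: GroupParams,
    year: int,
) -> tuple[list[EpisodeRecord], Optional[date], list[CostItem], dict]:
    episodes: list[EpisodeRecord] = []
    costs: list[CostItem] = []
    eid = 0

    def next_id() -> str:
        nonlocal eid
        eid += 1
        return f"{pid}-E{eid}"

    index_start = date(year, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
    ed_extra = int(rng.binomial(2, gp.ed_extra_day_p))
    hospitalized = arm == "HOSPITALIZED"
    no_ed_code = hospitalized and rng.random() < gp.p_no_ed_hf_code
    if no_ed_code:
        ed_dx = list(_ED_NO_HF)
    else:
        ed_dx = list(_ED_HF_PRIMARY if group == "pHF" else _ED_HF_SECONDARY)

    mu_los, sigma_los = lognormal_from_median_iqr(gp.los_median, gp.los_iqr)

    death_date: Optional[date] = None
    index_ed_id = next_id()
    index_hosp_id = ""
    died_in_hospital = False

    if arm == "DIED_IN_ED":
        ed_end = index_start + timedelta(days=ed_extra)
        episodes.append(
            EpisodeRecord(
                pid, index_ed_id, EpisodeKind.ED, index_start, ed_end,
                department="emergency", disposition=Disposition.DIED, diagnoses=ed_dx,
            )
        )
        costs += _cost_items_for(rng, index_ed_id, gp.cost_ed)
        death_date = ed_end
        return episodes, death_date, costs, {
            "index_episode_id": index_ed_id, "index_hosp_episode_id": "",
            "died_in_hospital": False, "discharge_date": ed_end,
        }

    if hospitalized:
        ed_end = index_start + timedelta(days=ed_extra)
        episodes.append(
            EpisodeRecord(
                pid, index_ed_id, EpisodeKind.ED, index_start, ed_end,
                department="emergency", disposition=Disposition.ADMITTED, diagnoses=ed_dx,
            )
        )
        costs += _cost_items_for(rng, index_ed_id, gp.cost_ed)
        los = _round_los(rng, mu_los, sigma_los)
        hosp_start = ed_end
        hosp_end = hosp_start + timedelta(days=los)
        died_in_hospital = rng.random() < gp.p_inhosp_death
        index_hosp_id = next_id()
        hosp_dx = list(_HOSP_HF_PRIMARY if group == "pHF" else _HOSP_HF_SECONDARY)
        episodes.append(
            EpisodeRecord(
                pid, index_hosp_id, EpisodeKind.HOSPITALIZATION, hosp_start, hosp_end,
                department="cardiology" if group == "pHF" else "internal medicine",
                disposition=Disposition.DIED if died_in_hospital else Disposition.HOME,
                diagnoses=hosp_dx,
            )
        )
        costs += _cost_items_for(rng, index_hosp_id, gp.cost_index_hosp)
        discharge = hosp_end
        if died_in_hospital:
            death_date = hosp_end
    else:
        ed_end = index_start + timedelta(days=ed_extra)
        episodes.append(
            EpisodeRecord(
                pid, index_ed_id, EpisodeKind.ED, index_start, ed_end,
                department="emergency", disposition=Disposition.HOME, diagnoses=ed_dx,
            )
        )
        costs += _cost_items_for(rng, index_ed_id, gp.cost_ed)
        discharge = ed_end

    info = {
        "index_episode_id": index_ed_id,
        "index_hosp_episode_id": index_hosp_id,
        "died_in_hospital": died_in_hospital,
        "discharge_date": discharge,
    }
    if died_in_hospital:
        return episodes, death_date, costs, info

    # --- post-discharge death -------------------------------------------------
    p30c = (gp.p_death_30d - gp.p_inhosp_death) / (1 - gp.p_inhosp_death)
    p1yc = (gp.p_death_1y - gp.p_inhosp_death) / (1 - gp.p_inhosp_death)
    d1, d2 = two_piece_hazard(p30c, p1yc)
    t_death = sample_two_piece(rng, d1, d2)
    death_offset: Optional[int] = None
    if t_death <= 365:
        death_offset = max(1, int(np.ceil(t_death)))
        death_date = discharge + timedelta(days=death_offset)

    def alive_limit() -> float:
        return death_offset if death_offset is not None else np.inf

    # --- readmissions (first event competing-calibrated, then recurrent) ------
    # utilization targets are crude over all patients of the cell; condition on
    # having survived the index hospitalization, like the death targets above
    alive0 = 1 - gp.p_inhosp_death
    r1, r2 = calibrate_competing_hazard(
        gp.readmit_p30 / alive0, gp.readmit_p365 / alive0, d1, d2
    )
    t = sample_two_piece(rng, r1, r2)
    prev_end_offset = 0.0
    while t <= 365 and t < t_death:
        start_offset = max(int(np.ceil(t)), int(prev_end_offset) + 1)
        if start_offset > 365 or start_offset >= alive_limit():
            break
        rid = next_id()
        start = discharge + timedelta(days=start_offset)
        los_r = _round_los(rng, mu_los, sigma_los)
        end = start + timedelta(days=los_r)
        disposition = Disposition.HOME
        if death_date is not None and end >= death_date:
            end = death_date
            disposition = Disposition.DIED
        episodes.append(
            EpisodeRecord(
                pid, rid, EpisodeKind.HOSPITALIZATION, start, end,
                department="internal medicine", disposition=disposition,
                diagnoses=list(_READMIT_DX),
            )
        )
        costs += _cost_items_for(rng, rid, gp.cost_readmission)
        if disposition is Disposition.DIED:
            break
        prev_end_offset = (end - discharge).days
        if r2 <= 0:
            break
        t = prev_end_offset + rng.exponential(1 / r2)

    hosp_intervals = [
        ((e.start_date - discharge).days, (e.end_date - discharge).days)
        for e in episodes
        if e.kind is EpisodeKind.HOSPITALIZATION and e.start_date >= discharge
    ]

    def in_hospital(offset: int) -> bool:
        return any(lo <= offset < max(hi, lo + 1) for lo, hi in hosp_intervals)

    # --- ED revisits -----------------------------------------------------------
    e1, e2 = calibrate_competing_hazard(
        gp.reed_p30 / alive0, gp.reed_p365 / alive0, d1, d2
    )
    t = sample_two_piece(rng, e1, e2)
    while t <= 365 and t < t_death:
        start_offset = int(np.ceil(t))
        if start_offset >= 1 and start_offset <= 365 and start_offset < alive_limit():
            vid = next_id()
            start = discharge + timedelta(days=start_offset)
            extra = int(rng.binomial(2, gp.ed_extra_day_p))
            end = start + timedelta(days=extra)
            if death_date is not None and end > death_date:
                end = death_date
            episodes.append(
                EpisodeRecord(
                    pid, vid, EpisodeKind.ED, start, end,
                    department="emergency", disposition=Disposition.HOME,
                    diagnoses=list(_REED_DX),
                )
            )
            costs += _cost_items_for(rng, vid, gp.cost_ed)
        if e2 <= 0:
            break
        t = t + rng.exponential(1 / e2)

    # --- outpatient and day-hospital point episodes ----------------------------
    last_day = int(min(365, alive_limit() - 1))
    if last_day >= 1:
        candidates = np.array(
            [d for d in range(1, last_day + 1) if not in_hospital(d)], dtype=int
        )
        n_op = min(_nb_count(rng, gp.outpatient_mean, gp.outpatient_sd), candidates.size)
        if n_op > 0:
            days = rng.choice(candidates, size=n_op, replace=False)
            for d in sorted(int(x) for x in days):
                oid = next_id()
                day = discharge + timedelta(days=d)
                episodes.append(
                    EpisodeRecord(
                        pid, oid, EpisodeKind.OUTPATIENT, day, day,
                        department="cardiology", disposition=Disposition.HOME,
                        diagnoses=list(_POINT_DX),
                    )
                )
        n_dh = min(int(rng.poisson(gp.day_hospital_rate)), candidates.size)
        if n_dh > 0:
            days = rng.choice(candidates, size=n_dh, replace=False)
            for d in sorted(int(x) for x in days):
                did = next_id()
                day = discharge + timedelta(days=d)
                episodes.append(
                    EpisodeRecord(
                        pid, did, EpisodeKind.DAY_HOSPITAL, day, day,
                        department="day hospital", disposition=Disposition.HOME,
                        diagnoses=list(_POINT_DX),
                    )
                )
                costs += _cost_items_for(rng, did, gp.cost_day_hospital)
    return episodes, death_date, costs, info


_ARM_CELLS = (
    ("HOSPITALIZED", "hospitalized"),
    ("DISCHARGED_HOME_FROM_ED", "ed_home"),
)


def generate_cohort(params: SyntheticParams, seed: int) -> SyntheticCohort:
    """Generate episode/vital/cost tables plus ground-truth labels.

    Identical ``(params, seed)`` reproduce the cohort exactly; each patient
    draws from an independent child stream of the seed.
    """
    params.validate()
    episodes: list[EpisodeRecord] = []
    vitals: list[VitalRecord] = []
    cost_items: list[CostItem] = []
    label_rows = []

    cells: list[tuple[str, str, GroupParams]] = []
    for arm, attr in _ARM_CELLS:
        for group, gp in getattr(params, attr).items():
            cells.append((arm, group, gp))
    for group, n in params.n_died_in_ed.items():
        if n > 0:
            base = params.ed_home.get(group) or next(iter(params.ed_home.values()), None)
            gp = replace(base, n=n) if base is not None else GroupParams(n=n)
            cells.append(("DIED_IN_ED", group, gp))

    arm_codes = {"HOSPITALIZED": "H", "DISCHARGED_HOME_FROM_ED": "D", "DIED_IN_ED": "X"}
    for ci, (arm, group, gp) in enumerate(cells):
        for i in range(gp.n):
            ss = np.random.SeedSequence(seed, spawn_key=(ci, i))
            rng = np.random.default_rng(ss)
            pid = f"{arm_codes[arm]}-{group}-{i:05d}"
            eps, death_date, costs, info = _simulate_patient(
                rng, pid, arm, group, gp, params.year
            )
            episodes.extend(eps)
            cost_items.extend(costs)
            vitals.append(VitalRecord(patient_id=pid, death_date=death_date))
            label_rows.append(
                {
                    "patient_id": pid,
                    "arm": arm,
                    "hf_group": group,
                    "index_episode_id": info["index_episode_id"],
                    "index_hosp_episode_id": info["index_hosp_episode_id"],
                    "died_in_hospital": info["died_in_hospital"],
                    "death_date": death_date.isoformat() if death_date else "",
                }
            )
    episodes.sort(key=lambda e: (e.patient_id, e.start_date, e.episode_id))
    vitals.sort(key=lambda v: v.patient_id)
    labels = pd.DataFrame(label_rows).sort_values("patient_id").reset_index(drop=True)
    return SyntheticCohort(
        episodes=episodes, vitals=vitals, cost_items=cost_items, labels=labels
    )


# ---------------------------------------------------------------------------
# parameter recovery


def recover_params(cohort: SyntheticCohort, year: int = 2018) -> dict:
    """Empirical per-cell rates/medians from a generated cohort, computed with
    the analysis pipeline itself (cohort builder + event rates).

    Returns a nested dict keyed by arm then group with observed in-hospital /
    30-day / 1-year mortality, 30-day / 1-year readmission and re-ED rates,
    median index LOS and mean episode costs per class.
    """
    from .cohort import build_strata
    from .engine import length_of_stay
    from .stats import EventType, build_followups, event_rate, in_hospital_mortality

    strata = build_strata(cohort.episodes, cohort.vitals, year)
    eps_by_id = {e.episode_id: e for e in cohort.episodes}
    cost_by_episode: dict[str, float] = {}
    for it in cohort.cost_items:
        cost_by_episode[it.episode_id] = cost_by_episode.get(it.episode_id, 0.0) + it.amount

    out: dict = {}
    for arm in ("HOSPITALIZED", "DISCHARGED_HOME_FROM_ED"):
        for group in ("pHF", "sHF"):
            sub = strata.select(arm=arm, hf_group=group)
            if len(sub) == 0:
                continue
            fus = build_followups(sub, cohort.episodes, cohort.vitals)
            cell = {
                "n": len(sub),
                "p_death_30d": event_rate(fus, EventType.DEATH, 30).rate,
                "p_death_1y": event_rate(fus, EventType.DEATH, 365).rate,
                "readmit_p30": event_rate(fus, EventType.READMISSION, 30).rate,
                "readmit_p365": event_rate(fus, EventType.READMISSION, 365).rate,
                "reed_p30": event_rate(fus, EventType.RE_ED_VISIT, 30).rate,
                "reed_p365": event_rate(fus, EventType.RE_ED_VISIT, 365).rate,
            }
            if arm == "HOSPITALIZED":
                cell["p_inhosp_death"] = in_hospital_mortality(sub, cohort.episodes).rate
                los = [
                    length_of_stay(eps_by_id[r])
                    for r in sub["index_hosp_episode_id"]
                    if r in eps_by_id
                ]
                cell["los_median"] = float(np.median(los))
                idx_costs = [
                    cost_by_episode.get(r, 0.0) for r in sub["index_hosp_episode_id"]
                ]
                cell["cost_index_hosp_mean"] = float(np.mean(idx_costs))
            out.setdefault(arm, {})[group] = cell
    return out
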