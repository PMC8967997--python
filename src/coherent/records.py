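"""Shared data model and delimited-table I/O for episode-level administrative records.

The package works from three flat tables, mirroring a minimum-basic-dataset
style export of hospital activity:

* ``episodes.csv`` — one row per care episode (ED visit, hospitalization,
  day-hospital session or outpatient visit) with dates, department,
  disposition and a packed diagnosis column.
* ``vitals.csv``   — one row per patient with a death date (empty if alive).
* ``costs.csv``    — one cost line item per row, attached to an episode.

All dates are ISO-8601 calendar dates; all interval arithmetic elsewhere in
the package is in whole days.  Episode intervals are closed on both calendar
dates at this layer; any half-open convention is applied by the state engine,
not by the file format.  Files are UTF-8, comma-delimited, decimal point —
fixed so that write -> read round-trips are bit-exact.

Diagnoses are packed into a single ``|``-separated column, one
``system:code:position:poa`` token per diagnosis (e.g.
``ICD10CM:I50.9:1:Y``).  ``position`` may be empty when the source system did
not rank the diagnosis; ``poa`` (present-on-admission) is ``Y``/``N`` for
hospitalization diagnoses and empty otherwise.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "CodingSystem",
    "EpisodeKind",
    "Disposition",
    "CostCategory",
    "DiagnosisCode",
    "EpisodeRecord",
    "VitalRecord",
    "CostItem",
    "SchemaError",
    "RowError",
    "ValidationError",
    "ReadReport",
    "read_episodes",
    "write_episodes",
    "read_vitals",
    "write_vitals",
    "read_costs",
    "write_costs",
    "scan_episodes",
    "EPISODE_COLUMNS",
    "VITAL_COLUMNS",
    "COST_COLUMNS",
]


class CodingSystem(str, enum.Enum):
    """Diagnosis coding system: ICD-10-CM (hospital) or ICPC-2 (ED)."""

    ICD10CM = "ICD10CM"
    ICPC2 = "ICPC2"


class EpisodeKind(str, enum.Enum):
    ED = "ED"
    HOSPITALIZATION = "HOSPITALIZATION"
    DAY_HOSPITAL = "DAY_HOSPITAL"
    OUTPATIENT = "OUTPATIENT"


class Disposition(str, enum.Enum):
    HOME = "HOME"
    ADMITTED = "ADMITTED"
    DIED = "DIED"
    OTHER = "OTHER"


class CostCategory(str, enum.Enum):
    """Full-costing components of an episode cost.

    DIRECT — costs directly imputable to the patient/episode (housing, diets,
    drugs, devices); CATALOG — unit-priced products or activities from the
    hospital service catalog (labs, imaging, procedures); RESIDUAL — costs
    that cannot be directly imputed and are transferred to episodes via an
    imputation weight.
    """

    DIRECT = "DIRECT"
    CATALOG = "CATALOG"
    RESIDUAL = "RESIDUAL"


class SchemaError(ValueError):
    """A table is missing a required column."""


class RowError(ValueError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class ValidationError(ValueError):
    """A record violates a type invariant."""


@dataclass(frozen=True)
class DiagnosisCode:
    """One coded diagnosis attached to an episode.

    ``position`` is the 1-based rank (1 = principal diagnosis) and may be
    ``None`` when the source did not define it.  ``present_on_admission``
    is only meaningful on hospitalization episodes.
    """

    system: CodingSystem
    code: str
    position: Optional[int] = None
    present_on_admission: Optional[bool] = None

    def validate(self) -> None:
        if not self.code:
            raise ValidationError("diagnosis code must be non-empty")
        if self.position is not None and self.position < 1:
            raise ValidationError(f"diagnosis position must be >= 1, got {self.position}")


@dataclass
class EpisodeRecord:
    """One care episode of one patient."""

    patient_id: str
    episode_id: str
    kind: EpisodeKind
    start_date: date
    end_date: date
    department: str = "other"
    disposition: Disposition = Disposition.HOME
    diagnoses: list[DiagnosisCode] = field(default_factory=list)

    def validate(self) -> None:
        if self.end_date < self.start_date:
            raise ValidationError(
                f"episode {self.episode_id}: end_date {self.end_date} before "
                f"start_date {self.start_date}"
            )
        if self.kind in (EpisodeKind.OUTPATIENT, EpisodeKind.DAY_HOSPITAL):
            if self.end_date != self.start_date:
                raise ValidationError(
                    f"episode {self.episode_id}: {self.kind.value} episodes are "
                    "point visits (end_date must equal start_date)"
                )
        positions = [d.position for d in self.diagnoses if d.position is not None]
        if len(positions) != len(set(positions)):
            raise ValidationError(
                f"episode {self.episode_id}: duplicate diagnosis positions"
            )
        for d in self.diagnoses:
            d.validate()
            if d.system is CodingSystem.ICPC2 and self.kind is not EpisodeKind.ED:
                raise ValidationError(
                    f"episode {self.episode_id}: ICPC-2 codes may only be "
                    "attached to ED episodes"
                )


@dataclass
class VitalRecord:
    """Vital status of one patient: a death date, or none if alive."""

    patient_id: str
    death_date: Optional[date] = None


@dataclass
class CostItem:
    """One cost line item attached to an episode.

    ``quantity`` and ``unit_cost`` are populated for CATALOG items only, and
    then ``amount = quantity * unit_cost`` (at cent precision).
    """

    episode_id: str
    category: CostCategory
    description: str
    amount: float
    quantity: Optional[float] = None
    unit_cost: Optional[float] = None

    def validate(self) -> None:
        if self.amount < 0:
            raise ValidationError(
                f"cost item on episode {self.episode_id}: negative amount {self.amount}"
            )
        if self.category is CostCategory.CATALOG:
            if self.quantity is None or self.unit_cost is None:
                raise ValidationError(
                    f"CATALOG item on episode {self.episode_id} needs quantity and unit_cost"
                )
            if self.quantity < 0:
                raise ValidationError("quantity must be non-negative")
            if round(self.quantity * self.unit_cost, 2) != round(self.amount, 2):
                raise ValidationError(
                    f"CATALOG item on episode {self.episode_id}: amount {self.amount} "
                    f"!= quantity x unit_cost {self.quantity * self.unit_cost}"
                )


# ---------------------------------------------------------------------------
# diagnosis packing

_DX_SEP = "|"
_DX_FIELD_SEP = ":"


def pack_diagnoses(diagnoses: Sequence[DiagnosisCode]) -> str:
    tokens = []
    for d in diagnoses:
        pos = "" if d.position is None else str(d.position)
        if d.present_on_admission is None:
            poa = ""
        else:
            poa = "Y" if d.present_on_admission else "N"
        tokens.append(_DX_FIELD_SEP.join([d.system.value, d.code, pos, poa]))
    return _DX_SEP.join(tokens)


def unpack_diagnoses(packed: str) -> list[DiagnosisCode]:
    if not packed:
        return []
    out = []
    for token in packed.split(_DX_SEP):
        parts = token.split(_DX_FIELD_SEP)
        if len(parts) != 4:
            raise ValueError(f"malformed diagnosis token {token!r}")
        system, code, pos, poa = parts
        out.append(
            DiagnosisCode(
                system=CodingSystem(system),
                code=code,
                position=int(pos) if pos else None,
                present_on_admission={"Y": True, "N": False, "": None}[poa],
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV schemas

EPISODE_COLUMNS = [
    "patient_id",
    "episode_id",
    "kind",
    "start_date",
    "end_date",
    "department",
    "disposition",
    "diagnoses",
]
VITAL_COLUMNS = ["patient_id", "death_date"]
COST_COLUMNS = ["episode_id", "category", "description", "quantity", "unit_cost", "amount"]


def _parse_date(s: str) -> date:
    return date.fromisoformat(s)


def _check_header(header: Sequence[str], required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _episode_from_row(row: dict, line: int) -> EpisodeRecord:
    try:
        kind = EpisodeKind(row["kind"])
    except ValueError:
        raise RowError(f"unknown kind {row['kind']!r}", line) from None
    try:
        disposition = Disposition(row["disposition"])
    except ValueError:
        raise RowError(f"unknown disposition {row['disposition']!r}", line) from None
    try:
        start = _parse_date(row["start_date"])
        end = _parse_date(row["end_date"])
    except ValueError as exc:
        raise RowError(f"unparseable date ({exc})", line) from None
    try:
        diagnoses = unpack_diagnoses(row["diagnoses"])
    except ValueError as exc:
        raise RowError(str(exc), line) from None
    return EpisodeRecord(
        patient_id=row["patient_id"],
        episode_id=row["episode_id"],
        kind=kind,
        start_date=start,
        end_date=end,
        department=row["department"],
        disposition=disposition,
        diagnoses=diagnoses,
    )


@dataclass
class ReadReport:
    """Result of a lenient table scan: parsed records plus rejected rows."""

    records: list
    rejected: list[RowError]

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_episodes(path) -> list[EpisodeRecord]:
    """Read an episodes table, raising on the first malformed or invalid row.

    Rows are returned sorted by ``(patient_id, start_date)``.
    """
    report = scan_episodes(path)
    if report.rejected:
        raise report.rejected[0]
    return report.records


def scan_episodes(path) -> ReadReport:
    """Lenient episode reader: parse what is valid, collect row errors.

    Structural problems (missing columns) still raise :class:`SchemaError`;
    rows violating type invariants or with unparseable fields are collected
    in ``report.rejected`` with their line numbers.
    """
    path = Path(path)
    records: list[EpisodeRecord] = []
    rejected: list[RowError] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        _check_header(reader.fieldnames, EPISODE_COLUMNS, path)
        for line, row in enumerate(reader, start=2):
            try:
                rec = _episode_from_row(row, line)
                rec.validate()
            except RowError as exc:
                rejected.append(exc)
                continue
            except ValidationError as exc:
                rejected.append(RowError(str(exc), line))
                continue
            records.append(rec)
    records.sort(key=lambda r: (r.patient_id, r.start_date, r.episode_id))
    return ReadReport(records=records, rejected=rejected)


def write_episodes(records: Iterable[EpisodeRecord], path) -> None:
    """Write an episodes table; validates every record before any write."""
    records = list(records)
    for rec in records:
        rec.validate()
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EPISODE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.episode_id,
                    r.kind.value,
                    r.start_date.isoformat(),
                    r.end_date.isoformat(),
                    r.department,
                    r.disposition.value,
                    pack_diagnoses(r.diagnoses),
                ]
            )


def read_vitals(path) -> list[VitalRecord]:
    path = Path(path)
    out: list[VitalRecord] = []
    seen: set[str] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        _check_header(reader.fieldnames, VITAL_COLUMNS, path)
        for line, row in enumerate(reader, start=2):
            pid = row["patient_id"]
            if pid in seen:
                raise RowError(f"duplicate vital record for patient {pid}", line)
            seen.add(pid)
            dd = row["death_date"]
            try:
                death = _parse_date(dd) if dd else None
            except ValueError as exc:
                raise RowError(f"unparseable date ({exc})", line) from None
            out.append(VitalRecord(patient_id=pid, death_date=death))
    out.sort(key=lambda r: r.patient_id)
    return out


def write_vitals(records: Iterable[VitalRecord], path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(VITAL_COLUMNS)
        for r in records:
            writer.writerow(
                [r.patient_id, r.death_date.isoformat() if r.death_date else ""]
            )


def _fmt_money(x: Optional[float]) -> str:
    return "" if x is None else f"{x:.2f}"


def read_costs(path) -> list[CostItem]:
    path = Path(path)
    out: list[CostItem] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        _check_header(reader.fieldnames, COST_COLUMNS, path)
        for line, row in enumerate(reader, start=2):
            try:
                category = CostCategory(row["category"])
            except ValueError:
                raise RowError(f"unknown cost category {row['category']!r}", line) from None
            try:
                item = CostItem(
                    episode_id=row["episode_id"],
                    category=category,
                    description=row["description"],
                    quantity=float(row["quantity"]) if row["quantity"] else None,
                    unit_cost=float(row["unit_cost"]) if row["unit_cost"] else None,
                    amount=float(row["amount"]),
                )
            except ValueError as exc:
                raise RowError(f"unparseable number ({exc})", line) from None
            try:
                item.validate()
            except ValidationError as exc:
                raise RowError(str(exc), line) from None
            out.append(item)
    return out


def write_costs(items: Iterable[CostItem], path) -> None:
    items = list(items)
    for it in items:
        it.validate()
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COST_COLUMNS)
        for it in items:
            qty = "" if it.quantity is None else (
                str(int(it.quantity)) if float(it.quantity).is_integer() else repr(it.quantity)
            )
            writer.writerow(
                [
                    it.episode_id,
                    it.category.value,
                    it.description,
                    qty,
                    _fmt_money(it.unit_cost),
                    _fmt_money(it.amount),
                ]
            )
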