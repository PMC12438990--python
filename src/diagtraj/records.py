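"""Reading, writing and validation of tabular diagnostic event records.

The input is a UTF-8 delimited file (comma default, tab accepted) with header
``person_id,sex,birth_date,event_date,event_type,icd10,parental_education``
and ISO-8601 dates.  Each row is one dated event for one person: a main
psychiatric discharge diagnosis, a death, or an emigration.  Only main
diagnoses belong in the file; if a source also carries concurrent secondary
diagnoses the caller must pre-filter them, since the format has no
main/secondary flag.

Reading is total: every row is either accepted or rejected with a named
reason collected in an :class:`IngestReport`, and accepted + rejected equals
the row count.  Person-level invariants (single death, no events after
death) are enforced in a second pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable

from .taxonomy import InvalidCodeError, normalize_code

SCHEMA: tuple[str, ...] = (
    "person_id", "sex", "birth_date", "event_date",
    "event_type", "icd10", "parental_education",
)

EVENT_TYPES = ("DIAGNOSIS", "DEATH", "EMIGRATION")
SEXES = ("F", "M")
EDUCATION_LEVELS = ("SHORT", "MEDIUM", "LONG", "UNKNOWN")

#: Average-year divisor used for exact ages in years.
DAYS_PER_YEAR = 365.25


class SchemaError(ValueError):
    """Raised when the input file header does not match the record schema."""


@dataclass(frozen=True)
class DiagnosisRecord:
    """One dated registry event (diagnosis, death, or emigration)."""

    person_id: str
    sex: str
    birth_date: date
    event_date: date
    event_type: str
    icd10: str = ""
    parental_education: str = "UNKNOWN"

    def age_at_event(self) -> float:
        """Age in years at the event date (exact days / 365.25)."""
        return (self.event_date - self.birth_date).days / DAYS_PER_YEAR


@dataclass
class Rejection:
    row_index: int  # 1-based data row index
    reason: str
    detail: str


@dataclass
class IngestReport:
    """Accounting of an ingest: every input row is accepted or rejected."""

    n_rows: int = 0
    n_accepted: int = 0
    rejections: list[Rejection] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.rejections:
            out[r.reason] = out.get(r.reason, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_accepted": self.n_accepted,
            "n_rejected": self.n_rejected,
            "reasons": self.reasons(),
            "rejections": [
                {"row": r.row_index, "reason": r.reason, "detail": r.detail}
                for r in self.rejections
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_text(self) -> str:
        lines = [
            f"rows: {self.n_rows}  accepted: {self.n_accepted}  "
            f"rejected: {self.n_rejected}"
        ]
        for reason, n in sorted(self.reasons().items()):
            lines.append(f"  {reason}: {n}")
        return "\n".join(lines)


def _parse_row(idx: int, row: dict[str, str]) -> DiagnosisRecord:
    sex = row["sex"].strip().upper()
    if sex not in SEXES:
        raise ValueError(f"bad_sex: {row['sex']!r}")
    try:
        birth = date.fromisoformat(row["birth_date"].strip())
        event = date.fromisoformat(row["event_date"].strip())
    except ValueError as exc:
        raise ValueError(f"bad_date: {exc}") from None
    if event < birth:
        raise ValueError(f"date_order: event {event} before birth {birth}")
    etype = row["event_type"].strip().upper()
    if etype not in EVENT_TYPES:
        raise ValueError(f"bad_event_type: {row['event_type']!r}")
    code = (row.get("icd10") or "").strip()
    if etype == "DIAGNOSIS":
        if not code:
            raise ValueError("missing_code: DIAGNOSIS row without icd10")
        try:
            code = normalize_code(code)
        except InvalidCodeError as exc:
            reason = "non_F_code" if code and not code.upper().startswith("F") else "bad_code"
            raise ValueError(f"{reason}: {exc}") from None
    elif code:
        raise ValueError(f"code_on_nondiagnosis: {etype} row carries {code!r}")
    edu = (row.get("parental_education") or "UNKNOWN").strip().upper() or "UNKNOWN"
    if edu not in EDUCATION_LEVELS:
        raise ValueError(f"bad_education: {row['parental_education']!r}")
    return DiagnosisRecord(
        person_id=row["person_id"].strip(),
        sex=sex,
        birth_date=birth,
        event_date=event,
        event_type=etype,
        icd10=code if etype == "DIAGNOSIS" else "",
        parental_education=edu,
    )


def read_records(path: str | Path, delimiter: str | None = None) -> tuple[list[DiagnosisRecord], IngestReport]:
    """Parse an event file; returns accepted records and an ingest report."""
    import csv

    path = Path(path)
    report = IngestReport()
    with path.open(newline="", encoding="utf-8") as fh:
        head = fh.readline()
        if delimiter is None:
            delimiter = "\t" if "\t" in head else ","
        names = [c.strip() for c in head.rstrip("\n").split(delimiter)]
        missing = [c for c in SCHEMA if c not in names]
        if missing:
            raise SchemaError(f"missing columns in {path.name}: {missing}")
        reader = csv.DictReader(fh, fieldnames=names, delimiter=delimiter)
        accepted: list[tuple[int, DiagnosisRecord]] = []
        rows_of: dict[str, list[tuple[int, DiagnosisRecord]]] = {}
        for idx, row in enumerate(reader, start=1):
            report.n_rows += 1
            try:
                rec = _parse_row(idx, row)
            except ValueError as exc:
                reason = str(exc).split(":", 1)[0]
                report.rejections.append(Rejection(idx, reason, str(exc)))
                continue
            accepted.append((idx, rec))
            rows_of.setdefault(rec.person_id, []).append((idx, rec))

    # person-level invariants: one death, nothing after death
    drop: set[int] = set()
    for pid, items in rows_of.items():
        items_sorted = sorted(items, key=lambda t: (t[1].event_date, t[0]))
        death_seen = False
        for idx, rec in items_sorted:
            if death_seen:
                reason = "multiple_death" if rec.event_type == "DEATH" else "event_after_death"
                report.rejections.append(
                    Rejection(idx, reason, f"{pid}: {rec.event_type} on {rec.event_date}")
                )
                drop.add(idx)
            elif rec.event_type == "DEATH":
                death_seen = True
    records = [rec for idx, rec in accepted if idx not in drop]
    report.n_accepted = len(records)
    return records, report


def write_records(records: Iterable[DiagnosisRecord], path: str | Path, delimiter: str = ",") -> None:
    """Write records in the canonical column order (round-trips exactly)."""
    import csv

    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(SCHEMA)
        for r in records:
            writer.writerow(
                [
                    r.person_id, r.sex, r.birth_date.isoformat(),
                    r.event_date.isoformat(), r.event_type, r.icd10,
                    r.parental_education,
                ]
            )


@dataclass
class CohortIndex:
    """Per-person sorted event lists plus the identified first diagnosis.

    The first diagnosis (cohort entry) is the chronologically first
    DIAGNOSIS record with age strictly below ``max_age`` years; same-day
    ties are broken by the last record that day in file order, mirroring
    the last-diagnosis-per-window convention used in sequence building.
    """

    events: dict[str, list[DiagnosisRecord]]
    d1: dict[str, DiagnosisRecord]
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def person_ids(self) -> list[str]:
        return sorted(self.d1)


def identify_d1(records: Iterable[DiagnosisRecord], max_age: float = 18.0) -> CohortIndex:
    """Build the cohort index: one entry diagnosis per eligible person."""
    per_person: dict[str, list[DiagnosisRecord]] = {}
    order: dict[int, int] = {}
    for i, rec in enumerate(records):
        per_person.setdefault(rec.person_id, []).append(rec)
        order[id(rec)] = i
    events: dict[str, list[DiagnosisRecord]] = {}
    d1: dict[str, DiagnosisRecord] = {}
    excluded: dict[str, str] = {}
    for pid, recs in per_person.items():
        recs = sorted(recs, key=lambda r: (r.event_date, order[id(r)]))
        events[pid] = recs
        chosen: DiagnosisRecord | None = None
        for rec in recs:
            if rec.event_type == "DEATH" and chosen is None:
                excluded[pid] = "death_before_diagnosis"
                break
            if rec.event_type != "DIAGNOSIS":
                continue
            if chosen is None:
                if rec.age_at_event() >= max_age:
                    excluded[pid] = "no_under18_diagnosis"
                    break
                chosen = rec
            elif rec.event_date == chosen.event_date:
                chosen = rec  # same-day tie: last in file order wins
            else:
                break
        if chosen is not None and pid not in excluded:
            d1[pid] = chosen
        elif pid not in excluded:
            excluded[pid] = "no_diagnosis"
    return CohortIndex(events=events, d1=d1, excluded=excluded)
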