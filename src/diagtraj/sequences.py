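"""Annual diagnostic state sequences built from dated records.

Follow-up after the entry diagnosis is divided into 10 consecutive 12-month
periods (12 months meaning the same day-of-month one year on, with
end-of-month clamping).  Each period's state is the category of the *last*
diagnosis dated inside that window — the most recent diagnosis is taken to
have the higher clinical validity — and the prevailing state is projected
forward through diagnosis-free windows.  A death or emigration event makes
the remainder of the sequence absorbing (death wins same-window ties); the
entry period itself always records the diagnostic state, with an absorbing
event there taking effect from the second period.

Within-category code changes (e.g. F32 -> F33, both SRD) do not alter the
state: sequences are defined over the 19 analysis categories.  Diagnoses
mapping to no category are ignored in windowing and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import pandas as pd

from .records import CohortIndex, DiagnosisRecord
from .taxonomy import (
    DEAD,
    EMIGRATED,
    SEQUENCE_ALPHABET,
    UNMAPPED,
    CategoryTaxonomy,
)

logger = logging.getLogger(__name__)

N_PERIODS = 10
PERIOD_MONTHS = 12

AGE_BANDS = ("0-10", "11-17")


class SequenceError(ValueError):
    """Raised for record sets that cannot form a valid sequence."""


def age_band(age_years: float) -> str:
    """Age band at cohort entry: 0-10 versus 11-17 years."""
    return AGE_BANDS[0] if age_years < 11.0 else AGE_BANDS[1]


def period_starts(d1_date: date, n_periods: int = N_PERIODS,
                  period_months: int = PERIOD_MONTHS) -> list[date]:
    """Start dates of periods 1..n+1 (the last is the follow-up end)."""
    t0 = pd.Timestamp(d1_date)
    return [
        (t0 + pd.DateOffset(months=period_months * k)).date()
        for k in range(n_periods + 1)
    ]


@dataclass(frozen=True)
class StateSequence:
    """A person's ordered annual trajectory over the 21-state alphabet."""

    person_id: str
    d1_category: str
    states: tuple[str, ...]
    d1_date: date
    sex: str
    age_band_at_d1: str
    parental_education: str
    entry_year: int

    def __post_init__(self) -> None:
        if self.states and self.states[0] in (DEAD, EMIGRATED):
            raise SequenceError("entry state cannot be absorbing")


@dataclass
class SequenceSet:
    """Sequences sharing a stratum, with their common alphabet."""

    label: tuple[str, ...]
    sequences: list[StateSequence]
    alphabet: tuple[str, ...] = SEQUENCE_ALPHABET

    def __len__(self) -> int:
        return len(self.sequences)


def build_sequence(
    records: Sequence[DiagnosisRecord],
    d1: DiagnosisRecord,
    taxonomy: CategoryTaxonomy,
    n_periods: int = N_PERIODS,
    period_months: int = PERIOD_MONTHS,
) -> StateSequence:
    """Windowed state assignment for one person.

    ``records`` must be the person's events sorted by date (same-day order
    preserved from the file); ``d1`` is the entry diagnosis, which must be
    the first diagnosis chronologically.
    """
    if not records:
        raise SequenceError("no records for person")
    for rec in records:
        if rec.event_type == "DIAGNOSIS" and rec.event_date < d1.event_date:
            raise SequenceError(
                f"{d1.person_id}: entry diagnosis is not the first "
                f"(found {rec.icd10} on {rec.event_date})"
            )
    d1_category = taxonomy.map_code(d1.icd10)
    if d1_category == UNMAPPED:
        raise SequenceError(f"{d1.person_id}: entry code {d1.icd10} is unmapped")

    bounds = period_starts(d1.event_date, n_periods, period_months)
    states: list[str] = []
    prevailing = d1_category
    for k in range(n_periods):
        start, end = bounds[k], bounds[k + 1]
        absorbing: str | None = None
        for rec in records:
            if not (start <= rec.event_date < end):
                continue
            if rec.event_type == "DEATH":
                absorbing = DEAD  # death beats emigration and any diagnosis
            elif rec.event_type == "EMIGRATION":
                if absorbing != DEAD:
                    absorbing = EMIGRATED
            else:
                cat = taxonomy.map_code(rec.icd10)
                if cat == UNMAPPED:
                    logger.debug("ignoring unmapped code %s for %s",
                                 rec.icd10, rec.person_id)
                    continue
                prevailing = cat  # last mapped diagnosis in window wins
        if absorbing is not None and k > 0:
            states.extend([absorbing] * (n_periods - k))
            break
        states.append(prevailing)
        if absorbing is not None:  # absorbing event inside the entry window
            states.extend([absorbing] * (n_periods - 1 - k))
            break

    return StateSequence(
        person_id=d1.person_id,
        d1_category=d1_category,
        states=tuple(states),
        d1_date=d1.event_date,
        sex=d1.sex,
        age_band_at_d1=age_band(d1.age_at_event()),
        parental_education=d1.parental_education,
        entry_year=d1.event_date.year,
    )


def build_sequences(
    cohort: CohortIndex,
    taxonomy: CategoryTaxonomy | None = None,
    n_periods: int = N_PERIODS,
    period_months: int = PERIOD_MONTHS,
) -> list[StateSequence]:
    """Build one sequence per indexed person, sorted by person id."""
    taxonomy = taxonomy or CategoryTaxonomy.default()
    out = []
    for pid in cohort.person_ids:
        out.append(
            build_sequence(cohort.events[pid], cohort.d1[pid], taxonomy,
                           n_periods, period_months)
        )
    return out


_STRATIFIERS = ("d1", "sex", "age_band", "education", "entry_year_band")


def build_sequence_set(
    sequences: Iterable[StateSequence],
    stratifiers: Sequence[str] = ("d1", "sex"),
    entry_year_bands: Sequence[tuple[int, int]] | None = None,
) -> list[SequenceSet]:
    """Partition sequences into strata (empty strata are omitted).

    Stratifiers: ``d1``, ``sex``, ``age_band``, ``education`` and
    ``entry_year_band`` (requires ``entry_year_bands`` as inclusive year
    ranges).
    """
    for s in stratifiers:
        if s not in _STRATIFIERS:
            raise ValueError(f"unknown stratifier {s!r}; choose from {_STRATIFIERS}")
    if "entry_year_band" in stratifiers and not entry_year_bands:
        raise ValueError("entry_year_band stratifier needs entry_year_bands")

    def year_band(year: int) -> str:
        for lo, hi in entry_year_bands or ():
            if lo <= year <= hi:
                return f"{lo}-{hi}"
        return "other"

    keys = {
        "d1": lambda q: q.d1_category,
        "sex": lambda q: q.sex,
        "age_band": lambda q: q.age_band_at_d1,
        "education": lambda q: q.parental_education,
        "entry_year_band": lambda q: year_band(q.entry_year),
    }
    strata: dict[tuple[str, ...], list[StateSequence]] = {}
    for seq in sequences:
        label = tuple(keys[s](seq) for s in stratifiers)
        strata.setdefault(label, []).append(seq)
    return [SequenceSet(label=k, sequences=v) for k, v in sorted(strata.items())]


@dataclass
class FrequencyTable:
    """Distinct-sequence counts with small-cell suppression.

    ``displayed`` holds sequences supported by at least ``min_count``
    persons, count-descending; rarer sequences are pooled into a single
    residual so displayed + residual always equals the stratum size.
    """

    displayed: pd.DataFrame  # columns: sequence, count
    suppressed_count: int
    suppressed_distinct: int
    min_count: int

    @property
    def total(self) -> int:
        return int(self.displayed["count"].sum()) + self.suppressed_count


def sequence_frequency_table(sset: SequenceSet, min_count: int = 5) -> FrequencyTable:
    """Tabulate distinct sequences, suppressing cells below ``min_count``."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not sset.sequences:
        raise ValueError(f"empty sequence set {sset.label}")
    counts: dict[tuple[str, ...], int] = {}
    for seq in sset.sequences:
        counts[seq.states] = counts.get(seq.states, 0) + 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    shown = [(">".join(s), n) for s, n in items if n >= min_count]
    hidden = [(s, n) for s, n in items if n < min_count]
    df = pd.DataFrame(shown, columns=["sequence", "count"])
    return FrequencyTable(
        displayed=df,
        suppressed_count=sum(n for _, n in hidden),
        suppressed_distinct=len(hidden),
        min_count=min_count,
    )


def sequences_to_frame(sequences: Iterable[StateSequence], wide: bool = True) -> pd.DataFrame:
    """Tabular export: wide (person_id, s1..s10, metadata) or long
    (person_id, period_index, state)."""
    seqs = list(sequences)
    if wide:
        rows = [
            {
                "person_id": q.person_id,
                "d1_category": q.d1_category,
                "sex": q.sex,
                "age_band_at_d1": q.age_band_at_d1,
                "parental_education": q.parental_education,
                "entry_year": q.entry_year,
                "d1_date": q.d1_date.isoformat(),
                **{f"s{k + 1}": s for k, s in enumerate(q.states)},
            }
            for q in seqs
        ]
        return pd.DataFrame(rows)
    rows = [
        {"person_id": q.person_id, "period_index": k + 1, "state": s}
        for q in seqs
        for k, s in enumerate(q.states)
    ]
    return pd.DataFrame(rows)


def frame_to_sequences(frame: pd.DataFrame) -> list[StateSequence]:
    """Inverse of :func:`sequences_to_frame` (wide format)."""
    state_cols = sorted(
        (c for c in frame.columns if c.startswith("s") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    out = []
    for _, row in frame.iterrows():
        out.append(
            StateSequence(
                person_id=str(row["person_id"]),
                d1_category=str(row["d1_category"]),
                states=tuple(str(row[c]) for c in state_cols),
                d1_date=date.fromisoformat(str(row["d1_date"])),
                sex=str(row["sex"]),
                age_band_at_d1=str(row["age_band_at_d1"]),
                parental_education=str(row["parental_education"]),
                entry_year=int(row["entry_year"]),
            )
        )
    return out
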