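"""Diagnostic-shift prevalence, stability shares and top subsequent categories.

A diagnostic shift is the occurrence, anywhere in a person's sequence, of a
diagnostic category different from the entry category.  Re-receiving the
entry diagnosis is not a shift, and the absorbing states (death, emigration)
never count as shifts; by default a person who dies without shifting counts
as diagnostically stable (set ``exclude_absorbed=True`` to drop persons with
truncated, shift-free follow-up from the denominator instead).

Because the annual windows keep only each period's last diagnosis, a shift
reversed within a single window is invisible at sequence level;
:func:`record_level_shift_summary` therefore also computes prevalence
directly from the raw records, and the two are reported side by side.
"""

from __future__ import annotations

import pandas as pd

from .records import CohortIndex
from .sequences import SequenceSet, StateSequence
from .taxonomy import ABSORBING_STATES, UNMAPPED, CategoryTaxonomy


def has_shift(seq: StateSequence) -> bool:
    """True iff any period's state is a diagnostic category other than the
    entry category."""
    return any(
        s != seq.d1_category and s not in ABSORBING_STATES for s in seq.states
    )


def _is_absorbed(seq: StateSequence) -> bool:
    return any(s in ABSORBING_STATES for s in seq.states)


def shift_summary(
    sets: list[SequenceSet], exclude_absorbed: bool = False
) -> pd.DataFrame:
    """Per-stratum shift prevalence and its complement, the stability share."""
    rows = []
    for sset in sets:
        seqs = sset.sequences
        if exclude_absorbed:
            seqs = [q for q in seqs if has_shift(q) or not _is_absorbed(q)]
        n = len(seqs)
        n_shift = sum(has_shift(q) for q in seqs)
        pct = 100.0 * n_shift / n if n else float("nan")
        rows.append(
            {
                "stratum": "|".join(sset.label),
                "n": n,
                "n_with_shift": n_shift,
                "pct_with_shift": pct,
                "stability_pct": 100.0 - pct,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["stratum", "n", "n_with_shift", "pct_with_shift", "stability_pct"],
    )


def shift_summary_by_sex(sequences: list[StateSequence]) -> pd.DataFrame:
    """Overall per-sex rollup of sequence-level shift prevalence."""
    sets = [
        SequenceSet(label=(sex,), sequences=[q for q in sequences if q.sex == sex])
        for sex in ("F", "M")
    ]
    return shift_summary([s for s in sets if s.sequences])


def record_level_shift_summary(
    cohort: CohortIndex, taxonomy: CategoryTaxonomy | None = None
) -> pd.DataFrame:
    """Per-sex shift prevalence computed from raw records.

    A person shifts if any diagnosis after the entry record maps to a
    different category; this sees shifts that reverse within one annual
    window and can therefore exceed the sequence-level figure.
    """
    taxonomy = taxonomy or CategoryTaxonomy.default()
    rows: dict[str, list[int]] = {"F": [], "M": []}
    for pid in cohort.person_ids:
        d1 = cohort.d1[pid]
        d1_cat = taxonomy.map_code(d1.icd10)
        shifted = 0
        for rec in cohort.events[pid]:
            if rec.event_type != "DIAGNOSIS" or rec.event_date < d1.event_date:
                continue
            cat = taxonomy.map_code(rec.icd10)
            if cat not in (d1_cat, UNMAPPED):
                shifted = 1
                break
        rows[d1.sex].append(shifted)
    out = []
    for sex, flags in rows.items():
        if not flags:
            continue
        n, n_shift = len(flags), sum(flags)
        out.append(
            {
                "stratum": sex,
                "n": n,
                "n_with_shift": n_shift,
                "pct_with_shift": 100.0 * n_shift / n,
                "stability_pct": 100.0 * (n - n_shift) / n,
            }
        )
    return pd.DataFrame(
        out,
        columns=["stratum", "n", "n_with_shift", "pct_with_shift", "stability_pct"],
    )


def top_subsequent_categories(
    sset: SequenceSet, k: int = 5, min_count: int = 5
) -> pd.DataFrame:
    """Most common subsequent categories in a stratum.

    For each diagnostic category other than the stratum's entry category,
    the percentage of persons whose sequence ever visits it (each person
    counted once per category).  Top-``k`` by percentage, ties broken
    alphabetically; categories visited by fewer than ``min_count`` persons
    are suppressed and reported only as an aggregate residual in the frame's
    ``attrs``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(sset.sequences)
    visits: dict[str, int] = {}
    for seq in sset.sequences:
        seen = {
            s
            for s in seq.states
            if s != seq.d1_category and s not in ABSORBING_STATES
        }
        for s in seen:
            visits[s] = visits.get(s, 0) + 1
    ranked = sorted(visits.items(), key=lambda kv: (-kv[1], kv[0]))
    shown = [(c, v) for c, v in ranked if v >= min_count][:k]
    hidden = [(c, v) for c, v in ranked if v < min_count]
    df = pd.DataFrame(
        [
            {"sd_category": c, "n_persons": v, "pct": 100.0 * v / n}
            for c, v in shown
        ],
        columns=["sd_category", "n_persons", "pct"],
    )
    df.attrs["stratum"] = "|".join(sset.label)
    df.attrs["n"] = n
    df.attrs["suppressed_categories"] = len(hidden)
    df.attrs["suppressed_persons"] = sum(v for _, v in hidden)
    return df
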