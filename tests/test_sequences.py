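"""Windowed state assignment, stratification and frequency suppression."""

from datetime import date, timedelta

import pytest

from diagtraj import (
    SequenceSet,
    StateSequence,
    build_sequence,
    build_sequence_set,
    build_sequences,
    identify_d1,
    sequence_frequency_table,
    sequences_to_frame,
)
from diagtraj.sequences import SequenceError, frame_to_sequences, period_starts

from conftest import make_record

D1_DATE = date(2002, 5, 1)


def person(records):
    idx = identify_d1(records)
    return idx.events["P1"], idx.d1["P1"]


def months_later(months, days=0):
    import pandas as pd

    return (pd.Timestamp(D1_DATE) + pd.DateOffset(months=months)).date() + timedelta(days=days)


def test_pure_projection_constant_sequence(taxonomy):
    recs, d1 = person([make_record(event=D1_DATE, icd10="F32.1")])
    seq = build_sequence(recs, d1, taxonomy)
    assert seq.states == ("SRD",) * 10
    assert seq.d1_category == "SRD"


def test_hand_traced_windowing_with_death(taxonomy):
    """Entry depression, personality disorder at month 30 (period 3), death
    at month 54 (period 5)."""
    recs, d1 = person(
        [
            make_record(event=D1_DATE, icd10="F32.1"),
            make_record(event=months_later(30), icd10="F60.3"),
            make_record(event=months_later(54), event_type="DEATH", icd10=""),
        ]
    )
    seq = build_sequence(recs, d1, taxonomy)
    assert seq.states == ("SRD", "SRD", "PD", "PD") + ("DEAD",) * 6


def test_last_diagnosis_in_window_wins(taxonomy):
    recs, d1 = person(
        [
            make_record(event=D1_DATE, icd10="F84.0"),
            make_record(event=months_later(38), icd10="F90.0"),
            make_record(event=months_later(44), icd10="F84.1"),
        ]
    )
    seq = build_sequence(recs, d1, taxonomy)
    assert seq.states[3] == "ASD"
    assert seq.states == ("ASD", "ASD", "ASD", "ASD") + ("ASD",) * 6


def test_death_overrides_same_window_diagnosis(taxonomy):
    recs, d1 = person(
        [
            make_record(event=D1_DATE, icd10="F32.1"),
            make_record(event=months_later(14), icd10="F60.3"),
            make_record(event=months_later(16), event_type="DEATH", icd10=""),
        ]
    )
    seq = build_sequence(recs, d1, taxonomy)
    assert seq.states == ("SRD",) + ("DEAD",) * 9


def test_emigration_absorbs(taxonomy):
    recs, d1 = person(
        [
            make_record(event=D1_DATE, icd10="F32.1"),
            make_record(event=months_later(25), event_type="EMIGRATION", icd10=""),
        ]
    )
    seq = build_sequence(recs, d1, taxonomy)
    assert seq.states == ("SRD", "SRD") + ("EMIGRATED",) * 8


def test_unmapped_codes_ignored_in_windowing(taxonomy):
    recs, d1 = person(
        [
            make_record(event=D1_DATE, icd10="F32.1"),
            make_record(event=months_later(18), icd10="F07.0"),
        ]
    )
    seq = build_sequence(recs, d1, taxonomy)
    assert seq.states == ("SRD",) * 10


def test_window_boundary_same_day_of_month(taxonomy):
    # a diagnosis exactly 12 months after entry opens period 2
    recs, d1 = person(
        [
            make_record(event=D1_DATE, icd10="F32.1"),
            make_record(event=months_later(12), icd10="F43.2"),
        ]
    )
    seq = build_sequence(recs, d1, taxonomy)
    assert seq.states == ("SRD",) + ("SAD",) * 9


def test_end_of_month_clamping():
    starts = period_starts(date(2004, 2, 29), 3)
    assert starts[1] == date(2005, 2, 28)


def test_no_records_is_error(taxonomy):
    with pytest.raises(SequenceError):
        build_sequence([], make_record(), taxonomy)


def test_d1_not_first_is_error(taxonomy):
    earlier = make_record(event=date(2000, 1, 1), icd10="F90.0")
    d1 = make_record(event=D1_DATE, icd10="F32.1")
    with pytest.raises(SequenceError, match="not the first"):
        build_sequence([earlier, d1], d1, taxonomy)


def test_absorbing_states_never_left(small_cohort, taxonomy):
    records, truth, cohort = small_cohort
    for seq in build_sequences(cohort, taxonomy):
        for k, s in enumerate(seq.states):
            if s in ("DEAD", "EMIGRATED"):
                assert all(later == s for later in seq.states[k:])
                break
        assert seq.states[0] not in ("DEAD", "EMIGRATED")
        assert len(seq.states) == 10


def test_rebuild_matches_latent_path(small_cohort, taxonomy):
    records, truth, cohort = small_cohort
    for seq in build_sequences(cohort, taxonomy):
        assert seq.states == truth.latent_paths[seq.person_id], seq.person_id


def test_row_order_independence(taxonomy):
    base = [
        make_record(event=D1_DATE, icd10="F32.1"),
        make_record(event=months_later(30), icd10="F60.3"),
        make_record(event=months_later(50), icd10="F43.2"),
    ]
    idx_a = identify_d1(base)
    idx_b = identify_d1(list(reversed(base)))
    tax_seq = lambda idx: build_sequence(idx.events["P1"], idx.d1["P1"], taxonomy)
    assert tax_seq(idx_a).states == tax_seq(idx_b).states


class TestStratification:
    def mk(self, pid, d1, sex, band="0-10", edu="SHORT", year=2000):
        return StateSequence(pid, d1, (d1,) * 10, date(year, 1, 1), sex, band,
                             edu, year)

    def test_cross_product_of_populated_cells(self):
        seqs = [
            self.mk("a", "SRD", "F"), self.mk("b", "SRD", "M"),
            self.mk("c", "ADHD", "F"), self.mk("d", "ADHD", "M"),
        ]
        sets = build_sequence_set(seqs, ("d1", "sex"))
        assert len(sets) == 4
        assert all(len(s) == 1 for s in sets)

    def test_empty_strata_omitted(self):
        seqs = [self.mk("a", "SRD", "F")]
        sets = build_sequence_set(seqs, ("d1", "sex"))
        assert [s.label for s in sets] == [("SRD", "F")]

    def test_unknown_stratifier_rejected(self):
        with pytest.raises(ValueError, match="unknown stratifier"):
            build_sequence_set([], ("d1", "postcode"))

    def test_entry_year_bands(self):
        seqs = [self.mk("a", "SRD", "F", year=1997),
                self.mk("b", "SRD", "F", year=2009)]
        sets = build_sequence_set(
            seqs, ("entry_year_band",), entry_year_bands=[(1996, 2003), (2004, 2011)]
        )
        assert [s.label for s in sets] == [("1996-2003",), ("2004-2011",)]


class TestFrequencyTable:
    def mk_set(self, counts):
        seqs = []
        i = 0
        variants = [("SRD",) * 10, ("SRD",) * 5 + ("PD",) * 5,
                    ("SRD",) * 9 + ("SAD",), ("SRD", "PD") * 5]
        for count, states in zip(counts, variants):
            for _ in range(count):
                seqs.append(
                    StateSequence(f"p{i}", "SRD", states, date(2000, 1, 1),
                                  "F", "0-10", "SHORT", 2000)
                )
                i += 1
        return SequenceSet(label=("SRD", "F"), sequences=seqs)

    def test_no_suppression_above_threshold(self):
        table = sequence_frequency_table(self.mk_set([7]), min_count=5)
        assert list(table.displayed["count"]) == [7]
        assert table.suppressed_count == 0

    def test_full_suppression_below_threshold(self):
        table = sequence_frequency_table(self.mk_set([4]), min_count=5)
        assert table.displayed.empty
        assert table.suppressed_count == 4
        assert table.suppressed_distinct == 1

    def test_mixed_counts_residual(self):
        table = sequence_frequency_table(self.mk_set([6, 5, 4, 3]), min_count=5)
        assert list(table.displayed["count"]) == [6, 5]
        assert table.suppressed_count == 7
        assert table.total == 18

    def test_min_count_must_be_positive(self):
        with pytest.raises(ValueError):
            sequence_frequency_table(self.mk_set([3]), min_count=0)


def test_frame_round_trip(small_cohort, taxonomy):
    _, _, cohort = small_cohort
    seqs = build_sequences(cohort, taxonomy)[:50]
    frame = sequences_to_frame(seqs, wide=True)
    assert frame_to_sequences(frame) == seqs
    long = sequences_to_frame(seqs, wide=False)
    assert len(long) == 10 * len(seqs)
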