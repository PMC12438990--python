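"""Diagnostic-shift prevalence and the most common subsequent categories.

A shift is any period spent in a diagnostic category other than the entry
category (death/emigration never count).  Sequence-level and record-level
prevalences are shown side by side: the latter also sees shifts that
reverse within one annual window.
"""

from diagtraj import (
    SyntheticCohortConfig,
    build_sequence_set,
    build_sequences,
    generate_cohort,
    identify_d1,
    record_level_shift_summary,
    shift_summary_by_sex,
    top_subsequent_categories,
)

records, _ = generate_cohort(SyntheticCohortConfig.default(n_persons=4000, seed=4))
cohort = identify_d1(records)
sequences = build_sequences(cohort)

print("sequence-level shift prevalence by sex:")
print(shift_summary_by_sex(sequences).to_string(index=False))
print("\nrecord-level shift prevalence by sex:")
print(record_level_shift_summary(cohort).to_string(index=False))

sets = build_sequence_set(sequences, ("d1", "sex"))
sset = max(sets, key=len)
table = top_subsequent_categories(sset, k=5, min_count=5)
print(f"\nmost common subsequent categories for stratum {sset.label} "
      f"(n={table.attrs['n']}):")
print(table.to_string(index=False))
# pct is the share of the stratum's persons whose trajectory ever visits
# that category; cells under five persons are suppressed.
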