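"""Build 10-period annual state sequences from dated event records.

Each person's follow-up is cut into ten 12-month windows from the entry
date; a window's state is the last diagnosis inside it, carried forward
through diagnosis-free windows, with death/emigration absorbing.
"""

from diagtraj import (
    SyntheticCohortConfig,
    build_sequences,
    generate_cohort,
    identify_d1,
    sequence_frequency_table,
    build_sequence_set,
)

records, truth = generate_cohort(SyntheticCohortConfig.default(n_persons=1500, seed=2))
cohort = identify_d1(records)
sequences = build_sequences(cohort)

print(f"{len(sequences)} sequences, all length {len(sequences[0].states)}")
sets = build_sequence_set(sequences, ("d1", "sex"))
print(f"{len(sets)} strata (entry category x sex)")

# frequency table with small-cell suppression for one stratum
sset = max(sets, key=len)
table = sequence_frequency_table(sset, min_count=5)
print(f"\nstratum {sset.label} (n={len(sset)}): "
      f"{len(table.displayed)} displayed sequences, "
      f"{table.suppressed_count} persons in suppressed sequences")
print(table.displayed.head(5).to_string(index=False))
# Rows are distinct 10-year trajectories with their person counts; any
# trajectory shared by fewer than five persons is pooled into the residual.
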