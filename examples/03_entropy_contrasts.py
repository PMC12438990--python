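"""Normalized sequence entropy and group contrasts.

Entropy 0 means a perfectly stable trajectory; higher values mean time
spread over more diagnostic states.  The contrast compares mean entropy
between entry-age bands (0-10 vs 11-17) with a Welch t-test.
"""

from diagtraj import (
    SyntheticCohortConfig,
    build_sequence_set,
    build_sequences,
    compare_entropy_groups,
    generate_cohort,
    identify_d1,
    normalized_entropy,
    summarize_entropy,
)

records, _ = generate_cohort(SyntheticCohortConfig.default(n_persons=3000, seed=3))
sequences = build_sequences(identify_d1(records))

sets = build_sequence_set(sequences, ("d1", "sex"))
summary = summarize_entropy(sets, alphabet_size=21, min_count=5)
print("mean entropy by entry category and sex (first rows):")
print(summary.head(6).to_string(index=False))

groups = {}
for q in sequences:
    groups.setdefault(q.age_band_at_d1, []).append(normalized_entropy(q, 21))
res = compare_entropy_groups(groups)
print(f"\nage-band contrast ({res.test}): statistic={res.statistic:.3f}, "
      f"p={res.p_value:.3g}")
print(res.groups.to_string(index=False))
# A small p-value would indicate the age bands differ in mean trajectory
# diversity; under the default generator the bands share one transition
# matrix, so differences reflect mixture composition only.
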