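# diagtraj

Sequence analysis of psychiatric diagnostic trajectories in childhood and
adolescence.

When a child or adolescent receives a first psychiatric hospital diagnosis
(before age 18.0), the diagnosis often does not stay put: over the following
years it may be revised, replaced, or joined by new conditions. `diagtraj`
turns dated ICD-10 registry-style event records into analyzable 10-year
trajectories and quantifies their stability. It is written for
epidemiologists and clinical researchers working with registry extracts —
and, because such registers are access-restricted, it ships a calibrated
synthetic cohort generator so every analysis step can be exercised, tested
and benchmarked without data access.

## What it computes

**Taxonomy.** ICD-10 F-chapter codes are grouped into 19 analysis
categories (SUD F10–F19, SZ F20–F29, BD F30–F31, SRD F32+F33, OMD F34–F39,
AND F40+F41+F93, OCD F42, SAD F43, SOM F44–F48, ED F50, PD F60–F69,
ID F70–F79, ODD F80–F83, ASD F84 minus F84.2–F84.4, ADHD F90+F98.8, CD F91,
AD F94 minus F94.0, TD F95, and a closed OTHER residual), with subcode-level
exceptions taking precedence over block rules. Codes claimed by no rule map
to `UNMAPPED` and are reported, not guessed.

**State sequences.** Follow-up after the entry diagnosis D1 is divided into
ten 12-month periods. Each period's state is the category of the *last*
diagnosis dated inside it, carried forward through diagnosis-free periods;
death and emigration are absorbing states. Sequences therefore live on a
21-letter alphabet (19 categories + DEAD + EMIGRATED).

**Normalized entropy.** For a sequence with occupancy fractions
$p_i$ over the alphabet of size $a$,

$$h = \frac{-\sum_i p_i \ln p_i}{\ln a} \in [0, 1],$$

0 for a perfectly stable trajectory and 1 when the sequence spends equal
time in every alphabet state (attainable when the length is a multiple of
$a$). Group contrasts use Welch's t-test (2 groups) or one-way ANOVA (3+).

**Diagnostic shifts.** A shift is any period spent in a diagnostic category
other than D1 (absorbing states never count; re-receiving D1 is not a
shift). Per-stratum prevalence, stability shares and the most common
subsequent categories are tabulated with small-cell suppression: no
displayed sequence or cell is backed by fewer than five persons.

**Hazard contrasts.** For each D1 category versus all other D1s, the time
to a first subsequent diagnosis in each 1-cipher chapter (F0–F9) is modeled
with a Cox proportional-hazards fit (Efron ties), censoring at death,
emigration or 10 years (3,652 days); the contrast grid applies a Bonferroni
plan (α/n tests) rendered as widened confidence intervals.

## Worked example

```python
from diagtraj import (SyntheticCohortConfig, generate_cohort, identify_d1,
                      build_sequences, shift_summary_by_sex)

records, truth = generate_cohort(SyntheticCohortConfig.default(n_persons=4000, seed=4))
sequences = build_sequences(identify_d1(records))
print(shift_summary_by_sex(sequences))
```

prints

```
stratum    n  n_with_shift  pct_with_shift  stability_pct
      F 1710           783       45.789474      54.210526
      M 2290           840       36.681223      63.318777
```

i.e. under the default calibration 45.8% of girls and 36.7% of boys in this
draw experience at least one diagnostic shift within 10 years — close to
the generator's configured expectations of 46.7% and 37.6% (the small gap
is sampling noise plus truncation by death/emigration). The `examples/`
directory has one short script per capability: cohort simulation, sequence
building and frequency tables, entropy summaries and contrasts, shift
tables, hazard contrasts, and the full pipeline with its reproducibility
manifest.

A thin CLI wraps the same functions:

```bash
diagtraj simulate --n 2000 --seed 1 --out records.csv
diagtraj build-sequences --records records.csv --out seqs.csv
diagtraj entropy --seqs seqs.csv --by d1,sex
diagtraj run-all --out outdir --seed 7
```

## Scope notes

- Only *main* diagnoses belong in the event file; the format has no
  main/secondary flag, so callers must pre-filter secondary diagnoses.
- The synthetic generator's defaults are a structural calibration, not
  estimates of any real cohort; see `docs/methods.md`.
- Death is a competing risk for subsequent diagnoses but is handled by
  censoring, not a competing-risks model (documented limitation).
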