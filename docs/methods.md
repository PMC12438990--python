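# Methods

## The analysis model

`diagtraj` analyses diagnostic trajectories after a first psychiatric
hospital diagnosis (D1) received before age 18.0 years. The unit of
analysis is a person's **annual state sequence**: follow-up is divided into
ten consecutive 12-month periods starting at the D1 date ("12 months"
meaning the same day-of-month one year later, clamped at month ends), and
each period is assigned one state from a 21-letter alphabet — the 19
diagnostic categories plus DEAD and EMIGRATED.

Assignment rules, in order:

1. the state of a period is the category of the **last** diagnosis dated
   inside it (the most recent diagnosis is taken to be the most clinically
   valid);
2. periods without diagnoses carry the prevailing state forward
   (last-observation-carried-forward projection);
3. a death or emigration event makes that period and all later periods
   absorbing; death wins same-period ties with emigration or diagnoses;
4. the entry period always records the diagnostic state — an absorbing
   event inside the entry window takes effect from period 2. This keeps
   the invariant that every sequence starts in a diagnostic state (the
   person was alive and diagnosed at entry) while preserving rule 3
   everywhere else;
5. within-category code changes (F32 → F33, both SRD) are not state
   changes: sequences are defined over the 19 categories;
6. codes mapped by no taxonomy rule are ignored in windowing and logged.

Ages are computed as exact day differences divided by 365.25; eligibility
requires age at D1 strictly below 18.0 years. Same-day multiple diagnoses
are resolved by file order, keeping the last record that day — the same
convention as rule 1.

The period length (12 months) and the number of periods (10) are
parameters of `build_sequence`, so 3- or 6-month sensitivity analyses are
possible; 12 months over 10 years is the primary design.

## Taxonomy

The 19 categories are encoded in an editable delimited file
(`data/taxonomy_default.csv`) as include/exclude prefix rules; matching is
longest-prefix on the dot-stripped code, so subcode exceptions
(F84.2–F84.4 → OTHER, F94.0 excluded from AD) always beat their parent
blocks. The OTHER group is a *closed* list headed by F99; the whole F99
block is treated as OTHER. Codes claimed by no rule — the organic block
F00–F09, F85–F87, F96–F97, bare F98, F98.7 and F94.0 — map to `UNMAPPED`:
they are excluded from sequences but counted in the ingest report, which
avoids silently inventing taxonomy. An exhaustive sweep over all
two-cipher codes plus listed subcodes verifies the rules partition the
code space and realize exactly 19 categories.

## Normalized entropy

For occupancy fractions $p_i$ of a sequence over an alphabet of size $a$:
$h = -\sum_i p_i \ln p_i \,/\, \ln a$. Properties relied on and tested:
$h=0$ iff the sequence is constant; $h=1$ iff occupancy is uniform over
the full alphabet (attainable when the length is a multiple of $a$); $h$
is permutation-invariant (it measures diversity, not ordering) and
strictly decreasing in $a$ for fixed non-constant occupancy.

Numerical choices: natural logarithms (normalization makes the base
irrelevant); summation via `math.fsum`; because floating-point evaluation
can land a hair outside $[0,1]$ (e.g. $(\ln 10 - \ln 2)/\ln 5$ exceeds 1
by one ulp), values within $10^{-12}$ of a bound are snapped to it and the
result is clamped to $[0,1]$.

The default alphabet size is 21 (19 categories + DEAD + EMIGRATED), on the
view that the absorbing states are part of "all the states that can
occur"; `alphabet_size=19` restricts the alphabet to diagnostic states.
Either convention only rescales $h$ by a constant factor
($\ln 21/\ln 19 \approx 1.03$), so orderings and contrasts are unaffected.

Group contrasts: Welch's unequal-variance t-test for two groups (chosen
over the pooled test as the robust default), one-way ANOVA for three or
more. Groups with fewer than two observations produce an explicit
insufficient-data result. Calendar-period contrasts are implemented as
entry-year banding.

## Shifts and suppression

A diagnostic shift is any period in a diagnostic category other than the
D1 category; DEAD/EMIGRATED never count, and by default a person who dies
without shifting counts as stable (an `exclude_absorbed` flag drops
absorbed shift-free persons from the denominator instead). Because the
windows keep only each period's last diagnosis, a shift reversed within
one window is invisible at sequence level; prevalence is therefore also
computed directly from records, and both figures are reported.

Small-cell suppression follows the under-5 rule throughout: distinct
sequences, top-subsequent-category cells and summary strata below five
persons are pooled into aggregate residuals, and the plotting layer
enforces the rule before anything reaches the canvas (each plot emits a
sidecar JSON of exactly what was drawn, making the contract testable
without image diffing).

## Hazard contrasts

For a D1 category versus all other D1s, time runs from the D1 date to the
first diagnosis whose 1-cipher chapter matches the outcome and whose
2-cipher block differs from the D1's block — repeating the entry diagnosis
is never a subsequent diagnosis, but a different block within the entry
chapter is (an `exclude_same_chapter_d1` flag provides the stricter
sensitivity analysis). Censoring occurs at death, emigration or 3,652 days
(10 years). Events on the entry date itself receive 0.5 days of exposure
to keep times positive. The model is a proportional-hazards fit with a
single binary exposure term, maximized by partial likelihood with Efron
tie handling (lifelines); Wald intervals are computed on the log-hazard
scale. Analyses run per sex without covariate adjustment.

Multiplicity: `bonferroni_plan(n)` sets the per-test level to $0.05/n$ and
the CI level to its complement. For 180 tests this is 0.0278%
(≈ 99.97% CIs, conventionally rendered as 99.9%); note that quoting
"0.026%" for 5%/180 is a rounding inconsistency — the package always
computes from first principles, and the test count is derived from the
actual contrast grid at run time (contrasts with zero events are skipped
and reported).

Death is a competing risk for receiving further diagnoses; it is handled
by censoring, not by a Fine–Gray model — a documented limitation.

## The synthetic cohort generator

The generator defines the study conditions for all tests. Per person it
draws sex (female share 0.4226), a 3-level parental-education covariate, a
D1 category from the per-sex mixture, an onset age from a truncated normal
(sd 2.2 y, support [0.5, 17.95) y), and an entry date uniform over
1996–2011. Trajectories then follow a discrete-time Markov chain over the
19 categories, one draw per 12-month period, preceded each period by
Bernoulli death (5·10⁻⁴) and emigration (2·10⁻³) draws; death is drawn
first and wins ties. A diagnosis record is emitted only on category
change, dated uniformly strictly inside the period, with a code drawn
uniformly from the category's code set. The latent 10-state path is
returned as ground truth; when change dates fall strictly inside periods
(as generated), rebuilding sequences from the emitted records reproduces
the latent path exactly, which is tested.

Calibration: the anchored structure is the per-sex leading-category shares
(girls: SAD 23.0%, ED 11.9%, ADHD 9.7%; boys: ADHD 24.7%, ASD 19.3%,
ODD 6.2%; BD smallest in both sexes at ≈0.21%/0.14%), the onset-age
ordering (AD and ASD earliest at 8.1–8.9 y; SUD and BD latest at
15.6–16.2 y; boys earlier than girls except SUD, with BD and TD tied), and
stay probabilities chosen so the expected 10-year shift prevalence is
46.7% (girls) and 37.6% (boys): stay = (1 − p)^(1/9), i.e. 0.9325 and
0.9494, with uniform off-diagonal mass. All remaining mixture shares and
mean ages are plausible fill-ins chosen once for realism. None of these
defaults are estimates of any real cohort's transition dynamics — real
registries exhibit destination-specific transition structure, calendar
drift, sibling clustering and service-use trends that this generator does
not model. Passing tests therefore demonstrate correctness of the
*machinery* (windowing, entropy, suppression, survival construction and
fitting) under known dynamics, not epidemiological conclusions about real
populations.

## Problem sizes and verification design

Test and verification sizes were chosen to give tight Monte-Carlo bounds
at desk scale: calibration recovery of mixture shares at n = 50,000
(±1% absolute), shift-prevalence recovery against the closed form
1 − 0.9⁹ at n = 20,000 (3 binomial SEs), windowing equivalence against an
independent day-resolution oracle on 1,000 persons with transitions plus
absorbing events, Cox recovery of a true HR = 2 over 50 replicates of
5,000/arm exponential survival (mean within 3%, 99.9% CI coverage allowed
at most one miss), and t-test calibration over 1,000 two-group resamples
of a 6,000-person entropy pool (rejection rate within 0.03–0.07 at
α = 0.05). Determinism is verified byte-for-byte on full pipeline reruns;
the run manifest records versions, seed and a configuration hash and
deliberately contains no timestamps.

## Known limitations

- Sequences carry only main diagnoses; concurrent secondary diagnoses are
  out of scope and must be pre-filtered by the caller.
- The entropy measure ignores ordering and transition counts; turbulence
  or complexity indices and optimal-matching distances are not provided.
- Sub-annual dynamics are invisible by design; within-window reversals
  are surfaced only through the record-level shift summary.
- Placement of F94.0 and F98.7 D1s is undefined in the 19-category scheme;
  such codes are flagged as unmapped rather than assigned.
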