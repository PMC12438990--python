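"""Time-to-subsequent-diagnosis hazard contrasts.

For one entry category versus all others, the hazard of a first diagnosis
in a given 1-cipher chapter is contrasted with a proportional-hazards
model; with many contrasts the grid applies a Bonferroni plan, widening
the confidence intervals accordingly.
"""

from diagtraj import (
    CategoryTaxonomy,
    SyntheticCohortConfig,
    bonferroni_plan,
    fit_hazard_contrast,
    generate_cohort,
    identify_d1,
    make_time_to_event,
)

records, _ = generate_cohort(SyntheticCohortConfig.default(n_persons=6000, seed=5))
cohort = identify_d1(records)
taxonomy = CategoryTaxonomy.default()

plan = bonferroni_plan(180)
print(f"Bonferroni plan for 180 tests: per-test alpha "
      f"{plan.alpha_adjusted:.4%}, CI level {plan.ci_level:.4%}")

rows = make_time_to_event(cohort, taxonomy, "ADHD", "F8", sex="M")
res = fit_hazard_contrast(rows, ci_level=plan.ci_level,
                          d1_category="ADHD", outcome_chapter="F8")
print(f"\nboys, entry ADHD vs rest, outcome chapter F8:")
print(f"  n_exposed={res.n_exposed}, n_unexposed={res.n_unexposed}, "
      f"events={res.n_events}")
if res.flag is None:
    print(f"  HR={res.hr:.2f} ({res.ci_low:.2f}-{res.ci_high:.2f})")
else:
    print(f"  degenerate contrast: {res.flag}")
# HR > 1 would mean boys entering with ADHD move into chapter F8
# (developmental disorders) faster than boys with any other entry
# diagnosis; under the default generator's uniform off-diagonal dynamics
# the true contrast is near 1.
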