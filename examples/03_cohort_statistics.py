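"""Day-vs-night cohort statistics at the study's design scale.

Simulates a cohort of 9 animals per group with ~7 cells each, night
volumes scaled to 75% at constant dry mass, then runs both analyses —
exact Mann-Whitney on pooled cells and the mixed-model ANOVA with a
random animal intercept — plus the volume-vs-mass regression whose
reciprocal slope is the effective cell density.
"""

import glimetry as g

cohort = g.simulate_cohort(seed=1)
print(f"{len(cohort)} cells from {cohort.animal_id.nunique()} animals\n")

comparisons = g.summarize(cohort)
fits = [g.fit_mass_volume(cohort, grp) for grp in ("day", "night")]
print(g.report_markdown(comparisons, fits))
# Expect: volume ~25% lower at night and clearly significant under the mixed
# model.  Dry mass is generated with no group effect; its observed change is a
# few percent and usually non-significant, though with 9 animals per group a
# minority of cohorts (like this seed) reach nominal significance by chance —
# exactly the type-I behaviour the acceptance checks quantify.  Night density
# exceeds day density because the same dry mass sits in a smaller volume.
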