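"""Simulate a cohort of smoking histories and look at its structure.

The generator emulates two prospective cohorts (women enrolled 1976 aged
30-55, men enrolled 1986 aged 40-75) with lifetime smoking episodes, and
draws COPD diagnoses from the built-in hazard model, competing other-cause
death from a status-stratified life table, and loss to follow-up.
"""

import pandas as pd

from copdrisk import CohortSpec, exclude_prevalent, generate_cohort

spec = CohortSpec(n_subjects=10_000, seed=1)
cohort = generate_cohort(spec)
cohort = exclude_prevalent(cohort, cutoff_year=1998)
print(f"{len(cohort)} subjects after excluding "
      f"{cohort.attrs['n_excluded_prevalent']} prevalent (pre-1998) cases\n")

print("outcomes (fractions):")
print(cohort["outcome"].value_counts(normalize=True).round(3).to_string(), "\n")

cases = cohort[cohort["outcome"] == "copd"]
never = cases["episodes"].apply(len) == 0
print(f"diagnosed during follow-up: {100 * len(cases) / len(cohort):.1f}% of subjects")
print(f"share of cases in never smokers: {100 * never.mean():.0f}%")
print(f"median age at diagnosis: {cases['outcome_age'].median():.0f} years")
# Roughly 3-4% of subjects are diagnosed in the 1998-2008 window, about a
# quarter of them never smokers, with diagnoses concentrated around age 70 --
# the structure the downstream modelling stages expect.
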