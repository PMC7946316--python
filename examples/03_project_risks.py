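"""Project absolute 6-year COPD risks for smoking scenarios.

Combines the fitted relative-hazard model with the never-smoker log-normal
baseline into age-specific incidence and N-year risks, optionally adjusted
for the competing risk of death from other causes.
"""

from copdrisk import (
    CohortSpec, PredictionBundle, Scenario, default_true_model,
    exclude_prevalent, expand_cohort, fit, fit_baseline, generate_cohort,
    nyear_risk, relative_risk,
)

spec = CohortSpec(n_subjects=20_000, seed=2)
model = default_true_model()
cohort = exclude_prevalent(generate_cohort(spec, model), 1998)
pp = expand_cohort(cohort, spec.followup_window)
hazard_fit = fit(pp)
baseline = fit_baseline(pp, female_log_hr=float(hazard_fit.beta["sex_female"]))
bundle = PredictionBundle(fit=hazard_fit, baseline=baseline)

print("age-specific incidence per 100,000 person-years:")
for age in (55, 65, 75):
    nev = bundle.scenario_hazard(Scenario.never_smoker(1, age), [age])[0]
    cur = bundle.scenario_hazard(Scenario.current_smoker(1, age, cpd=20.0), [age])[0]
    print(f"  age {age}: female never {1e5 * nev:7.0f}   female 20-CPD smoker {1e5 * cur:7.0f}")

cur60 = Scenario.current_smoker(1, 60.0, cpd=40.0)
nev60 = Scenario.never_smoker(1, 60.0)
print(f"\nrelative risk, 60-year-old female 40-CPD smoker vs never smoker: "
      f"{relative_risk(bundle, cur60, nev60, 60.0):.1f}")

# a 70-year-old female with 20 pack-years over 30 years (~13 CPD)
scen = Scenario(sex_female=1, episodes=((40.0, None, 20 * 20 / 30),), age=70.0, horizon=6)
unadj = nyear_risk(bundle, scen, n_boot=100, seed=2)
adj = nyear_risk(bundle, scen, life_table=model.life_table, n_boot=100, seed=2)
print(f"\n6-year risk of diagnosis, 70-year-old female, 20 pack-years over 30 years:")
print(f"  unadjusted          {100 * unadj.risk:.2f}%  (95% CI {100 * unadj.ci[0]:.2f}-{100 * unadj.ci[1]:.2f})")
print(f"  mortality-adjusted  {100 * adj.risk:.2f}%  (95% CI {100 * adj.ci[0]:.2f}-{100 * adj.ci[1]:.2f})")
# The adjusted risk is lower because some subjects die of other causes
# before a diagnosis could occur.
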