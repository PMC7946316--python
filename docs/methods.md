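# Methods

This note records the model, the conventions the implementation commits
to where the underlying methodology leaves choices open, the synthetic
cohort the package uses in place of restricted cohort data, and the
numerical decisions a maintainer would want to know.

## Hazard model

Diagnosed COPD incidence is modelled as a proportional-hazards process on
the **age** timescale,

    h(t) = λ₀(t) · exp(β(t)·X(t)),

with time-varying covariates X(t) = (pack-years, duration,
years-since-quit, sex, sex×duration) and a time-dependent pack-years
coefficient β_py(t) = β_py + γ₁B₁(t) + γ₂B₂(t), where {B₁, B₂} is a
natural cubic spline basis of age with 2 degrees of freedom.  Units are
per pack-year, per year of smoking, per year since quitting; covariates
are never standardized, so exp(β) values read directly as hazard ratios
per natural unit.

**Annual person-period coding.**  Histories are expanded to half-open
annual intervals [a, a+1), a integer, from birth to the end of follow-up.
Events are attributed to the interval whose endpoint is the (year-end)
outcome age.  Covariates are *left-continuous*: the values driving the
hazard over [a, a+1) are the exposures accumulated strictly before a, so
same-interval exposure can never post-date the event it explains.  Rows
before study entry or before the observation window (default calendar
years 1998–2008) are emitted but flagged not-at-risk; the fitter uses
only at-risk rows, which implements left truncation (delayed entry)
through risk-set membership.  Within-interval exposure is evaluated at
the interval start; interval-midpoint evaluation was considered and left
as a sensitivity option for future work.

**Exposure coding.**  Intensity is reported in six categories (0–4, 5–14,
15–24, 25–34, 35–44, 45+ CPD) mapped to the midpoints 2, 9.5, 19.5, 29.5,
39.5 and 50 CPD; pack-years accumulate as CPD/20 per year smoked.
Duration, pack-years and years-since-quit are coded zero for never
smokers.  A subject who has not yet initiated at age a counts as a never
smoker *at that age*.

**Estimation.**  Maximum partial likelihood in counting-process form,
Newton–Raphson with step-halving; convergence requires relative
log-likelihood change < 1e-9 and maximum score component < 1e-6.  Annual
coding produces heavy ties at integer event ages; ties are handled by
Efron's method by default (Breslow available).  Events in the same
integer age are tied as-is, never jittered.  Risk-set sums are
accumulated with difference arrays over the sorted distinct event ages,
so each iteration is O(rows); a fit on ~10⁶ person-years with 7
covariates takes a few seconds.  Rank-deficient designs are rejected up
front with the offending columns named.  The step-halving acceptance
tolerance is *relative* (1e-10·|loglik|): with |loglik| ~ 10⁴ an absolute
epsilon sits below float resolution and roundoff would masquerade as
non-monotonicity.

**Spline knots.**  Boundary knots at the min/max of the at-risk event
ages in the training data, one interior knot at their median (df = 2).
The basis is the textbook truncated-power construction rescaled to O(1)
values, and is serialized inside the fit artifact; predictions always
reuse the stored knots, never recompute them.  No centering or
orthogonalization — the raw coefficients stay interpretable and the basis
reconstructs exactly from the artifact.

## Never-smoker baseline hazard

λ₀(t) — the hazard of the all-zero covariate profile, the male never
smoker — is estimated by fitting a log-normal distribution to
never-smoker age at diagnosis ("never smoker" = status `never` in every
at-risk row).  Most of the fitted distribution's mass typically lies far
beyond human ages; it is a hazard-shape device over the observed range
(~55–90), not a claim that everyone is eventually diagnosed.

Two deliberate departures from the naive censored MLE, both exposed as
options:

1. **Interval-censored likelihood (default for person-period data).**
   Outcomes are recorded at year ends, so "event at age t" means "event
   in (t−1, t]".  Fitting the exact-time density at the rounded-up age
   systematically steepens the fitted hazard (verified by simulation: at
   ~13,000 events the exact-time fit landed >10 SE from the generating
   parameters; the interval likelihood, using S(t−1)−S(t), recovers them).
   The exact-time likelihood remains available for genuinely continuous
   times and is what the closed-form uncensored tests use.
2. **Sex offset.**  The baseline profile is male, but two thirds of
   never-smoker events are female, carrying the sex hazard ratio.  The
   MLE therefore accepts a fixed per-subject log-HR offset c_i (the
   fitted sex coefficient for women): survival enters as S₀(t)^{c_i}.
   Pooling both sexes without the offset inflates λ₀ by ~40% under the
   default generator; the no-offset behaviour is retained as the naive
   variant.

Left truncation: the default likelihood conditions on being event-free at
the first at-risk age (−ln S(entry) terms).  A `truncation_mode="none"`
(`--paper-mode` on the CLI) fits without the correction; under heavy
delayed entry it is biased — the location parameter inflates because
survivors-to-entry are treated as the whole population — and the test
suite demonstrates both the direction of that bias and its removal by the
truncated likelihood.  The relative-hazard model and the parametric
baseline are estimated sequentially, not jointly; the semiparametric fit
and the parametric baseline are therefore not a single coherent
likelihood.  This mirrors the two-stage practice the design follows, and
the inconsistency is accepted rather than resolved.

## Absolute risk

For a smoking scenario (episodes with raw CPD values, evaluation age a,
horizon N, default 6 years), the engine evaluates h(t) on the annual grid
t = a, …, a+N−1 with hazards constant within years:

- unadjusted: 1 − exp(−Σ h(t));
- adjusted for competing mortality m(t) = −ln(1 − q(t, status(t))) from a
  life table stratified by smoking status:
  Σ_t exp(−Σ_{u<t}(h+m)) · h/(h+m) · (1 − e^{−(h+m)}),
  the exact cause-specific risk for piecewise-constant hazards.  It
  reduces to the unadjusted form when m ≡ 0 and to
  h/(h+m)·(1−e^{−N(h+m)}) for constant hazards — both covered by tests at
  1e-10.  A 0.5-year grid refinement is available; for annual hazards
  ≤ 0.05 it moves 6-year risks by < 2%.

The life-table status follows the scenario (a quitter transitions
current→former mid-horizon).  Scenario risk intervals come from a
parametric bootstrap: 100 draws of the coefficient vector from
N(β̂, V̂), baseline held fixed — CI width therefore reflects
relative-hazard uncertainty only, not baseline uncertainty (an option for
which would be a one-line extension).  Behaviour over the horizon either
continues the scenario plan (default: smokers keep accruing duration and
pack-years, quitters accrue years-since-quit) or is frozen at the
evaluation age (`behavior_freeze`).

The packaged life table is **synthetic**: Gompertz-type
q(a) = 5e-5·e^{0.085a}, capped at 0.7, with multipliers never 1.0,
former 1.5, current 2.2 — the broad level and status ordering of U.S.
adult all-cause mortality.  Real tables in the same CSV schema
(`age,status,q_annual`) drop in by file.

## Validation

Calibration: observed events and person-years per sex × smoking status ×
5-year age band on the held-out half, against expected counts
Σ row-hazards over the *same* rows (so total expected equals the summed
predicted hazards exactly, a bookkeeping identity the tests assert).
Bands are exact (Garwood/chi-square) Poisson intervals on expected
counts; the goodness-of-fit statistic is the Poisson deviance across
strata with a chi-square reference — a stated choice, since the
methodology being followed does not name its test.  Empty strata simply
do not appear.

Discrimination: every validation subject is scored with their 6-year risk
at baseline (the later of study entry and the window start), smoking
behaviour held to its baseline state, exposures accruing; the label is a
diagnosis within the horizon.  AUC is the Mann–Whitney statistic
(midranks for ties; cross-checked against scikit-learn), CIs are
subject-level nonparametric bootstrap with 100 iterations, and model
comparisons use a *paired* bootstrap of ΔAUC with shared resampling
indices, with a two-sided sign probability as p-value.  Subjects dying or
lost before the horizon without a diagnosis count as controls by default;
an exclusion mode is provided.

## Synthetic cohort generator

The generator is the package's stand-in for restricted prospective cohort
data and defines the conditions under which everything is tested.

Structure: 68.6% women enrolled in 1976 (entry ages ~N(42, (12/1.349)²)
truncated to 30–55) and men enrolled in 1986 (~N(52, (16/1.349)²),
40–75); observation window 1998–2008; subjects conditioned alive and
diagnosis-free at entry; diagnoses before 1998 excluded as prevalent
(recall-bias guard), which doubles as the left-truncation condition for
the baseline fit.

Smoking: ever-smoking probability 0.58 (women) / 0.68 (men); initiation
age ~N(18, 3²) in [12, 35]; one intensity category per subject drawn from
sex-specific distributions (men heavier); cessation as a 3%/year
geometric hazard with no relapse — a two-state annual current/former
chain, since relapse is not modelled downstream either.  Loss to
follow-up is an independent 0.5%/year; the source design reports ≥90%
questionnaire response but no loss model, so this is a free parameter,
not an estimate.

Onset: the inverse-CDF draw from the exact discrete annual hazard
λ₀(a)·exp(β·X(a)) with year-end placement, so generator and risk engine
share one discretization and self-consistency checks have no
discretization gap.  Death uses the packaged life table via the subject's
current smoking status; outcome is the earliest of onset, death, loss and
administrative end, with ties resolved diagnosis > death > loss.

Generating coefficients default to the combined-model hazard ratios the
modelled study reports (pack-years 1.05, duration 1.02, years-since-quit
0.99, sex 1.78, sex×duration 0.99, spline interactions 0.96/0.97 on this
package's basis scale with boundary knots 40/90 and interior knot 65).
The baseline defaults (μ = ln-age location 4.95, σ = 0.35) and the
initiation probabilities were chosen once so the simulated margins match
the published cohort description — ~3.5–4% of subjects diagnosed during
1998–2008, about a quarter of cases in never smokers, median diagnosis
age ~70, never-smoker incidence rising from ~40 to ~300 per 100,000
between ages 55 and 75 — and are not tuned per experiment.  A log-normal
hazard cannot combine that incidence level with much steeper age growth,
which has one visible consequence: at 40 pack-years held fixed, projected
risk can dip between ages 70 and 80 because the age-declining per-pack-
year coefficient outruns baseline growth.  Age-monotonicity of the risk
grid is therefore asserted (and guaranteed) only for moderate exposure.

What the generator does **not** emulate: calendar trends in initiation or
cessation, relapse, multiple episodes or products, age-banded pre-entry
intensity reconstruction, reporting error in recalled histories, and
diagnosis misclassification.  Passing tests show the pipeline is correct
*under its own model family and a realistic data shape* — they cannot
show robustness to model misspecification or measurement error in real
cohorts.

Randomness: every named quantity draws from its own stream seeded by
(master seed, variable id), so cohorts are deterministic given the seed
and the first k subjects of a larger cohort coincide with a size-k
cohort.

## Problem sizes and test design

The statistical acceptance tests run, by choice, at: one 50,000-subject
cohort for parameter recovery (fitted HRs within 2 SE of generating
values) and calibration under the generating model; 100 replicates of
5,000 subjects for 95% CI coverage (accepting 89–99/100 per coefficient);
100 replicates of 10,000 subjects for the discrimination ordering
(combined ≥ pack-years-only AUC in ≥ 90); 2,500 fresh scenario-following
subjects per scenario for end-to-end self-consistency, sized so the
3-binomial-SE band dominates the ~5% estimation error of a build-half
fit; and 20 small random datasets checked against an independent survival
package at 1e-6.  Oracle checks pin the spline basis to an independent
natural-interpolant construction and the small-sample partial likelihood
to a brute-force grid maximization.

## Known limitations

- The log-normal baseline constrains the achievable age-gradient of
  incidence (see above); alternative families sit behind a small
  interface but are not implemented.
- Bootstrap CIs ignore baseline-parameter uncertainty by default.
- The sequential relative-hazard + parametric-baseline construction is
  internally inconsistent in principle (no joint likelihood).
- Calibration of a bundle fitted on a few hundred events can fail a
  deviance test purely from estimation noise; the goodness-of-fit p-value
  tests the fitted bundle, not the methodology.
- Entry ages, initiation and cessation are annual-resolution
  simplifications; sub-annual timing is out of scope throughout.
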