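"""Synthetic cohort generator: determinism, degenerate parameters,
prevalent-case exclusion, splitting, and distributional checks against the
generating hazard."""

import numpy as np
import pandas as pd
import pytest

from copdrisk.baseline import BaselineHazard
from copdrisk.cohort import (
    CohortSpec,
    SexParams,
    TrueModel,
    default_true_model,
    exclude_prevalent,
    generate_cohort,
    split_build_validate,
)
from copdrisk.exposure import expand_cohort


def small_spec(**kw):
    base = dict(n_subjects=500, seed=12)
    base.update(kw)
    return CohortSpec(**base)


def no_smoking_spec(**kw):
    spec = small_spec(**kw)
    return CohortSpec(
        **{
            **{k: getattr(spec, k) for k in (
                "n_subjects", "sex_mix", "initiation_age_mean", "initiation_age_sd",
                "initiation_age_range", "annual_cessation_prob", "annual_loss_prob",
                "followup_window", "seed",
            )},
            "female": SexParams(**{**spec.female.__dict__, "init_prob": 0.0}),
            "male": SexParams(**{**spec.male.__dict__, "init_prob": 0.0}),
        }
    )


def zero_beta_model(mu=5.0, sigma=0.5):
    base = default_true_model()
    return TrueModel(
        beta={k: 0.0 for k in base.beta},
        basis=base.basis,
        baseline=BaselineHazard(mu=mu, sigma=sigma),
        life_table=base.life_table,
    )


def test_fixed_seed_is_reproducible():
    a = generate_cohort(small_spec())
    b = generate_cohort(small_spec())
    pd.testing.assert_frame_equal(a, b)


def test_prefix_stability_under_subsetting():
    small = generate_cohort(small_spec(n_subjects=200))
    large = generate_cohort(small_spec(n_subjects=500))
    pd.testing.assert_frame_equal(small, large.iloc[:200])


def test_zero_initiation_probability_gives_all_never_smokers():
    cohort = generate_cohort(no_smoking_spec())
    assert (cohort["episodes"].apply(len) == 0).all()
    pp = expand_cohort(cohort, (1998, 2008))
    assert (pp[["duration", "pack_years", "ysq"]].to_numpy() == 0).all()


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        CohortSpec(n_subjects=0)
    with pytest.raises(ValueError):
        CohortSpec(n_subjects=10, sex_mix=1.5)
    with pytest.raises(ValueError):
        CohortSpec(n_subjects=10, followup_window=(2008, 1998))


def test_incompatible_coefficient_names_rejected():
    with pytest.raises(ValueError, match="coefficient names"):
        TrueModel(beta={"pack_years": 0.1})


def test_outcome_invariants():
    cohort = generate_cohort(small_spec(n_subjects=2000))
    assert (cohort["outcome_age"] > cohort["entry_age"]).all()
    assert set(cohort["outcome"]) <= {"copd", "death", "lost", "admin_censor"}
    admin = cohort[cohort["outcome"] == "admin_censor"]
    assert (
        admin["birth_year"] + admin["outcome_age"] == small_spec().followup_window[1]
    ).all()


def test_person_time_conservation_through_expansion():
    cohort = generate_cohort(small_spec())
    pp = expand_cohort(cohort, small_spec().followup_window)
    total_rows = pp.groupby("subject_id").size()
    expected = cohort.set_index("subject_id")["outcome_age"].clip(lower=1)
    assert (total_rows == expected.loc[total_rows.index]).all()


def test_constant_hazard_incidence_recovered_with_null_coefficients():
    """With all coefficients zero the observed annual incidence among
    at-risk never-smoker-equivalents equals the baseline hazard."""
    # lognormal with huge sigma is nearly flat over 55-75; use moderate ages
    model = zero_beta_model(mu=5.0, sigma=0.5)
    spec = small_spec(n_subjects=30000, annual_loss_prob=0.0)
    cohort = generate_cohort(spec, model, disable_mortality=True)
    pp = expand_cohort(cohort, spec.followup_window)
    ar = pp[pp["at_risk"] == 1]
    by_age = ar.groupby("age_start").agg(n=("event", "size"), ev=("event", "sum"))
    by_age = by_age[by_age["n"] > 3000]
    lam = model.baseline.hazard(by_age.index.to_numpy(float))
    expect_p = -np.expm1(-lam)
    obs = by_age["ev"] / by_age["n"]
    se = np.sqrt(expect_p * (1 - expect_p) / by_age["n"])
    assert (np.abs(obs - expect_p) < 4 * se).all()


def test_competing_mortality_reduces_case_count():
    spec = small_spec(n_subjects=5000)
    with_death = generate_cohort(spec)
    without = generate_cohort(spec, disable_mortality=True)
    assert (with_death["outcome"] == "copd").sum() < (without["outcome"] == "copd").sum()


def test_exclude_prevalent_calendar_rule():
    cohort = pd.DataFrame(
        {
            "subject_id": [1, 2, 3],
            "sex_female": [1, 1, 0],
            "birth_year": [1934, 1934, 1940],
            "entry_age": [42, 42, 46],
            "episodes": [[], [], []],
            "outcome": ["copd", "copd", "death"],
            "outcome_age": [60, 66, 60],
        }
    )
    kept = exclude_prevalent(cohort, 1998)
    # diagnosed 1994 -> excluded; diagnosed 2000 -> retained; death untouched
    assert sorted(kept["subject_id"]) == [2, 3]
    assert kept.attrs["n_excluded_prevalent"] == 1
    no_cases = cohort[cohort["outcome"] != "copd"].reset_index(drop=True)
    pd.testing.assert_frame_equal(exclude_prevalent(no_cases, 1998), no_cases)


@pytest.mark.parametrize("n,sizes", [(10, {5}), (11, {5, 6})])
def test_split_sizes(n, sizes):
    cohort = generate_cohort(small_spec(n_subjects=n))
    a, b = split_build_validate(cohort, seed=0)
    assert {len(a), len(b)} == sizes
    assert set(a["subject_id"]).isdisjoint(b["subject_id"])
    assert len(a) + len(b) == n


def test_split_deterministic():
    cohort = generate_cohort(small_spec(n_subjects=101))
    a1, b1 = split_build_validate(cohort, seed=5)
    a2, b2 = split_build_validate(cohort, seed=5)
    pd.testing.assert_frame_equal(a1, a2)
    pd.testing.assert_frame_equal(b1, b2)


def test_km_of_onset_matches_lognormal_survival_without_competing_risks():
    """With null coefficients, no mortality and no loss, the onset-age
    survival curve from the simulation tracks 1 - Phi((ln t - mu)/sigma)
    conditioned on entry."""
    model = zero_beta_model(mu=5.2, sigma=0.6)
    spec = small_spec(n_subjects=30000, annual_loss_prob=0.0)
    cohort = generate_cohort(spec, model, disable_mortality=True)
    # restrict to one female entry age so the conditioning is a single
    # survival ratio and administrative censoring (age 74) is beyond reach
    sub = cohort[
        cohort["entry_age"].between(41, 43) & (cohort["sex_female"] == 1)
    ]
    assert len(sub) > 2000
    onsets = sub[sub["outcome"] == "copd"]["outcome_age"]
    at_risk_base = len(sub)
    for age in (50, 60, 70):
        p_model = 1 - np.exp(
            -(model.baseline.cumulative_hazard(age) - model.baseline.cumulative_hazard(42))
        )
        # discrete-grid analogue of the cumulative incidence by `age`
        lam = model.baseline.hazard(np.arange(42, age).astype(float))
        p_grid = 1 - np.exp(-lam.sum())
        p_obs = (onsets <= age).sum() / at_risk_base
        se = np.sqrt(p_grid * (1 - p_grid) / at_risk_base)
        assert abs(p_obs - p_grid) < 4 * se
        assert p_grid == pytest.approx(p_model, rel=0.05)
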