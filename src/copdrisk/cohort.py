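"""Synthetic smoking cohorts with simulated COPD onset and censoring.

The generator emulates the structure of two large prospective cohorts: a
female subcohort enrolled in 1976 at ages 30-55 and a male subcohort
enrolled in 1986 at ages 40-75, with lifetime smoking histories (start
age, intensity category, possible cessation) and an observation window
(default 1998-2008) in which diagnoses are ascertained.

Disease onset is simulated from the same hazard model the pipeline fits:
``h(a) = lambda0(a) * exp(beta . X(a))`` on an annual grid, where ``X(a)``
carries duration, cumulative pack-years, years-since-quit, sex and the
age x pack-years spline interactions, all left-continuous.  Onset within a
year is placed at the year end, matching the annual-interval coding of the
person-period expansion, so the simulated distribution coincides exactly
with the discrete-hazard model downstream modules assume.  Other-cause
death is drawn from a smoking-status-stratified life table, loss to
follow-up as a small constant annual probability; the observed outcome is
the earliest of onset, death, loss and administrative end of study.
Subjects are conditioned on being alive and disease-free at study entry.

Randomness: each named variable draws from its own stream seeded by
``(master seed, variable id)``, so the first ``k`` subjects of a size-``n``
cohort equal a size-``k`` cohort with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baseline import BaselineHazard
from .coxtv import COMBINED_COVARIATES
from .exposure import CPD_CATEGORIES, CPD_MIDPOINTS
from .lifetable import LifeTable, default_life_table
from .splines import SplineBasis

__all__ = [
    "CohortSpec",
    "TrueModel",
    "default_true_model",
    "generate_cohort",
    "split_build_validate",
    "exclude_prevalent",
]

#: generating log hazard ratios; exp() of these are the hazard-ratio
#: defaults for the combined model (per pack-year, per year of duration,
#: per year since quit, female vs male, and per pack-year per spline unit).
DEFAULT_HR = {
    "pack_years": 1.05,
    "duration": 1.02,
    "ysq": 0.99,
    "sex_female": 1.78,
    "sex_female_x_duration": 0.99,
    "spline1_x_pack_years": 0.96,
    "spline2_x_pack_years": 0.97,
}


@dataclass(frozen=True)
class SexParams:
    """Per-sex enrolment and smoking-behaviour parameters."""

    start_year: int  # calendar year of cohort enrolment
    entry_age_median: float
    entry_age_iqr: float
    entry_age_range: tuple[float, float]
    init_prob: float  # probability of ever initiating smoking
    cpd_probs: tuple[float, ...]  # over the six CPD categories


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort."""

    n_subjects: int
    sex_mix: float = 0.686  # proportion female
    female: SexParams = SexParams(
        start_year=1976,
        entry_age_median=42.0,
        entry_age_iqr=12.0,
        entry_age_range=(30, 55),
        init_prob=0.58,
        cpd_probs=(0.10, 0.25, 0.40, 0.15, 0.07, 0.03),
    )
    male: SexParams = SexParams(
        start_year=1986,
        entry_age_median=52.0,
        entry_age_iqr=16.0,
        entry_age_range=(40, 75),
        init_prob=0.68,
        cpd_probs=(0.05, 0.15, 0.35, 0.25, 0.12, 0.08),
    )
    initiation_age_mean: float = 18.0
    initiation_age_sd: float = 3.0
    initiation_age_range: tuple[float, float] = (12, 35)
    annual_cessation_prob: float = 0.03
    annual_loss_prob: float = 0.005
    followup_window: tuple[int, int] = (1998, 2008)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for p in (
            self.sex_mix,
            self.female.init_prob,
            self.male.init_prob,
            self.annual_cessation_prob,
            self.annual_loss_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not self.followup_window[0] < self.followup_window[1]:
            raise ValueError("followup window start must precede end")


@dataclass(frozen=True)
class TrueModel:
    """Generating hazard model: coefficients, spline basis, baseline, mortality."""

    beta: dict = field(default_factory=lambda: {k: float(np.log(v)) for k, v in DEFAULT_HR.items()})
    basis: SplineBasis = SplineBasis(boundary_knots=(40.0, 90.0), interior_knots=(65.0,))
    baseline: BaselineHazard = BaselineHazard(mu=4.95, sigma=0.35)
    life_table: LifeTable = field(default_factory=default_life_table)

    def __post_init__(self) -> None:
        expected = set(COMBINED_COVARIATES)
        got = set(self.beta)
        if got != expected:
            raise ValueError(
                f"coefficient names {sorted(got)} do not match the design "
                f"columns {sorted(expected)}"
            )
        for name, v in self.beta.items():
            if not np.isfinite(v):
                raise ValueError(f"coefficient {name} is not finite")

    def with_beta(self, **updates) -> "TrueModel":
        beta = dict(self.beta)
        beta.update(updates)
        return replace(self, beta=beta)

    def linear_predictor_grid(self, ages, sex_female, duration, pack_years, ysq):
        """``beta . X(a)`` for broadcastable covariate arrays over ``ages``."""
        b = self.beta
        spl = self.basis.evaluate(np.asarray(ages, dtype=float))
        lp = (
            b["pack_years"] * pack_years
            + b["duration"] * duration
            + b["ysq"] * ysq
            + b["sex_female"] * sex_female
            + b["sex_female_x_duration"] * sex_female * duration
            + b["spline1_x_pack_years"] * spl[..., 0] * pack_years
            + b["spline2_x_pack_years"] * spl[..., 1] * pack_years
        )
        return lp


def default_true_model() -> TrueModel:
    return TrueModel()


def _stream(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt]))


def _draw_from_inverse(u, probs):
    """Categorical draw by inverse CDF so streams stay prefix-stable."""
    edges = np.cumsum(probs)
    edges = edges / edges[-1]
    return np.searchsorted(edges, u, side="right").clip(0, len(probs) - 1)


def _first_crossing(cum, start_idx, target):
    """First interval ``a >= start_idx`` where the cumulative hazard gained
    since ``start_idx`` reaches ``target``.

    ``cum`` has shape ``(n, G+1)`` with ``cum[:, a]`` the cumulative hazard
    from age 0 to age ``a``; the crossing condition is ``cum[:, a+1] -
    cum[:, start] >= target``.  Returns ``G`` when the target is never
    reached on the grid.
    """
    n, G1 = cum.shape
    G = G1 - 1
    base = cum[np.arange(n), start_idx]
    excess = cum[:, 1:] - base[:, None] - target[:, None]
    hit = excess >= 0
    hit &= np.arange(G)[None, :] >= start_idx[:, None]
    any_hit = hit.any(axis=1)
    return np.where(any_hit, hit.argmax(axis=1), G)


def generate_cohort(
    spec: CohortSpec,
    model: TrueModel | None = None,
    disable_mortality: bool = False,
) -> pd.DataFrame:
    """Simulate a cohort of smoking histories with observed outcomes.

    Returns one row per subject: ``subject_id, sex_female, birth_year,
    entry_age, episodes, outcome, outcome_age``, where ``episodes`` is a
    list of ``(start_age, end_age | None, category)`` tuples and outcomes
    are ``copd``, ``death``, ``lost`` or ``admin_censor`` at integer
    (year-end) ages.  Deterministic for a fixed ``spec.seed``.
    """
    if model is None:
        model = default_true_model()
    n = spec.n_subjects
    seed = spec.seed
    start_year_window, end_year = spec.followup_window

    sex_female = (_stream(seed, 1).uniform(size=n) < spec.sex_mix).astype(int)

    # entry age: normal around the per-sex median (sd from the IQR of a
    # normal), truncated to the enrolment range, annual resolution
    z = _stream(seed, 2).standard_normal(n)
    med = np.where(sex_female == 1, spec.female.entry_age_median, spec.male.entry_age_median)
    sd = np.where(sex_female == 1, spec.female.entry_age_iqr, spec.male.entry_age_iqr) / 1.349
    lo = np.where(sex_female == 1, spec.female.entry_age_range[0], spec.male.entry_age_range[0])
    hi = np.where(sex_female == 1, spec.female.entry_age_range[1], spec.male.entry_age_range[1])
    entry_age = np.clip(np.round(med + sd * z), lo, hi).astype(int)
    start_year = np.where(sex_female == 1, spec.female.start_year, spec.male.start_year)
    birth_year = start_year - entry_age
    admin_age = end_year - birth_year  # administrative censoring age

    # smoking initiation, intensity and cessation
    init_p = np.where(sex_female == 1, spec.female.init_prob, spec.male.init_prob)
    ever = _stream(seed, 3).uniform(size=n) < init_p
    a0 = np.clip(
        np.round(spec.initiation_age_mean + spec.initiation_age_sd * _stream(seed, 4).standard_normal(n)),
        *spec.initiation_age_range,
    ).astype(int)
    u_cat = _stream(seed, 5).uniform(size=n)
    cat_idx = np.where(
        sex_female == 1,
        _draw_from_inverse(u_cat, np.asarray(spec.female.cpd_probs)),
        _draw_from_inverse(u_cat, np.asarray(spec.male.cpd_probs)),
    )
    cpd = np.asarray([CPD_MIDPOINTS[c] for c in CPD_CATEGORIES])[cat_idx]
    # years smoked before quitting: geometric via inverse CDF (support >= 1)
    u_quit = _stream(seed, 6).uniform(size=n)
    p_c = spec.annual_cessation_prob
    if p_c > 0:
        k = np.ceil(np.log1p(-u_quit) / np.log1p(-p_c)).astype(int).clip(1, None)
        quit_age = a0 + k
    else:
        quit_age = np.full(n, np.iinfo(np.int64).max // 2)
    start_s = np.where(ever, a0, 10**6).astype(float)  # inf-like for never
    quit_s = np.where(ever, quit_age, 10**6).astype(float)
    cpd_s = np.where(ever, cpd, 0.0)

    # annual hazard grid from age 0 to the oldest possible censoring age
    G = int(admin_age.max()) + 1
    ages = np.arange(G, dtype=float)  # interval [a, a+1)
    dur = np.clip(np.minimum(ages[None, :], quit_s[:, None]) - start_s[:, None], 0.0, None)
    py = dur * (cpd_s[:, None] / 20.0)
    ysq = np.clip(ages[None, :] - quit_s[:, None], 0.0, None)
    lp = model.linear_predictor_grid(ages, sex_female[:, None], dur, py, ysq)
    lam0 = np.zeros(G)
    lam0[1:] = model.baseline.hazard(ages[1:])
    h = lam0[None, :] * np.exp(lp)
    cum_h = np.concatenate([np.zeros((n, 1)), np.cumsum(h, axis=1)], axis=1)
    # cum_h[:, a] = cumulative disease hazard from age 0 to age a

    # onset: inverse-cdf draw conditioned on being disease-free at entry
    e_onset = -np.log(_stream(seed, 7).uniform(size=n))
    onset_idx = _first_crossing(cum_h, entry_age, e_onset)
    onset_age = np.where(onset_idx < G, onset_idx + 1, 10**6)
    # onset_idx is the interval start a; onset placed at year end a+1

    # other-cause death from the life table, by current smoking status
    if disable_mortality:
        death_age = np.full(n, 10**6)
    else:
        lt_lo, m_grid = model.life_table.hazard_matrix()
        status_idx = np.zeros((n, G), dtype=int)  # 0=never, 1=current, 2=former
        is_cur = (start_s[:, None] <= ages[None, :]) & (ages[None, :] < quit_s[:, None])
        is_for = ages[None, :] >= quit_s[:, None]
        status_idx[is_cur] = 1
        status_idx[is_for] = 2
        age_cols = np.clip(np.arange(G) - lt_lo, 0, m_grid.shape[1] - 1)
        m = m_grid[status_idx, age_cols[None, :]]
        cum_m = np.concatenate([np.zeros((n, 1)), np.cumsum(m, axis=1)], axis=1)
        e_death = -np.log(_stream(seed, 8).uniform(size=n))
        death_idx = _first_crossing(cum_m, entry_age, e_death)
        death_age = np.where(death_idx < G, death_idx + 1, 10**6)

    # loss to follow-up: constant annual probability after entry
    u_loss = _stream(seed, 9).uniform(size=n)
    if spec.annual_loss_prob > 0:
        k_loss = np.ceil(np.log1p(-u_loss) / np.log1p(-spec.annual_loss_prob)).astype(int).clip(1, None)
        loss_age = entry_age + k_loss
    else:
        loss_age = np.full(n, 10**6)

    candidates = np.stack([onset_age, death_age, loss_age, admin_age], axis=1)
    labels = np.array(["copd", "death", "lost", "admin_censor"])
    # ties resolve in listed order: diagnosis beats death beats loss
    which = candidates.argmin(axis=1)
    outcome_age = candidates[np.arange(n), which]
    outcome = labels[which]

    episodes = []
    for i in range(n):
        if not ever[i] or start_s[i] >= outcome_age[i]:
            episodes.append([])
        elif quit_age[i] >= outcome_age[i]:
            episodes.append([(int(a0[i]), None, CPD_CATEGORIES[cat_idx[i]])])
        else:
            episodes.append([(int(a0[i]), int(quit_age[i]), CPD_CATEGORIES[cat_idx[i]])])

    return pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "sex_female": sex_female,
            "birth_year": birth_year,
            "entry_age": entry_age,
            "episodes": episodes,
            "outcome": outcome,
            "outcome_age": outcome_age.astype(int),
        }
    )


def split_build_validate(cohort: pd.DataFrame, seed: int = 0):
    """Random 50-50 subject-level split into build and validation halves."""
    n = len(cohort)
    if n < 2:
        raise ValueError("need at least two subjects to split")
    perm = np.random.default_rng(np.random.SeedSequence([int(seed), 99])).permutation(n)
    half = n // 2
    build = cohort.iloc[np.sort(perm[:half])].reset_index(drop=True)
    validate = cohort.iloc[np.sort(perm[half:])].reset_index(drop=True)
    return build, validate


def exclude_prevalent(cohort: pd.DataFrame, cutoff_year: int = 1998) -> pd.DataFrame:
    """Drop subjects diagnosed in a calendar year before ``cutoff_year``.

    Diagnosis year is ``birth_year + outcome_age`` (year-end placement).
    """
    year = cohort["birth_year"] + cohort["outcome_age"]
    prevalent = (cohort["outcome"] == "copd") & (year < cutoff_year)
    kept = cohort[~prevalent].reset_index(drop=True)
    kept.attrs["n_excluded_prevalent"] = int(prevalent.sum())
    return kept
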