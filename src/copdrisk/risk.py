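"""Absolute COPD risk projection from a fitted hazard bundle.

A prediction bundle pairs the fitted hazard-ratio model with the
never-smoker log-normal baseline: the age-specific incidence for a smoking
scenario is ``lambda0(t) * exp(beta . X(t))``.  N-year risks integrate
that hazard over an annual grid with hazards held constant within years:

    unadjusted risk = 1 - exp(-sum_t h(t))

and, with competing other-cause mortality ``m(t) = -ln(1 - q(t, status))``
from a life table, the cause-specific (adjusted) risk

    sum_t  exp(-sum_{u<t} (h(u)+m(u))) * h(t)/(h(t)+m(t)) * (1 - e^{-(h(t)+m(t))})

which reduces exactly to the unadjusted form when ``m == 0`` and to the
closed form ``h/(h+m) * (1 - e^{-N(h+m)})`` for constant hazards.
Confidence intervals come from a parametric bootstrap of the coefficient
vector (multivariate normal with the fit covariance), holding the baseline
fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baseline import BaselineHazard
from .coxtv import HazardModelFit
from .lifetable import LifeTable

__all__ = [
    "Scenario",
    "PredictionBundle",
    "RiskEstimate",
    "incidence_at",
    "relative_risk",
    "nyear_risk",
    "risk_table",
    "TABLE_AGES",
    "TABLE_DURATIONS",
    "TABLE_PACK_YEARS",
]

TABLE_AGES = (50, 60, 70, 80)
TABLE_DURATIONS = (20, 30, 40)
TABLE_PACK_YEARS = (20, 40)
MIN_START_AGE = 12  # youngest plausible initiation age for feasibility checks


@dataclass(frozen=True)
class Scenario:
    """A smoking plan to project risk for.

    ``episodes`` holds ``(start_age, end_age | None, cpd)`` triples with raw
    cigarettes-per-day values (``None`` end = smoking continues through the
    horizon).  ``behavior_freeze`` evaluates all covariates at ``age`` and
    holds them fixed over the horizon instead of letting duration,
    pack-years and years-since-quit accrue.
    """

    sex_female: int
    episodes: tuple = ()
    age: float = 60.0
    horizon: int = 6
    behavior_freeze: bool = False

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 year")
        prev = -np.inf
        for s, e, cpd in self.episodes:
            end = np.inf if e is None else e
            if not s < end:
                raise ValueError(f"episode start {s} must precede end {e}")
            if s < prev:
                raise ValueError("episodes overlap or are out of order")
            if cpd < 0:
                raise ValueError("cpd must be non-negative")
            prev = end

    @classmethod
    def never_smoker(cls, sex_female: int, age: float, **kw) -> "Scenario":
        return cls(sex_female=sex_female, episodes=(), age=age, **kw)

    @classmethod
    def current_smoker(cls, sex_female: int, age: float, cpd: float, start_age: float = 20.0, **kw):
        return cls(sex_female=sex_female, episodes=((start_age, None, cpd),), age=age, **kw)

    @classmethod
    def former_smoker(
        cls, sex_female: int, age: float, cpd: float, start_age: float = 20.0, quit_age: float = 40.0, **kw
    ):
        return cls(sex_female=sex_female, episodes=((start_age, quit_age, cpd),), age=age, **kw)

    def covariates_at(self, ages) -> dict[str, np.ndarray]:
        """Left-continuous duration / pack-years / ysq / status at each age."""
        a = np.atleast_1d(np.asarray(ages, dtype=float))
        if self.behavior_freeze:
            a = np.full_like(a, float(self.age))
        dur = np.zeros_like(a)
        py = np.zeros_like(a)
        current = np.zeros_like(a, dtype=bool)
        last_quit = np.full_like(a, -np.inf)
        for s, e, cpd in self.episodes:
            end = np.inf if e is None else float(e)
            years = np.clip(np.minimum(a, end) - s, 0.0, None)
            dur += years
            py += years * cpd / 20.0
            current |= (s <= a) & (a < end)
            last_quit = np.where((end <= a) & (end > last_quit), end, last_quit)
        former = (~current) & (last_quit > -np.inf)
        ysq = np.where(former, a - last_quit, 0.0)
        status = np.where(current, "current", np.where(former, "former", "never"))
        return {"duration": dur, "pack_years": py, "ysq": ysq, "status": status}


@dataclass(frozen=True)
class RiskEstimate:
    scenario: Scenario
    risk: float
    adjusted: bool
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.ci is not None and not (self.ci[0] <= self.risk <= self.ci[1]):
            raise ValueError("point estimate outside its confidence interval")


@dataclass
class PredictionBundle:
    """Fitted hazard-ratio model + baseline hazard, ready for projection."""

    fit: HazardModelFit
    baseline: BaselineHazard

    def linear_predictor(self, ages, sex_female, duration, pack_years, ysq) -> np.ndarray:
        """``beta . X(t)`` from raw covariate arrays (broadcastable)."""
        beta = self.fit.beta
        ages = np.asarray(ages, dtype=float)
        lp = np.zeros(np.broadcast(ages, duration, pack_years).shape)
        get = beta.get
        lp = lp + get("pack_years", 0.0) * pack_years
        lp = lp + get("duration", 0.0) * duration
        lp = lp + get("ysq", 0.0) * ysq
        lp = lp + get("sex_female", 0.0) * sex_female
        lp = lp + get("sex_female_x_duration", 0.0) * sex_female * duration
        if "spline1_x_pack_years" in beta.index:
            if self.fit.spline_basis is None:
                raise ValueError("fit has spline terms but no serialized basis")
            b = self.fit.spline_basis.evaluate(ages)
            lp = lp + beta["spline1_x_pack_years"] * b[..., 0] * pack_years
            lp = lp + beta["spline2_x_pack_years"] * b[..., 1] * pack_years
        return lp

    def with_beta(self, beta: pd.Series) -> "PredictionBundle":
        return PredictionBundle(fit=replace(self.fit, beta=beta), baseline=self.baseline)

    def scenario_hazard(self, scenario: Scenario, ages) -> np.ndarray:
        """Per-year incidence ``lambda0(t) e^{beta.X(t)}`` along ``ages``."""
        a = np.atleast_1d(np.asarray(ages, dtype=float))
        if np.any(a <= 0):
            raise ValueError("ages must be positive (baseline support)")
        cov = scenario.covariates_at(a)
        lp = self.linear_predictor(
            a, float(scenario.sex_female), cov["duration"], cov["pack_years"], cov["ysq"]
        )
        return self.baseline.hazard(a) * np.exp(lp)


def incidence_at(bundle: PredictionBundle, scenario: Scenario, age: float) -> float:
    """Scenario incidence at one age, events per person-year."""
    return float(bundle.scenario_hazard(scenario, [float(age)])[0])


def relative_risk(
    bundle: PredictionBundle, scenario_a: Scenario, scenario_b: Scenario, age: float
) -> float:
    """Incidence ratio of two scenarios at the same age; the baseline
    hazard cancels exactly."""
    return incidence_at(bundle, scenario_a, age) / incidence_at(bundle, scenario_b, age)


def _cause_specific_risk(h: np.ndarray, m: np.ndarray) -> float:
    """Discrete cause-specific cumulative risk with annual constant hazards."""
    tot = h + m
    surv_in = np.exp(-np.concatenate([[0.0], np.cumsum(tot[:-1])]))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, h / np.where(tot > 0, tot, 1.0), 0.0)
    return float(np.sum(surv_in * frac * -np.expm1(-tot)))


def nyear_risk(
    bundle: PredictionBundle,
    scenario: Scenario,
    life_table: LifeTable | None = None,
    n_boot: int = 0,
    seed: int = 0,
    step: float = 1.0,
) -> RiskEstimate:
    """Probability of diagnosis within ``scenario.horizon`` years of
    ``scenario.age``, conditional on being diagnosis-free (and, when a life
    table is supplied, alive) at that age.

    With no life table the risk is ``1 - exp(-sum h)``; with one, the
    competing-mortality-adjusted cause-specific risk (see module docstring).
    ``step`` < 1 refines the grid (hazards still constant within steps).
    ``n_boot`` > 0 adds a percentile CI from a parametric bootstrap of the
    coefficients.
    """
    a0, N = float(scenario.age), int(scenario.horizon)
    grid = np.arange(a0, a0 + N, step)

    def risk_for(b: PredictionBundle) -> float:
        h = b.scenario_hazard(scenario, grid) * step
        if life_table is None:
            return float(-np.expm1(-h.sum()))
        status = scenario.covariates_at(grid)["status"]
        m = life_table.hazard(np.floor(grid).astype(int), status) * step
        return _cause_specific_risk(h, m)

    point = risk_for(bundle)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(
            bundle.fit.beta.to_numpy(), bundle.fit.vcov.to_numpy(), size=n_boot
        )
        sims = np.array(
            [risk_for(bundle.with_beta(pd.Series(d, index=bundle.fit.beta.index))) for d in draws]
        )
        lo, hi = np.quantile(sims, [0.025, 0.975])
        ci = (min(float(lo), point), max(float(hi), point))
    return RiskEstimate(scenario=scenario, risk=point, adjusted=life_table is not None, ci=ci)


def risk_table(
    bundle: PredictionBundle,
    life_table: LifeTable | None = None,
    ages=TABLE_AGES,
    durations=TABLE_DURATIONS,
    pack_years=TABLE_PACK_YEARS,
    horizon: int = 6,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Grid of N-year risks for current/former smoker scenarios.

    Rows span sex x pack-years x age x duration x {current, former
    quitting at the evaluation age}; ``feasible`` is False when the
    requested duration cannot fit before the evaluation age.  Risks are in
    percent with bootstrap percentile CIs.
    """
    rows = []
    for sex_female in (1, 0):
        for py in pack_years:
            for age in ages:
                for dur in durations:
                    start = age - dur
                    feasible = start >= MIN_START_AGE
                    for kind in ("current", "former"):
                        row = {
                            "sex": "female" if sex_female else "male",
                            "pack_years": py,
                            "age": age,
                            "duration": dur,
                            "smoker": kind,
                            "feasible": feasible,
                        }
                        if feasible:
                            cpd = 20.0 * py / dur
                            quit = None if kind == "current" else float(age)
                            scen = Scenario(
                                sex_female=sex_female,
                                episodes=((float(start), quit, cpd),),
                                age=float(age),
                                horizon=horizon,
                            )
                            est = nyear_risk(
                                bundle, scen, life_table=life_table, n_boot=n_boot, seed=seed
                            )
                            row["risk_pct"] = 100 * est.risk
                            if est.ci is not None:
                                row["ci_lo_pct"] = 100 * est.ci[0]
                                row["ci_hi_pct"] = 100 * est.ci[1]
                        rows.append(row)
    return pd.DataFrame(rows)


def incidence_curve(
    bundle: PredictionBundle, scenario: Scenario, ages
) -> pd.DataFrame:
    """Age-specific incidence per 100,000 person-years along ``ages``."""
    h = bundle.scenario_hazard(scenario, ages)
    return pd.DataFrame({"age": np.asarray(ages, float), "incidence_per_100k": 1e5 * h})
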