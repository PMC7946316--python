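"""Cox proportional-hazards fitting on counting-process person-period rows.

The model is ``h(t) = lambda0(t) * exp(beta(t) . X(t))`` with age as the
timescale.  Covariates change yearly, subjects enter the risk set at their
study-entry age (left truncation), and the age-varying pack-years effect is
carried by spline interaction columns, so the partial likelihood itself is
the standard counting-process one: a subject is in the risk set at event
age ``t`` iff one of its at-risk rows covers ``t`` (interval ``(start,
stop]``).  Annual intervals produce heavily tied event ages; ties are
handled with Efron's method by default (Breslow optional).

Estimation is Newton-Raphson with step-halving on the exact partial
log-likelihood, its score and observed information.  All risk-set sums are
accumulated with difference arrays over the sorted distinct event ages, so
the cost per iteration is linear in rows and the fit scales to millions of
person-years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .splines import SplineBasis, build_basis, interaction_columns

__all__ = [
    "ModelSpec",
    "HazardModelFit",
    "COMBINED_COVARIATES",
    "PACKYEARS_ONLY",
    "build_design",
    "fit",
    "linear_predictor",
    "lr_test",
]

#: covariates of the full model: main smoking terms, sex, the sex x duration
#: interaction and the two spline x pack-years interaction columns.
COMBINED_COVARIATES = (
    "pack_years",
    "duration",
    "ysq",
    "sex_female",
    "sex_female_x_duration",
    "spline1_x_pack_years",
    "spline2_x_pack_years",
)

#: comparator model using the single summary exposure measure.
PACKYEARS_ONLY = ("pack_years",)


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter the linear predictor, and the ties method."""

    covariates: tuple[str, ...] = COMBINED_COVARIATES
    ties: str = "efron"

    def __post_init__(self) -> None:
        if len(self.covariates) == 0:
            raise ValueError("at least one covariate must be enabled")
        unknown = set(self.covariates) - set(COMBINED_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")
        if self.ties not in ("efron", "breslow"):
            raise ValueError(f"ties must be 'efron' or 'breslow', got {self.ties!r}")

    @property
    def needs_basis(self) -> bool:
        return any(c.startswith("spline") for c in self.covariates)


class ConvergenceError(RuntimeError):
    """Raised when Newton-Raphson fails; carries the last iterate."""

    def __init__(self, msg: str, beta_last: np.ndarray, loglik_last: float):
        super().__init__(msg)
        self.beta_last = beta_last
        self.loglik_last = loglik_last


class RankDeficientError(ValueError):
    """Design matrix has collinear columns on the at-risk rows."""

    def __init__(self, columns: list[str]):
        super().__init__(f"design matrix is rank deficient; suspect columns: {columns}")
        self.columns = columns


@dataclass
class HazardModelFit:
    """Fitted hazard-ratio model plus everything needed to predict from it."""

    spec: ModelSpec
    beta: pd.Series  # log hazard ratios, indexed by covariate name
    vcov: pd.DataFrame
    loglik: float
    loglik_null: float
    n_events: int
    n_at_risk_rows: int
    converged: bool
    iterations: int
    spline_basis: SplineBasis | None = None

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.values)), index=self.beta.index)

    def summary(self) -> pd.DataFrame:
        """Hazard ratios with 95% Wald intervals, one row per covariate."""
        se = self.se
        z = stats.norm.ppf(0.975)
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": se,
                "hr": np.exp(self.beta),
                "hr_lo": np.exp(self.beta - z * se),
                "hr_hi": np.exp(self.beta + z * se),
                "p": 2 * stats.norm.sf(np.abs(self.beta) / se),
            }
        )

    def pack_years_coef_at(self, age) -> np.ndarray:
        """Age-specific log-HR per pack-year: beta_py + g1*B1(age) + g2*B2(age)."""
        out = np.full(np.shape(np.atleast_1d(age)), self.beta.get("pack_years", 0.0))
        if self.spline_basis is not None and "spline1_x_pack_years" in self.beta.index:
            b = self.spline_basis.evaluate(np.atleast_1d(age))
            out = out + b[:, 0] * self.beta["spline1_x_pack_years"]
            out = out + b[:, 1] * self.beta["spline2_x_pack_years"]
        return out


def build_design(
    pp: pd.DataFrame,
    spec: ModelSpec,
    basis: SplineBasis | None = None,
) -> tuple[np.ndarray, SplineBasis | None]:
    """Assemble the design matrix for the at-risk rows of a person-period table.

    Spline interaction columns are ``B_j(age_start) * pack_years``; when no
    basis is supplied one is built from the at-risk event ages (knots at
    min/median/max for df=2).  Returns ``(X, basis)``.
    """
    if spec.needs_basis and basis is None:
        event_ages = pp.loc[pp["event"] == 1, "age_stop"].to_numpy(float)
        basis = build_basis(event_ages, df=2)
    cols = {}
    age = pp["age_start"].to_numpy(float)
    for name in spec.covariates:
        if name == "sex_female_x_duration":
            cols[name] = pp["sex_female"].to_numpy(float) * pp["duration"].to_numpy(float)
        elif name.startswith("spline"):
            j = int(name[len("spline")]) - 1
            b = basis.evaluate(age)
            cols[name] = b[:, j] * pp["pack_years"].to_numpy(float)
        else:
            cols[name] = pp[name].to_numpy(float)
    X = np.column_stack([cols[c] for c in spec.covariates])
    return X, basis


def _risk_index(start, stop, event_times):
    """For each row, the contiguous index range of distinct event times it
    is at risk for: ``k in [k_lo, k_hi]`` with ``start < t_k <= stop``."""
    k_lo = np.searchsorted(event_times, start, side="right")
    k_hi = np.searchsorted(event_times, stop, side="right") - 1
    return k_lo, k_hi


class _PartialLikelihood:
    """Efron/Breslow partial likelihood with score and observed information."""

    def __init__(self, start, stop, event, X, ties="efron"):
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        event = np.asarray(event, dtype=bool)
        stop = np.asarray(stop, dtype=float)
        start = np.asarray(start, dtype=float)
        self.times = np.unique(stop[event])
        self.K = self.times.size
        if self.K == 0:
            raise ValueError("no events among at-risk rows")
        self.k_lo, self.k_hi = _risk_index(start, stop, self.times)
        self.in_risk = self.k_lo <= self.k_hi
        # event rows, grouped by event-time index
        self.ev_rows = np.flatnonzero(event)
        self.ev_k = np.searchsorted(self.times, stop[self.ev_rows])
        self.d = np.bincount(self.ev_k, minlength=self.K).astype(float)
        self.ties = ties
        # upper-triangle index pairs for the information matrix
        self.tri = [(a, b) for a in range(self.p) for b in range(a, self.p)]

    def _risk_sums(self, w, extra_cols):
        """Cumulated risk-set sums at each event time for weights ``w`` and
        each of ``extra_cols`` (weights times covariate products)."""
        K = self.K
        out = []
        for col in [w] + extra_cols:
            lo = np.bincount(self.k_lo, weights=col, minlength=K + 1)
            hi = np.bincount(self.k_hi + 1, weights=col, minlength=K + 2)
            out.append(np.cumsum(lo[: K + 1] - hi[: K + 1])[:K])
        return out

    def loglik_score_info(self, beta, want_derivs=True):
        X, p, K = self.X, self.p, self.K
        eta = X @ beta
        # guard against overflow in exp during step-halving excursions
        shift = max(eta.max(), 0.0) if eta.size else 0.0
        w = np.exp(eta - shift)
        wX = w[:, None] * X
        cols1 = [wX[:, j] for j in range(p)]
        cols2 = [wX[:, a] * X[:, b] for a, b in self.tri] if want_derivs else []
        sums = self._risk_sums(w, cols1 + cols2)
        S0 = sums[0]
        S1 = np.column_stack(sums[1 : 1 + p])
        if want_derivs:
            S2 = np.zeros((K, p, p))
            for idx, (a, b) in enumerate(self.tri):
                S2[:, a, b] = sums[1 + p + idx]
                S2[:, b, a] = sums[1 + p + idx]

        # tied-event sums per event time
        ev, ek = self.ev_rows, self.ev_k
        s0D = np.bincount(ek, weights=w[ev], minlength=K)
        s1D = np.zeros((K, p))
        for j in range(p):
            s1D[:, j] = np.bincount(ek, weights=wX[ev, j], minlength=K)
        if want_derivs:
            s2D = np.zeros((K, p, p))
            for a, b in self.tri:
                v = np.bincount(ek, weights=wX[ev, a] * X[ev, b], minlength=K)
                s2D[:, a, b] = v
                s2D[:, b, a] = v
        sum_eta_D = float(np.sum(eta[ev]))
        xsum_D = np.zeros((K, p))
        for j in range(p):
            xsum_D[:, j] = np.bincount(ek, weights=X[ev, j], minlength=K)

        ll = sum_eta_D
        score = xsum_D.sum(axis=0) if want_derivs else None
        info = np.zeros((p, p)) if want_derivs else None
        for k in range(K):
            dk = int(self.d[k])
            if self.ties == "efron":
                frac = np.arange(dk) / dk
            else:  # breslow: no tie correction
                frac = np.zeros(dk)
            denom = S0[k] - frac * s0D[k]  # (dk,)
            ll -= float(np.sum(np.log(denom))) + dk * shift
            if not want_derivs:
                continue
            num1 = S1[k][None, :] - frac[:, None] * s1D[k][None, :]  # (dk, p)
            mean = num1 / denom[:, None]
            score -= mean.sum(axis=0)
            num2 = S2[k][None, :, :] - frac[:, None, None] * s2D[k][None, :, :]
            info += (num2 / denom[:, None, None]).sum(axis=0)
            info -= np.einsum("lj,lk->jk", mean, mean)
        return ll, score, info


def _newton_raphson(pl, p, tol_ll=1e-9, tol_score=1e-6, max_iter=50):
    beta = np.zeros(p)
    ll, score, info = pl.loglik_score_info(beta)
    ll_null = ll
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular information matrix", beta, ll)
        # step-halving: never accept a decrease in the partial log-likelihood
        # (tolerance is relative: at large |ll| roundoff noise exceeds any
        # absolute epsilon)
        slack = 1e-10 * (abs(ll) + 1.0)
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, score_new, info_new = pl.loglik_score_info(cand)
            if np.isfinite(ll_new) and ll_new >= ll - slack:
                break
            factor /= 2.0
        else:
            if np.max(np.abs(score)) < tol_score:
                return beta, ll, ll_null, info, it, True
            raise ConvergenceError("step-halving failed to improve", beta, ll)
        rel = abs(ll_new - ll) / (abs(ll) + 1.0)
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if rel < tol_ll and np.max(np.abs(score)) < tol_score:
            return beta, ll, ll_null, info, it, True
    raise ConvergenceError(f"no convergence in {max_iter} iterations", beta, ll)


def fit(
    pp: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    basis: SplineBasis | None = None,
) -> HazardModelFit:
    """Maximum partial likelihood on the at-risk person-period rows.

    Parameters
    ----------
    pp
        Person-period table (see :mod:`copdrisk.exposure`); only rows with
        ``at_risk == 1`` contribute.
    spec
        Covariate set and ties method.
    basis
        Optional pre-built spline basis.  By default knots are placed from
        the at-risk event ages of ``pp`` and stored in the fit, so that
        predictions never recompute knots.
    """
    rows = pp[pp["at_risk"] == 1]
    n_events = int(rows["event"].sum())
    if n_events < 1:
        raise ValueError("no events among at-risk rows")
    X, basis = build_design(rows, spec, basis)
    # reject collinear designs up front, naming the offending columns
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, R = np.linalg.qr(X - X.mean(axis=0))
        diag = np.abs(np.diag(R))
        bad = [spec.covariates[j] for j in np.where(diag <= 1e-8 * max(diag.max(), 1))[0]]
        if not bad:
            bad = list(spec.covariates)
        raise RankDeficientError(bad)
    pl = _PartialLikelihood(
        rows["age_start"].to_numpy(float),
        rows["age_stop"].to_numpy(float),
        rows["event"].to_numpy(bool),
        X,
        ties=spec.ties,
    )
    beta, ll, ll_null, info, iters, ok = _newton_raphson(pl, X.shape[1])
    vcov = np.linalg.inv(info)
    vcov = (vcov + vcov.T) / 2.0
    names = list(spec.covariates)
    return HazardModelFit(
        spec=spec,
        beta=pd.Series(beta, index=names),
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        loglik=ll,
        loglik_null=ll_null,
        n_events=n_events,
        n_at_risk_rows=len(rows),
        converged=ok,
        iterations=iters,
        spline_basis=basis,
    )


def linear_predictor(fit_: HazardModelFit, rows: pd.DataFrame) -> np.ndarray:
    """``beta . X(t)`` per row; ``exp`` of it is the hazard ratio against the
    all-zero reference profile (male never smoker)."""
    if fit_.spec.needs_basis and fit_.spline_basis is None:
        raise ValueError("fit has spline columns but no serialized basis")
    X, _ = build_design(rows, fit_.spec, fit_.spline_basis)
    return X @ fit_.beta.to_numpy()


def lr_test(fit_full: HazardModelFit, fit_nested: HazardModelFit):
    """Likelihood-ratio test of nested covariate sets fitted to the same rows.

    Returns ``(statistic, df, p)``.
    """
    full = set(fit_full.spec.covariates)
    nested = set(fit_nested.spec.covariates)
    if not nested <= full:
        raise ValueError("models are not nested")
    if fit_full.n_at_risk_rows != fit_nested.n_at_risk_rows:
        raise ValueError("fits must use the same person-period rows")
    df = len(full) - len(nested)
    statistic = max(2.0 * (fit_full.loglik - fit_nested.loglik), 0.0)
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return statistic, df, p
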