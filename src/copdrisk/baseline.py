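"""Log-normal baseline hazard estimated from never smokers.

The absolute-risk engine needs the baseline hazard ``lambda0(t)`` for the
all-zero covariate profile (male never smoker).  It is modelled
parametrically: age at diagnosis among never smokers follows a log-normal
distribution, ``ln T ~ N(mu, sigma^2)``, fitted by maximum likelihood with
right censoring.  Because subjects enter the cohort in mid-life, the
default likelihood also conditions on being event-free at the entry age
(left truncation); ``truncation_mode="none"`` reproduces the plain
censored-MLE behaviour, which is biased under heavy delayed entry.

Most of the log-normal mass may sit far beyond human ages: the
distribution is a hazard-shape device, not a claim that everyone is
eventually diagnosed.  Only the hazard over observed ages matters
downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["BaselineHazard", "fit_baseline", "never_smoker_times", "hazard_at"]


@dataclass(frozen=True)
class BaselineHazard:
    """Log-normal baseline hazard on the age scale.

    ``mu`` and ``sigma`` are the location/scale of ``ln(age at onset)``;
    survival is ``S0(t) = 1 - Phi((ln t - mu)/sigma)`` and the hazard is
    ``f0(t)/S0(t)``, positive and finite for all ``t > 0``.
    """

    mu: float
    sigma: float
    truncation_mode: str = "left_truncated"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.truncation_mode not in ("none", "left_truncated"):
            raise ValueError(f"unknown truncation_mode {self.truncation_mode!r}")

    def _z(self, age):
        age = np.asarray(age, dtype=float)
        if np.any(age <= 0):
            raise ValueError("age must be positive")
        return (np.log(age) - self.mu) / self.sigma

    def log_survival(self, age):
        """``ln S0(t)``, computed via the stable normal log-sf."""
        return stats.norm.logsf(self._z(age))

    def survival(self, age):
        return np.exp(self.log_survival(age))

    def cumulative_hazard(self, age):
        return -self.log_survival(age)

    def hazard(self, age):
        """Per-year hazard ``lambda0(t) = phi(z) / (sigma * t * (1 - Phi(z)))``."""
        z = self._z(age)
        age = np.asarray(age, dtype=float)
        log_h = stats.norm.logpdf(z) - np.log(self.sigma) - np.log(age) - stats.norm.logsf(z)
        return np.exp(log_h)

    def to_dict(self) -> dict:
        return {
            "family": "lognormal",
            "mu": self.mu,
            "sigma": self.sigma,
            "truncation_mode": self.truncation_mode,
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaselineHazard":
        return cls(
            mu=float(d["mu"]),
            sigma=float(d["sigma"]),
            truncation_mode=d.get("truncation_mode", "left_truncated"),
            meta=d.get("meta", {}),
        )


def hazard_at(b: BaselineHazard, age):
    """Convenience alias for ``b.hazard(age)``."""
    return b.hazard(age)


def never_smoker_times(pp: pd.DataFrame) -> pd.DataFrame:
    """Collapse person-period rows to per-subject times for baseline fitting.

    A "never smoker" is a subject whose every at-risk row has status
    ``never``.  Returns one row per such subject with ``entry`` (first
    at-risk age), ``time`` (last at-risk age reached) and ``event``.
    """
    at_risk = pp[pp["at_risk"] == 1]
    if at_risk.empty:
        raise ValueError("person-period table has no at-risk rows")
    g = at_risk.groupby("subject_id", sort=False)
    never = g["status"].agg(lambda s: (s == "never").all())
    tab = pd.DataFrame(
        {
            "entry": g["age_start"].min(),
            "time": g["age_stop"].max(),
            "event": g["event"].max(),
            "sex_female": g["sex_female"].first(),
        }
    )
    return tab[never.to_numpy()].reset_index()


def fit_baseline(
    pp: pd.DataFrame,
    truncation_mode: str = "left_truncated",
    female_log_hr: float | None = None,
    init: tuple[float, float] | None = None,
) -> BaselineHazard:
    """Censored log-normal MLE of the never-smoker baseline hazard.

    Maximizes ``sum_events ln f(t_i) + sum_censored ln S(t_i)`` and, in
    ``left_truncated`` mode, subtracts ``sum_i ln S(entry_i)`` so the
    likelihood conditions on each subject being event-free at study entry.

    Parameters
    ----------
    pp
        Person-period table; never smokers are selected internally.
    truncation_mode
        ``"left_truncated"`` (default, correct for delayed entry) or
        ``"none"`` (plain censored MLE, as when the entry condition is
        ignored).
    female_log_hr
        Optional fixed log hazard ratio applied to female never smokers
        (the sex coefficient of the fitted relative-hazard model).  The
        baseline profile is the *male* never smoker; pooling both sexes
        without this offset inflates ``lambda0`` by the female excess.
        ``None`` pools the sexes as-is.

    Notes
    -----
    Person-period outcomes are recorded at year ends, so an "event at age
    ``t``" really means an event somewhere in ``(t-1, t]``.  The fit
    therefore uses the interval-censored likelihood contribution
    ``S(t-1) - S(t)`` for events; evaluating the exact-time density at the
    rounded-up age instead would bias the hazard shape.
    """
    tab = never_smoker_times(pp)
    offset = None
    if female_log_hr is not None:
        offset = female_log_hr * tab["sex_female"].to_numpy(float)
    return fit_lognormal(
        time=tab["time"].to_numpy(float),
        event=tab["event"].to_numpy(bool),
        entry=tab["entry"].to_numpy(float),
        truncation_mode=truncation_mode,
        log_offset=offset,
        likelihood="interval",
        init=init,
    )


def _numeric_se(negll, x):
    """Wald SEs from a central-difference Hessian of the negative log-likelihood."""
    h = 1e-4
    p = len(x)
    H = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.eye(p)[i] * h
            ej = np.eye(p)[j] * h
            H[i, j] = H[j, i] = (
                negll(x + ei + ej) - negll(x + ei - ej) - negll(x - ei + ej) + negll(x - ei - ej)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return float(se[0]), float(se[1])


def fit_lognormal(
    time,
    event,
    entry=None,
    truncation_mode: str = "left_truncated",
    log_offset=None,
    likelihood: str = "exact",
    init: tuple[float, float] | None = None,
) -> BaselineHazard:
    """Low-level censored (optionally left-truncated) log-normal MLE.

    ``log_offset`` gives each subject a fixed proportional-hazards tilt
    ``c_i = exp(offset_i)``: survival becomes ``S0(t)^{c_i}`` and the event
    density ``c_i lambda0(t) S0(t)^{c_i}``, so the estimated ``(mu, sigma)``
    describe the offset-zero reference profile.

    ``likelihood="exact"`` uses the event-time density ``f(t)`` (times
    recorded exactly); ``"interval"`` treats an event time ``t`` as "event
    within ``(t-1, t]``" and uses ``S(t-1)^c - S(t)^c``, appropriate for
    annual year-end-coded data.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=bool)
    if t.size == 0 or not np.any(d):
        raise ValueError("need at least one event to fit the baseline")
    if np.any(t <= 0):
        raise ValueError("event/censoring times must be positive")
    truncate = truncation_mode == "left_truncated"
    if truncation_mode not in ("none", "left_truncated"):
        raise ValueError(f"unknown truncation_mode {truncation_mode!r}")
    if truncate:
        if entry is None:
            raise ValueError("left_truncated mode requires entry ages")
        a = np.asarray(entry, dtype=float)
    if likelihood not in ("exact", "interval"):
        raise ValueError(f"unknown likelihood {likelihood!r}")
    c = np.ones(t.size) if log_offset is None else np.exp(np.asarray(log_offset, dtype=float))
    logt = np.log(t)
    if likelihood == "interval" and np.any(t[d] <= 1):
        raise ValueError("interval likelihood needs event times > 1 year")

    def negll(theta):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        z = (logt - mu) / sigma
        logS = stats.norm.logsf(z)
        if likelihood == "exact":
            # events: ln c + ln f(t) + (c-1) ln S0(t)
            ll = np.sum(
                np.log(c[d]) + stats.norm.logpdf(z[d]) - log_sigma - logt[d]
                + (c[d] - 1.0) * logS[d]
            )
        else:
            # events in (t-1, t]: ln( S(t-1)^c - S(t)^c )
            za_ev = (np.log(t[d] - 1.0) - mu) / sigma
            lsa = c[d] * stats.norm.logsf(za_ev)
            lsb = c[d] * logS[d]
            ll = np.sum(lsa + np.log1p(-np.exp(np.minimum(lsb - lsa, -1e-12))))
        ll += np.sum(c[~d] * logS[~d])  # censored: c ln S0(t)
        if truncate:
            za = (np.log(a) - mu) / sigma
            ll -= np.sum(c * stats.norm.logsf(za))
        return -ll

    if init is None:
        # moment start from event times (crude but inside the basin)
        init = (float(np.mean(logt[d])), float(np.std(logt[d]) + 0.05))
    x0 = np.array([init[0], np.log(init[1])])
    res = optimize.minimize(negll, x0, method="BFGS", options={"gtol": 1e-8, "maxiter": 500})
    # acceptably flat gradient scales with the likelihood magnitude
    grad_tol = 1e-4 * max(1.0, abs(float(res.fun)))
    if not res.success and np.max(np.abs(res.jac)) > grad_tol:
        # BFGS can stall on the flat truncated-likelihood ridge; polish with
        # a derivative-free restart before giving up
        res2 = optimize.minimize(
            negll, res.x, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if res2.fun <= res.fun:
            res2.jac = optimize.approx_fprime(res2.x, negll, 1e-6)
            res = res2
        if np.max(np.abs(res.jac)) > grad_tol:
            raise RuntimeError(
                f"baseline MLE did not converge: {res.message}; last iterate "
                f"mu={res.x[0]:.4f} sigma={np.exp(res.x[1]):.4f}"
            )
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    se_mu, se_sigma = _numeric_se(negll, res.x)
    n_events = int(d.sum())
    meta = {
        "n_subjects": int(t.size),
        "n_events": n_events,
        "loglik": float(-res.fun),
        "converged": bool(res.success) or float(np.max(np.abs(res.jac))) < grad_tol,
        "se_mu": se_mu,
        "se_sigma": se_sigma * sigma,  # delta method from log-sigma scale
    }
    if n_events < 5:
        warnings.warn(
            f"baseline fitted on only {n_events} events; estimates are fragile",
            stacklevel=2,
        )
        meta["few_events"] = True
    return BaselineHazard(mu=mu, sigma=sigma, truncation_mode=truncation_mode, meta=meta)
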