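"""Calibration and discrimination of a fitted bundle on held-out data.

Calibration compares observed event counts with model-expected counts
(sum of predicted annual hazards over at-risk person-years) within
sex x smoking-status x age-band strata, with exact Poisson bands and a
Poisson-deviance goodness-of-fit statistic.  Discrimination scores every
validation subject with their 6-year risk at the start of the observation
window -- smoking behaviour held to its baseline state, exposures accruing
-- and summarizes with the Mann-Whitney AUC, bootstrap CIs, and a paired
bootstrap test for the AUC difference between two models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .risk import PredictionBundle

__all__ = [
    "CalibrationReport",
    "DiscriminationReport",
    "calibrate",
    "auc_6yr",
    "compare_models",
    "mann_whitney_auc",
]


@dataclass
class CalibrationReport:
    strata: pd.DataFrame  # per-stratum observed/expected incidence
    deviance: float
    df: int
    p: float
    expected_total: float
    observed_total: int


@dataclass
class DiscriminationReport:
    """Per-sex AUCs plus the per-subject scores backing them."""

    table: pd.DataFrame  # group, auc, ci_lo, ci_hi, n_cases, n_controls
    subjects: pd.DataFrame  # subject_id, sex_female, score, label
    model_label: str = ""
    horizon: int = 6


def _row_hazards(bundle: PredictionBundle, rows: pd.DataFrame) -> np.ndarray:
    """Predicted annual hazard for each person-period row (interval-start
    covariates and baseline age)."""
    lp = bundle.linear_predictor(
        rows["age_start"].to_numpy(float),
        rows["sex_female"].to_numpy(float),
        rows["duration"].to_numpy(float),
        rows["pack_years"].to_numpy(float),
        rows["ysq"].to_numpy(float),
    )
    return bundle.baseline.hazard(rows["age_start"].to_numpy(float)) * np.exp(lp)


def calibrate(
    bundle: PredictionBundle,
    pp_validate: pd.DataFrame,
    age_band: int = 5,
) -> CalibrationReport:
    """Observed vs expected incidence by sex, smoking status and age band.

    Expected counts are sums of predicted hazards over the same at-risk
    person-period rows that produce the observed counts, so the totals obey
    the bookkeeping identity ``sum(expected) == sum(row hazards)`` exactly.
    Strata with no person-time simply do not appear.
    """
    rows = pp_validate[pp_validate["at_risk"] == 1].copy()
    if rows.empty:
        raise ValueError("no at-risk rows in the validation table")
    rows["hazard"] = _row_hazards(bundle, rows)
    band_lo = (rows["age_start"] // age_band * age_band).astype(int)
    rows["age_band"] = band_lo.astype(str) + "-" + (band_lo + age_band - 1).astype(str)
    g = rows.groupby(["sex_female", "status", "age_band"], observed=True)
    out = g.agg(
        person_years=("at_risk", "size"),
        observed=("event", "sum"),
        expected=("hazard", "sum"),
    ).reset_index()
    # exact Poisson band on the expected count, reported per 100k person-years
    alpha = 0.05
    lo = stats.chi2.ppf(alpha / 2, 2 * out["expected"]) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (out["expected"] + 1)) / 2
    out["obs_per_100k"] = 1e5 * out["observed"] / out["person_years"]
    out["exp_per_100k"] = 1e5 * out["expected"] / out["person_years"]
    out["band_lo_per_100k"] = 1e5 * np.nan_to_num(lo) / out["person_years"]
    out["band_hi_per_100k"] = 1e5 * hi / out["person_years"]

    obs = out["observed"].to_numpy(float)
    exp = out["expected"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = 2 * (np.where(obs > 0, obs * np.log(obs / exp), 0.0) - (obs - exp))
    deviance = float(dev_terms.sum())
    df = len(out)
    return CalibrationReport(
        strata=out,
        deviance=deviance,
        df=df,
        p=float(stats.chi2.sf(deviance, df)),
        expected_total=float(exp.sum()),
        observed_total=int(obs.sum()),
    )


def _baseline_snapshot(cohort: pd.DataFrame, baseline_age: np.ndarray):
    """Smoking state at each subject's baseline age: status code
    (0 never / 1 current / 2 former), duration, pack-years, ysq, current CPD."""
    from .io import parse_episodes

    n = len(cohort)
    dur = np.zeros(n)
    py = np.zeros(n)
    ysq = np.zeros(n)
    code = np.zeros(n, dtype=int)
    cpd_now = np.zeros(n)
    from .exposure import cpd_from_category

    for i, (a0, eps) in enumerate(zip(baseline_age, cohort["episodes"])):
        if isinstance(eps, str):
            eps = parse_episodes(eps)
        last_quit = -np.inf
        for s, e, cat in eps:
            cpd = cpd_from_category(cat)
            end = np.inf if e is None else float(e)
            years = min(a0, end) - s
            if years > 0:
                dur[i] += years
                py[i] += years * cpd / 20.0
            if s <= a0 < end:
                code[i] = 1
                cpd_now[i] = cpd
            elif end <= a0:
                last_quit = max(last_quit, end)
        if code[i] == 0 and last_quit > -np.inf:
            code[i] = 2
            ysq[i] = a0 - last_quit
    return code, dur, py, ysq, cpd_now


def six_year_scores(
    bundle: PredictionBundle,
    cohort: pd.DataFrame,
    window: tuple[int, int],
    horizon: int = 6,
) -> pd.DataFrame:
    """Risk scores and outcome labels at the start of the observation window.

    Baseline age is the later of study entry and the window start.  Smoking
    behaviour is held at its baseline state over the horizon: current
    smokers keep accruing duration and pack-years at their current CPD,
    former smokers accrue years-since-quit, never smokers stay at zero.
    The label is a diagnosis within ``horizon`` years of baseline;
    ``followup_end`` records the subject's outcome age and type so callers
    can apply censoring rules.
    """
    base_age = np.maximum(
        cohort["entry_age"].to_numpy(float),
        window[0] - cohort["birth_year"].to_numpy(float),
    )
    alive = cohort["outcome_age"].to_numpy(float) > base_age
    sub = cohort[alive].reset_index(drop=True)
    base_age = base_age[alive]
    code, dur0, py0, ysq0, cpd_now = _baseline_snapshot(sub, base_age)

    off = np.arange(horizon, dtype=float)[None, :]
    ages = base_age[:, None] + off
    is_cur = (code == 1)[:, None]
    is_for = (code == 2)[:, None]
    dur = dur0[:, None] + np.where(is_cur, off, 0.0)
    py = py0[:, None] + np.where(is_cur, off * cpd_now[:, None] / 20.0, 0.0)
    ysq = np.where(is_for, ysq0[:, None] + off, 0.0)
    lp = bundle.linear_predictor(
        ages, sub["sex_female"].to_numpy(float)[:, None], dur, py, ysq
    )
    h = bundle.baseline.hazard(ages) * np.exp(lp)
    score = -np.expm1(-h.sum(axis=1))

    out_age = sub["outcome_age"].to_numpy(float)
    label = (sub["outcome"] == "copd").to_numpy() & (out_age <= base_age + horizon)
    return pd.DataFrame(
        {
            "subject_id": sub["subject_id"],
            "sex_female": sub["sex_female"],
            "score": score,
            "label": label.astype(int),
            "outcome": sub["outcome"],
            "outcome_age": out_age,
            "baseline_age": base_age,
        }
    )


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney U statistic (midranks for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs at least one case and one control")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _auc_with_ci(sub: pd.DataFrame, n_boot: int, rng) -> tuple[float, float, float]:
    auc = mann_whitney_auc(sub["score"], sub["label"])
    sims = []
    n = len(sub)
    s = sub["score"].to_numpy()
    l = sub["label"].to_numpy()
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if l[idx].sum() in (0, n):
            continue
        sims.append(mann_whitney_auc(s[idx], l[idx]))
    lo, hi = np.quantile(sims, [0.025, 0.975])
    return auc, min(float(lo), auc), max(float(hi), auc)


def auc_6yr(
    bundle: PredictionBundle,
    cohort_validate: pd.DataFrame,
    window: tuple[int, int],
    horizon: int = 6,
    n_boot: int = 100,
    seed: int = 0,
    dropouts_as_controls: bool = True,
    model_label: str = "",
) -> DiscriminationReport:
    """Six-year-risk discrimination on a held-out cohort, overall and per sex.

    Subjects who die or are lost before the horizon without a diagnosis
    count as controls by default; ``dropouts_as_controls=False`` excludes
    them instead.
    """
    subj = six_year_scores(bundle, cohort_validate, window, horizon)
    if not dropouts_as_controls:
        dropped = (
            (subj["label"] == 0)
            & (subj["outcome"] != "copd")
            & (subj["outcome_age"] < subj["baseline_age"] + horizon)
        )
        subj = subj[~dropped].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    rows = []
    for group, sel in [
        ("all", np.ones(len(subj), dtype=bool)),
        ("female", subj["sex_female"].to_numpy() == 1),
        ("male", subj["sex_female"].to_numpy() == 0),
    ]:
        sub = subj[sel]
        if sub.empty or sub["label"].nunique() < 2:
            continue
        auc, lo, hi = _auc_with_ci(sub, n_boot, rng)
        rows.append(
            {
                "group": group,
                "auc": auc,
                "ci_lo": lo,
                "ci_hi": hi,
                "n_cases": int(sub["label"].sum()),
                "n_controls": int((1 - sub["label"]).sum()),
            }
        )
    return DiscriminationReport(
        table=pd.DataFrame(rows), subjects=subj, model_label=model_label, horizon=horizon
    )


def compare_models(
    report_a: DiscriminationReport,
    report_b: DiscriminationReport,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired bootstrap of the AUC difference (model a minus model b).

    Both reports must score the identical subjects; resampling indices are
    shared between models so the comparison is paired.  The two-sided p is
    the bootstrap sign probability, 1.0 when the scores are identical.
    """
    a, b = report_a.subjects, report_b.subjects
    if not np.array_equal(a["subject_id"].to_numpy(), b["subject_id"].to_numpy()):
        raise ValueError("reports score different subjects; cannot pair")
    if not np.array_equal(a["label"].to_numpy(), b["label"].to_numpy()):
        raise ValueError("reports disagree on outcome labels")
    rng = np.random.default_rng(seed)
    rows = []
    for group, sel in [
        ("all", np.ones(len(a), dtype=bool)),
        ("female", a["sex_female"].to_numpy() == 1),
        ("male", a["sex_female"].to_numpy() == 0),
    ]:
        sa, sb = a[sel], b[sel]
        if sa.empty or sa["label"].nunique() < 2:
            continue
        d_obs = mann_whitney_auc(sa["score"], sa["label"]) - mann_whitney_auc(
            sb["score"], sb["label"]
        )
        n = len(sa)
        s_a, s_b, l = sa["score"].to_numpy(), sb["score"].to_numpy(), sa["label"].to_numpy()
        deltas = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if l[idx].sum() in (0, n):
                continue
            deltas.append(mann_whitney_auc(s_a[idx], l[idx]) - mann_whitney_auc(s_b[idx], l[idx]))
        deltas = np.asarray(deltas)
        B = len(deltas)
        p = min(1.0, 2 * min((1 + (deltas <= 0).sum()) / (B + 1), (1 + (deltas >= 0).sum()) / (B + 1)))
        rows.append({"group": group, "delta_auc": d_obs, "p": p, "n_boot": B})
    return pd.DataFrame(rows)
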