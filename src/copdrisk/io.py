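"""Plain-text file formats: cohort CSV, person-period CSV, life-table CSV,
and JSON artifacts for fitted models.

Everything round-trips exactly (episodes through their serialized string
form, model fits through JSON) and malformed inputs are rejected with the
offending row named rather than silently dropped.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .baseline import BaselineHazard
from .coxtv import HazardModelFit, ModelSpec
from .exposure import PP_COLUMNS, cpd_from_category
from .lifetable import LifeTable, STATUSES
from .splines import SplineBasis

__all__ = [
    "serialize_episodes",
    "parse_episodes",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_pp_csv",
    "read_pp_csv",
    "write_life_table_csv",
    "read_life_table_csv",
    "write_fit_json",
    "read_fit_json",
    "write_baseline_json",
    "read_baseline_json",
]

COHORT_COLUMNS = [
    "subject_id",
    "sex_female",
    "birth_year",
    "entry_age",
    "episodes",
    "outcome",
    "outcome_age",
]
OUTCOMES = ("copd", "death", "lost", "admin_censor")


def serialize_episodes(episodes) -> str:
    """``start:end:category`` triples joined by ``;``; empty end = ongoing."""
    parts = []
    for s, e, cat in episodes:
        cpd_from_category(cat)  # validates the label
        end = "" if e is None or (isinstance(e, float) and np.isinf(e)) else f"{e:g}"
        parts.append(f"{s:g}:{end}:{cat}")
    return ";".join(parts)


def parse_episodes(text: str):
    """Inverse of :func:`serialize_episodes`."""
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return []
    episodes = []
    for part in str(text).split(";"):
        fields = part.split(":")
        if len(fields) != 3:
            raise ValueError(f"malformed episode {part!r}; expected start:end:category")
        s, e, cat = fields
        cpd_from_category(cat)
        episodes.append((float(s), float(e) if e != "" else None, cat))
    return episodes


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    out["episodes"] = [serialize_episodes(eps) for eps in out["episodes"]]
    out[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"episodes": "string"})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {sorted(missing)}")
    bad = ~df["outcome"].isin(OUTCOMES)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]  # 1-based incl. header
        raise ValueError(f"invalid outcome labels at lines {rows} of {path}")
    episodes = []
    for i, text in enumerate(df["episodes"]):
        try:
            episodes.append(parse_episodes(text if not pd.isna(text) else ""))
        except ValueError as err:
            raise ValueError(f"line {i + 2} of {path}: {err}") from None
    df = df.drop(columns="episodes")
    df["episodes"] = episodes
    return df[COHORT_COLUMNS]


def write_pp_csv(pp: pd.DataFrame, path) -> None:
    pp[PP_COLUMNS].to_csv(path, index=False)


def read_pp_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"person-period file {path} missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["subject_id", "age_start"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:5]
        raise ValueError(f"duplicate (subject_id, age_start) keys at lines {rows} of {path}")
    return df[PP_COLUMNS]


def write_life_table_csv(lt: LifeTable, path) -> None:
    lt.table[["age", "status", "q_annual"]].to_csv(path, index=False)


def read_life_table_csv(path) -> LifeTable:
    df = pd.read_csv(path)
    missing = {"age", "status", "q_annual"} - set(df.columns)
    if missing:
        raise ValueError(f"life table {path} missing columns: {sorted(missing)}")
    unknown = set(df["status"].unique()) - set(STATUSES)
    if unknown:
        raise ValueError(f"life table {path} has unknown statuses: {sorted(unknown)}")
    return LifeTable(df)


def write_fit_json(fit: HazardModelFit, path) -> None:
    payload = {
        "spec": {"covariates": list(fit.spec.covariates), "ties": fit.spec.ties},
        "beta": {k: float(v) for k, v in fit.beta.items()},
        "vcov": fit.vcov.values.tolist(),
        "loglik": fit.loglik,
        "loglik_null": fit.loglik_null,
        "n_events": fit.n_events,
        "n_at_risk_rows": fit.n_at_risk_rows,
        "converged": fit.converged,
        "iterations": fit.iterations,
        "spline_basis": None if fit.spline_basis is None else fit.spline_basis.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fit_json(path) -> HazardModelFit:
    d = json.loads(Path(path).read_text())
    names = list(d["beta"])
    return HazardModelFit(
        spec=ModelSpec(covariates=tuple(d["spec"]["covariates"]), ties=d["spec"]["ties"]),
        beta=pd.Series(d["beta"]),
        vcov=pd.DataFrame(np.asarray(d["vcov"]), index=names, columns=names),
        loglik=d["loglik"],
        loglik_null=d["loglik_null"],
        n_events=d["n_events"],
        n_at_risk_rows=d["n_at_risk_rows"],
        converged=d["converged"],
        iterations=d["iterations"],
        spline_basis=None
        if d["spline_basis"] is None
        else SplineBasis.from_dict(d["spline_basis"]),
    )


def write_baseline_json(b: BaselineHazard, path) -> None:
    Path(path).write_text(json.dumps(b.to_dict(), indent=1))


def read_baseline_json(path) -> BaselineHazard:
    return BaselineHazard.from_dict(json.loads(Path(path).read_text()))
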