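"""Annual person-period expansion of episodic smoking histories.

Lifetime smoking is recorded as episodes ``(start_age, end_age | ongoing,
CPD category)``.  The hazard model needs covariates on an annual grid, so
each subject is expanded to one row per integer year of age from birth to
the end of follow-up, in counting-process form: half-open intervals
``[a, a+1)`` with the event attributed to the interval whose endpoint is
the (year-end) outcome age.

Covariates are left-continuous: the values driving the hazard over
``[a, a+1)`` are the exposures accumulated strictly before age ``a``, so
same-interval exposure never post-dates the event it explains.  Rows before
study entry or before the observation window are emitted but flagged
``at_risk = 0``; the fitter uses only at-risk rows (left truncation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "CPD_CATEGORIES",
    "CPD_MIDPOINTS",
    "cpd_from_category",
    "accumulate_pack_years",
    "expand",
    "expand_cohort",
    "PP_COLUMNS",
]

#: intensity categories as collected on the questionnaires, with the
#: category mid-point used as the working cigarettes-per-day value
#: (the open-ended category is coded 50 CPD).
CPD_CATEGORIES = ("0-4", "5-14", "15-24", "25-34", "35-44", "45+")
CPD_MIDPOINTS = {
    "0-4": 2.0,
    "5-14": 9.5,
    "15-24": 19.5,
    "25-34": 29.5,
    "35-44": 39.5,
    "45+": 50.0,
}

PP_COLUMNS = [
    "subject_id",
    "age_start",
    "age_stop",
    "at_risk",
    "event",
    "sex_female",
    "status",
    "duration",
    "pack_years",
    "ysq",
]


def cpd_from_category(category: str) -> float:
    """Cigarettes per day for a reported intensity category (mid-point coding)."""
    key = str(category).replace("–", "-").strip()
    try:
        return CPD_MIDPOINTS[key]
    except KeyError:
        raise ValueError(
            f"unknown CPD category {category!r}; expected one of {CPD_CATEGORIES}"
        ) from None


def _episode_arrays(episodes):
    """Validate and unpack episodes into (start, end, cpd) float arrays.

    ``episodes`` is an iterable of ``(start_age, end_age | None, category)``;
    ``None`` (or ``inf``) marks a still-ongoing episode.
    """
    starts, ends, cpds = [], [], []
    prev_end = -np.inf
    for ep in episodes:
        s, e, cat = ep
        e = np.inf if e is None else float(e)
        s = float(s)
        if not s < e:
            raise ValueError(f"episode start {s} must precede end {e}")
        if s < prev_end:
            raise ValueError("episodes overlap or are out of order")
        prev_end = e
        starts.append(s)
        ends.append(e)
        cpds.append(cpd_from_category(cat))
    return np.asarray(starts), np.asarray(ends), np.asarray(cpds)


def accumulate_pack_years(episodes, age) -> float | np.ndarray:
    """Cumulative pack-years smoked strictly before ``age``.

    Each episode-year contributes CPD/20; the sum is piecewise linear in
    age within episodes.  Never smokers (no episodes) get 0 at any age.
    """
    s, e, cpd = _episode_arrays(episodes)
    a = np.asarray(age, dtype=float)
    if s.size == 0:
        return np.zeros(a.shape) if a.ndim else 0.0
    years = np.clip(np.minimum(a[..., None], e) - s, 0.0, None)
    out = (years * cpd / 20.0).sum(axis=-1)
    return out if a.ndim else float(out)


def smoking_duration(episodes, age) -> float | np.ndarray:
    """Total years smoked strictly before ``age``."""
    s, e, _ = _episode_arrays(episodes)
    a = np.asarray(age, dtype=float)
    if s.size == 0:
        return np.zeros(a.shape) if a.ndim else 0.0
    years = np.clip(np.minimum(a[..., None], e) - s, 0.0, None)
    out = years.sum(axis=-1)
    return out if a.ndim else float(out)


def expand(history, window: tuple[int, int]) -> pd.DataFrame:
    """Expand one subject's history to annual person-period rows.

    ``history`` is a mapping with keys ``subject_id, sex_female, birth_year,
    entry_age, episodes, outcome, outcome_age``; ``window`` is the
    ``(start_year, end_year)`` observation window.  See
    :func:`expand_cohort` for the columns of the result.
    """
    df = pd.DataFrame([dict(history)])
    return expand_cohort(df, window)


def expand_cohort(cohort: pd.DataFrame, window: tuple[int, int]) -> pd.DataFrame:
    """Vectorized person-period expansion of a whole cohort.

    Parameters
    ----------
    cohort
        One row per subject: ``subject_id``, ``sex_female``, ``birth_year``,
        ``entry_age``, ``episodes`` (list of ``(start, end|None, category)``
        tuples, or the serialized ``start:end:cat;...`` string), ``outcome``
        (``copd``/``death``/``lost``/``admin_censor``), ``outcome_age``.
    window
        Calendar observation window ``(start_year, end_year)``; a row is
        at risk when its year lies in ``[start_year, end_year)`` and the
        subject has entered the study.

    Returns
    -------
    DataFrame with columns ``subject_id, age_start, age_stop, at_risk,
    event, sex_female, status, duration, pack_years, ysq``, one row per
    integer age ``[a, a+1)`` from birth to the outcome age, sorted by
    ``(subject_id, age_start)``.
    """
    from .io import parse_episodes  # serialized-string support

    n = len(cohort)
    outcome_age = np.ceil(cohort["outcome_age"].to_numpy(float)).astype(int)
    entry_age = cohort["entry_age"].to_numpy(float)
    if np.any(cohort["outcome_age"].to_numpy(float) < entry_age):
        bad = cohort.loc[cohort["outcome_age"].to_numpy(float) < entry_age, "subject_id"]
        raise ValueError(f"outcome before study entry for subjects {list(bad[:5])}")
    birth_year = cohort["birth_year"].to_numpy(int)
    sex_female = cohort["sex_female"].to_numpy(int)
    is_copd = (cohort["outcome"] == "copd").to_numpy()

    n_rows = np.maximum(outcome_age, 1)  # at least one row per subject
    row_subj = np.repeat(np.arange(n), n_rows)
    offsets = np.concatenate([[0], np.cumsum(n_rows)])
    age = np.arange(offsets[-1]) - np.repeat(offsets[:-1], n_rows)

    # unpack episodes; validate via the scalar path
    ep_subj, ep_s, ep_e, ep_cpd = [], [], [], []
    for i, eps in enumerate(cohort["episodes"]):
        if isinstance(eps, str):
            eps = parse_episodes(eps)
        s, e, cpd = _episode_arrays(eps)
        ep_subj.extend([i] * len(s))
        ep_s.extend(s)
        ep_e.extend(e)
        ep_cpd.extend(cpd)
    ep_subj = np.asarray(ep_subj, dtype=int)
    ep_s = np.asarray(ep_s)
    ep_e = np.asarray(ep_e)
    ep_cpd = np.asarray(ep_cpd)

    N = offsets[-1]
    duration = np.zeros(N)
    pack_years = np.zeros(N)
    n_current = np.zeros(N)
    last_quit = np.full(N, -np.inf)
    if len(ep_subj):
        # pair every episode with every person-period row of its subject
        pair_counts = n_rows[ep_subj]
        pair_row = (
            np.arange(pair_counts.sum())
            - np.repeat(np.cumsum(pair_counts) - pair_counts, pair_counts)
            + np.repeat(offsets[ep_subj], pair_counts)
        )
        a = age[pair_row].astype(float)
        s = np.repeat(ep_s, pair_counts)
        e = np.repeat(ep_e, pair_counts)
        cpd = np.repeat(ep_cpd, pair_counts)
        years = np.clip(np.minimum(a, e) - s, 0.0, None)
        np.add.at(duration, pair_row, years)
        np.add.at(pack_years, pair_row, years * cpd / 20.0)
        np.add.at(n_current, pair_row, ((s <= a) & (a < e)).astype(float))
        quit_seen = np.where(e <= a, e, -np.inf)
        np.maximum.at(last_quit, pair_row, quit_seen)

    current = n_current > 0
    former = (~current) & (last_quit > -np.inf)
    status = np.where(current, "current", np.where(former, "former", "never"))
    ysq = np.where(former, age - last_quit, 0.0)

    year = birth_year[row_subj] + age
    at_risk = (
        (age >= entry_age[row_subj])
        & (year >= window[0])
        & (year < window[1])
    ).astype(int)
    is_last = np.zeros(N, dtype=bool)
    is_last[offsets[1:] - 1] = True
    event = (is_last & is_copd[row_subj]).astype(int)

    pp = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy()[row_subj],
            "age_start": age,
            "age_stop": age + 1,
            "at_risk": at_risk,
            "event": event,
            "sex_female": sex_female[row_subj],
            "status": status,
            "duration": duration,
            "pack_years": pack_years,
            "ysq": ysq,
        }
    )
    return pp
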