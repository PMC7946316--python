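"""Calibration bookkeeping and AUC machinery on constructed cases."""

import numpy as np
import pandas as pd
import pytest

from copdrisk.baseline import BaselineHazard
from copdrisk.cohort import default_true_model
from copdrisk.coxtv import HazardModelFit, ModelSpec
from copdrisk.risk import PredictionBundle
from copdrisk.validate import (
    DiscriminationReport,
    calibrate,
    compare_models,
    mann_whitney_auc,
    six_year_scores,
)


def make_bundle(model=None):
    if model is None:
        model = default_true_model()
    names = list(model.beta)
    return PredictionBundle(
        fit=HazardModelFit(
            spec=ModelSpec(),
            beta=pd.Series(model.beta),
            vcov=pd.DataFrame(1e-6 * np.eye(len(names)), index=names, columns=names),
            loglik=0.0,
            loglik_null=0.0,
            n_events=1,
            n_at_risk_rows=1,
            converged=True,
            iterations=1,
            spline_basis=model.basis,
        ),
        baseline=model.baseline,
    )


def pp_rows(n_subjects=200, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        status = ["never", "current", "former"][i % 3]
        ev_last = rng.random() < 0.1
        for a in range(60, 65):
            rows.append(
                dict(
                    subject_id=i,
                    age_start=a,
                    age_stop=a + 1,
                    at_risk=1,
                    event=int(ev_last and a == 64),
                    sex_female=i % 2,
                    status=status,
                    duration=0.0 if status == "never" else 30.0,
                    pack_years=0.0 if status == "never" else 20.0,
                    ysq=10.0 if status == "former" else 0.0,
                )
            )
    return pd.DataFrame(rows)


def test_calibration_bookkeeping_identity():
    bundle = make_bundle()
    pp = pp_rows()
    rep = calibrate(bundle, pp)
    # expected total equals the sum of per-row predicted hazards exactly
    lp = bundle.linear_predictor(
        pp["age_start"].to_numpy(float),
        pp["sex_female"].to_numpy(float),
        pp["duration"].to_numpy(float),
        pp["pack_years"].to_numpy(float),
        pp["ysq"].to_numpy(float),
    )
    hazards = bundle.baseline.hazard(pp["age_start"].to_numpy(float)) * np.exp(lp)
    assert rep.expected_total == pytest.approx(hazards.sum(), rel=1e-12)
    assert rep.observed_total == int(pp["event"].sum())
    assert (rep.strata["person_years"] > 0).all()


def test_calibration_detects_doubled_hazard():
    pp = pp_rows(n_subjects=3000, seed=1)
    bundle = make_bundle()
    rep = calibrate(bundle, pp)
    doubled = make_bundle()
    doubled.fit.beta = bundle.fit.beta.copy()
    doubled.baseline = BaselineHazard(
        mu=bundle.baseline.mu - 2.0, sigma=bundle.baseline.sigma
    )  # much larger hazard level
    rep2 = calibrate(doubled, pp)
    assert rep2.expected_total > 2 * rep.expected_total
    assert rep2.deviance > rep.deviance


def test_empty_strata_absent():
    pp = pp_rows()
    rep = calibrate(make_bundle(), pp[pp["status"] != "former"])
    assert "former" not in set(rep.strata["status"])


def test_auc_perfect_separation_and_null():
    assert mann_whitney_auc([0.9] * 5 + [0.1] * 5, [1] * 5 + [0] * 5) == 1.0
    rng = np.random.default_rng(0)
    scores = rng.uniform(size=4000)
    labels = rng.integers(0, 2, size=4000)
    assert abs(mann_whitney_auc(scores, labels) - 0.5) < 0.03
    with pytest.raises(ValueError):
        mann_whitney_auc([0.5, 0.6], [1, 1])


def test_auc_agrees_with_sklearn():
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(5)
    scores = rng.uniform(size=300)
    labels = (rng.uniform(size=300) < scores).astype(int)
    assert mann_whitney_auc(scores, labels) == pytest.approx(
        sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12
    )


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(2)
    scores = rng.uniform(size=500)
    labels = (rng.uniform(size=500) < scores).astype(int)
    a = mann_whitney_auc(scores, labels)
    b = mann_whitney_auc(np.log(scores + 1e-9), labels)
    c = mann_whitney_auc(scores**3, labels)
    assert a == pytest.approx(b, abs=1e-12)
    assert a == pytest.approx(c, abs=1e-12)


def _report(subjects, label=""):
    return DiscriminationReport(table=pd.DataFrame(), subjects=subjects, model_label=label)


def test_compare_identical_scores_gives_zero_delta_and_p_one():
    subj = pd.DataFrame(
        {
            "subject_id": np.arange(40),
            "sex_female": np.tile([0, 1], 20),
            "score": np.linspace(0, 1, 40),
            "label": np.tile([0, 0, 0, 1], 10),
        }
    )
    comp = compare_models(_report(subj), _report(subj.copy()), n_boot=50, seed=1)
    row = comp[comp["group"] == "all"].iloc[0]
    assert row["delta_auc"] == 0.0
    assert row["p"] == 1.0


def test_compare_requires_same_subjects():
    subj = pd.DataFrame(
        {"subject_id": [1, 2, 3], "sex_female": [0, 0, 1], "score": [0.1, 0.2, 0.3],
         "label": [0, 1, 0]}
    )
    other = subj.copy()
    other["subject_id"] = [1, 2, 4]
    with pytest.raises(ValueError, match="different subjects"):
        compare_models(_report(subj), _report(other))


def test_paired_delta_on_handmade_subjects():
    """Five subjects where model A ranks the case top and model B ranks it
    bottom: exhaustive AUCs are 1 and 0, so the paired difference is 1."""
    subj_a = pd.DataFrame(
        {
            "subject_id": [1, 2, 3, 4, 5],
            "sex_female": [0] * 5,
            "score": [0.9, 0.1, 0.2, 0.3, 0.4],
            "label": [1, 0, 0, 0, 0],
        }
    )
    subj_b = subj_a.copy()
    subj_b["score"] = [0.05, 0.1, 0.2, 0.3, 0.4]
    comp = compare_models(_report(subj_a), _report(subj_b), n_boot=200, seed=3)
    row = comp[comp["group"] == "all"].iloc[0]
    assert row["delta_auc"] == pytest.approx(1.0)
    assert row["p"] < 0.05


def test_six_year_scores_labels_and_freeze_semantics():
    cohort = pd.DataFrame(
        [
            # diagnosed 4 years after window start -> case
            dict(subject_id=1, sex_female=1, birth_year=1934, entry_age=42,
                 episodes=[(20, None, "15-24")], outcome="copd", outcome_age=68),
            # diagnosed 8 years after window start -> beyond horizon, control
            dict(subject_id=2, sex_female=1, birth_year=1934, entry_age=42,
                 episodes=[], outcome="copd", outcome_age=72),
            # died before window start -> not scoreable, dropped
            dict(subject_id=3, sex_female=0, birth_year=1940, entry_age=46,
                 episodes=[], outcome="death", outcome_age=55),
        ]
    )
    scores = six_year_scores(make_bundle(), cohort, (1998, 2008), horizon=6)
    assert sorted(scores["subject_id"]) == [1, 2]
    assert scores.set_index("subject_id")["label"].to_dict() == {1: 1, 2: 0}
    # smoker scores above the never smoker of the same sex and age
    s = scores.set_index("subject_id")["score"]
    assert s[1] > s[2]
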