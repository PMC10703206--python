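"""Cox fitting: oracle agreement, invariances, robust variance, battery."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from pipcox.bleeding_detector import detect_bleedings
from pipcox.cox_analysis import (
    Z_95,
    default_plan,
    fit_cox,
    interaction_stratum_hrs,
    run_plan,
)
from pipcox.criteria_engine import evaluate_cohort_part1
from pipcox.ehr_model import DateInterval, PatientRecord
from pipcox.timesplit import ModelDataset, ModelSpec, assemble_model_dataset, build_rows
from pipcox._coxfit import efron_cox_fit

from cox_oracle import efron_loglik, maximize_efron, random_small_instance


def _dataset_from_frame(df, covs, tag="test"):
    from pipcox.timesplit import CountingProcessRow

    rows = [
        CountingProcessRow(
            r.cluster_id, int(r.t_start), int(r.t_stop), int(r.event),
            {c: float(getattr(r, c)) for c in covs},
        )
        for r in df.itertuples(index=False)
    ]
    return ModelDataset(rows, list(covs), tag)


def test_fitter_matches_partial_likelihood_oracle_on_small_instances():
    """Coefficients agree with brute-force maximization to 1e-6."""
    rng = np.random.default_rng(42)
    checked = 0
    for _ in range(25):
        df, covs = random_small_instance(rng)
        X = df[covs].to_numpy(float)
        if np.allclose(X.var(axis=0), 0):
            continue
        try:
            fit = efron_cox_fit(
                X, df["t_start"].to_numpy(float), df["t_stop"].to_numpy(float),
                df["event"].to_numpy(int), tol=1e-11,
            )
        except ValueError:
            continue
        if not fit.converged or np.any(np.abs(fit.beta) > 10):
            continue  # monotone instances are covered separately
        ref = maximize_efron(X, df["t_start"], df["t_stop"], df["event"], x0=fit.beta * 0.9)
        assert np.max(np.abs(fit.beta - ref)) < 1e-6
        checked += 1
    assert checked >= 12


def test_six_patient_toy_binary_covariate():
    """Classic textbook-sized example against the oracle."""
    df = pd.DataFrame(
        {
            "cluster_id": [f"P{i}" for i in range(6)],
            "t_start": [0, 0, 0, 0, 0, 0],
            "t_stop": [3, 5, 7, 2, 8, 9],
            "event": [1, 1, 0, 1, 1, 0],
            "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        }
    )
    ds = _dataset_from_frame(df, ["x"])
    res = fit_cox(ds, cluster=False, robust=False)
    ref = maximize_efron(df[["x"]].to_numpy(), df["t_start"], df["t_stop"], df["event"])
    assert res.covariate("x")["coef"] == pytest.approx(ref[0], abs=1e-6)


def test_symmetric_groups_give_zero_coefficient():
    """Identical event patterns in both groups: no association."""
    rows = []
    for g, x in (("a", 1.0), ("b", 0.0)):
        for i, (stop, ev) in enumerate([(3, 1), (5, 1), (7, 0), (9, 1)]):
            rows.append((f"{g}{i}", 0, stop, ev, x))
    df = pd.DataFrame(rows, columns=["cluster_id", "t_start", "t_stop", "event", "x"])
    res = fit_cox(_dataset_from_frame(df, ["x"]), cluster=False, robust=False)
    assert abs(res.covariate("x")["coef"]) < 1e-8


def test_split_invariance_of_estimates():
    """Splitting any row at a non-event time changes nothing (to 1e-8)."""
    rng = np.random.default_rng(9)
    df, covs = random_small_instance(rng, n_patients=8)
    ds = _dataset_from_frame(df, covs)
    base = fit_cox(ds, fit_options={"precision": 1e-11})

    split_rows = []
    for r in df.itertuples(index=False):
        if r.t_stop - r.t_start >= 2:
            mid = (r.t_start + r.t_stop) // 2
            a = r._asdict()
            b = r._asdict()
            a["t_stop"], a["event"] = mid, 0
            b["t_start"] = mid
            split_rows.extend([a, b])
        else:
            split_rows.append(r._asdict())
    df2 = pd.DataFrame(split_rows)
    res2 = fit_cox(_dataset_from_frame(df2, covs), fit_options={"precision": 1e-11})
    for c in covs:
        assert res2.covariate(c)["coef"] == pytest.approx(base.covariate(c)["coef"], abs=1e-8)
        assert res2.covariate(c)["robust_se"] == pytest.approx(
            base.covariate(c)["robust_se"], abs=1e-8
        )


def test_matches_lifelines_coefficients():
    """Independent library cross-check of the point estimates."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(21)
    df, covs = random_small_instance(rng, n_patients=10)
    ds = _dataset_from_frame(df, covs)
    res = fit_cox(ds, cluster=False, robust=False)
    cph = lifelines.CoxPHFitter()
    cph.fit(
        df[["t_start", "t_stop", "event"] + covs],
        duration_col="t_stop", entry_col="t_start", event_col="event",
    )
    for c in covs:
        assert res.covariate(c)["coef"] == pytest.approx(cph.params_[c], abs=1e-5)
        assert res.covariate(c)["robust_se"] == pytest.approx(
            cph.standard_errors_[c], abs=1e-4
        )


def test_frozen_r_survival_reference():
    """Coefficients and cluster-robust SEs equal R survival::coxph values.

    Reference values computed once with
    coxph(Surv(start,stop,event) ~ x + z + cluster(id), ties="efron")
    on this frozen fixture (R 4.3.3, survival 3.8-3).
    """
    df = pd.DataFrame(
        {
            "cluster_id": ["0", "0", "1", "2", "3", "4", "5", "5", "6", "7", "8", "9", "9", "10", "11", "11"],
            "t_start": [3, 9, 0, 0, 3, 0, 0, 2, 3, 0, 0, 3, 9, 0, 0, 6],
            "t_stop": [9, 14, 2, 2, 6, 6, 2, 3, 6, 4, 2, 8, 12, 7, 6, 8],
            "event": [0, 1, 1, 1, 1, 1, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0],
            "x": [1.0, 0.0, 0.0, 1.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 1.0],
            "z": [-0.248362, -0.552647, 1.634783, 1.600019, -1.163226, 0.553378,
                  0.829855, -0.980747, 0.020690, -0.396190, -1.109350, 0.043632,
                  -0.255790, 0.738042, 1.448731, 0.844993],
        }
    )
    res = fit_cox(_dataset_from_frame(df, ["x", "z"]))
    assert res.covariate("x")["coef"] == pytest.approx(0.5231549, abs=1e-6)
    assert res.covariate("z")["coef"] == pytest.approx(-0.3313543, abs=1e-6)
    assert res.covariate("x")["robust_se"] == pytest.approx(0.472684, abs=1e-5)
    assert res.covariate("z")["robust_se"] == pytest.approx(0.4486556, abs=1e-5)
    naive = fit_cox(_dataset_from_frame(df, ["x", "z"]), cluster=False, robust=False)
    assert naive.covariate("x")["robust_se"] == pytest.approx(0.7480483, abs=1e-5)
    assert naive.covariate("z")["robust_se"] == pytest.approx(0.4841203, abs=1e-5)


def test_summary_identities_hold_exactly():
    """HR, CI bounds and p recompute from coef and robust SE."""
    rng = np.random.default_rng(3)
    df, covs = random_small_instance(rng, n_patients=9)
    res = fit_cox(_dataset_from_frame(df, covs))
    from scipy import stats

    for c in covs:
        row = res.covariate(c)
        if not row["estimable"]:
            continue
        assert row["hazard_ratio"] == np.exp(row["coef"])
        assert row["ci95_low"] == np.exp(row["coef"] - Z_95 * row["robust_se"])
        assert row["ci95_high"] == np.exp(row["coef"] + Z_95 * row["robust_se"])
        assert row["p_value"] == 2 * stats.norm.sf(abs(row["coef"] / row["robust_se"]))


def test_zero_events_refused():
    df = pd.DataFrame(
        {"cluster_id": ["a", "b"], "t_start": [0, 0], "t_stop": [5, 6],
         "event": [0, 0], "x": [1.0, 0.0]}
    )
    with pytest.raises(ValueError, match="no events"):
        fit_cox(_dataset_from_frame(df, ["x"]))


def test_monotone_likelihood_flagged_not_crashed():
    """Events only in the unexposed group: exposure HR non-estimable."""
    rows = []
    for i in range(8):
        rows.append((f"u{i}", 0, 5 + i, 1, 0.0))  # all events unexposed
        rows.append((f"e{i}", 0, 6 + i, 0, 1.0))  # exposed, censored
    df = pd.DataFrame(rows, columns=["cluster_id", "t_start", "t_stop", "event", "x"])
    res = fit_cox(_dataset_from_frame(df, ["x"]))
    assert res.monotone_likelihood_flag
    row = res.covariate("x")
    assert not row["estimable"]
    assert np.isnan(row["hazard_ratio"])


def test_robust_and_naive_agree_without_clustering_structure():
    """One row per patient, no recurrence: sandwich ~ model-based SE."""
    rng = np.random.default_rng(77)
    n = 1200
    x = rng.integers(0, 2, n).astype(float)
    # exponential event times under a true effect, administrative censoring
    lam = 0.02 * np.exp(0.7 * x)
    t = rng.exponential(1 / lam)
    cens = 60.0
    stop = np.maximum(1, np.ceil(np.minimum(t, cens)))  # whole days
    ev = (t <= cens).astype(int)
    df = pd.DataFrame(
        {"cluster_id": [f"P{i}" for i in range(n)], "t_start": 0.0,
         "t_stop": stop, "event": ev, "x": x}
    )
    ds = _dataset_from_frame(df, ["x"])
    robust = fit_cox(ds).covariate("x")["robust_se"]
    naive = fit_cox(ds, cluster=False, robust=False).covariate("x")["robust_se"]
    assert abs(robust - naive) / naive < 0.10


def test_interaction_stratum_identity():
    """PPI-stratum HR from the interaction fit equals the recoded refit.

    Recoding med-exposure into disjoint med-without-PPI and
    med-with-PPI indicators reparameterizes the same model, so
    exp(b_meds + b_interaction) must equal exp(c_med_with_ppi).
    """
    from pipcox.calibration import calibration_config
    from pipcox.synthetic_data import generate_cohort

    cohort, _ = generate_cohort(calibration_config(800, seed=23))
    bleedings = detect_bleedings(cohort)
    spec = ModelSpec("ALL_STARTS", "part2_interaction")
    ds = assemble_model_dataset(cohort, [], bleedings, spec)
    res = fit_cox(ds, fit_options={"precision": 1e-10})
    assert res.covariate("meds_x_ppi")["estimable"]
    strata = interaction_stratum_hrs(res)

    df = ds.to_frame()
    df["med_noppi"] = df["meds"] * (1 - df["ppi"])
    df["med_ppi"] = df["meds"] * df["ppi"]
    ds2 = _dataset_from_frame(df, ["med_noppi", "med_ppi", "ppi", "age", "sex"])
    res2 = fit_cox(ds2, fit_options={"precision": 1e-10})
    assert np.log(strata["no_ppi_hr"]) == pytest.approx(
        res2.covariate("med_noppi")["coef"], abs=1e-6
    )
    assert np.log(strata["ppi_hr"]) == pytest.approx(
        res2.covariate("med_ppi")["coef"], abs=1e-6
    )


def test_run_plan_full_battery(medium_cohort):
    """The whole model battery runs; non-estimable entries don't crash."""
    cohort, _ = medium_cohort
    records = evaluate_cohort_part1(cohort)
    bleedings = detect_bleedings(cohort)
    table, fits = run_plan(cohort, records, bleedings, default_plan())
    assert len(table) == len(default_plan().specs)
    # every estimable row reports a finite positive HR and CI order
    est = table[table["estimable"]]
    assert (est["hr"] > 0).all()
    assert (est["ci95_low"] <= est["hr"]).all() and (est["hr"] <= est["ci95_high"]).all()
    # rare criteria with no qualifying exposure are reported, not dropped
    assert set(table["criterion"]) > {"ALL_COMBINED", "START_D2B", "STOPP_A9"}


def test_run_plan_handles_criterion_nobody_triggers(small_cohort):
    cohort, _ = small_cohort
    bleedings = detect_bleedings(cohort)
    from pipcox.cox_analysis import AnalysisPlan

    table, fits = run_plan(cohort, [], bleedings, AnalysisPlan([ModelSpec("STOPP_E5")]))
    assert len(table) == 1
    assert not table.iloc[0]["estimable"]
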