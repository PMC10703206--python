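"""Time-dependent Cox models with participant-clustered robust variance.

Fits the proportional-hazards model ``H(t) = h0(t) * exp(b'X(t))`` on
counting-process rows ``(t_start, t_stop]`` with delayed entry, Efron
tie handling (day-grain data guarantees tied event times) and a
cluster-robust sandwich variance treating all sequences of one
participant as a correlated cluster.  Hazard ratios, Wald 95% CIs and
p-values are derived from the coefficient and its robust standard
error.

A criterion during which no bleeding ever occurs has a monotone partial
likelihood — the exposure coefficient diverges to -inf and no finite
hazard ratio exists.  Such fits are flagged and reported as
non-estimable instead of a numeric HR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._coxfit import efron_cox_fit

from .bleeding_detector import BleedingEvent
from .criteria_engine import CRITERION_CODES, START_CODES, CriteriaConfig, PIPRecord
from .ehr_model import Cohort
from .timesplit import GROUPS, ModelDataset, ModelSpec, assemble_model_dataset

__all__ = [
    "CoxFitResult",
    "fit_cox",
    "AnalysisPlan",
    "default_plan",
    "run_plan",
    "interaction_stratum_hrs",
    "Z_95",
]

#: normal quantile for two-sided 95% confidence intervals
Z_95 = 1.959964

#: |coefficient| beyond which we declare the likelihood monotone
MONOTONE_BETA = 15.0


@dataclass
class CoxFitResult:
    """One fitted model: per-covariate estimates plus diagnostics.

    ``summary`` is indexed by covariate with columns ``coef``,
    ``robust_se``, ``hazard_ratio``, ``ci95_low``, ``ci95_high``,
    ``p_value`` and ``estimable``.  The HR and CI columns always satisfy
    ``hr = exp(coef)`` and ``ci = exp(coef +/- 1.959964 * se)``.
    """

    model_tag: str
    summary: pd.DataFrame
    n_rows: int
    n_events: int
    convergence_flag: bool
    monotone_likelihood_flag: bool
    log_likelihood: float = np.nan

    def covariate(self, name: str) -> pd.Series:
        return self.summary.loc[name]


def _summary_from(coefs: pd.Series, ses: pd.Series) -> pd.DataFrame:
    df = pd.DataFrame({"coef": coefs, "robust_se": ses})
    # diverged (monotone) coefficients overflow exp(); they are blanked
    # to NaN by the caller, so compute quietly
    with np.errstate(over="ignore", invalid="ignore"):
        df["hazard_ratio"] = np.exp(df["coef"])
        df["ci95_low"] = np.exp(df["coef"] - Z_95 * df["robust_se"])
        df["ci95_high"] = np.exp(df["coef"] + Z_95 * df["robust_se"])
        z = df["coef"] / df["robust_se"]
    df["p_value"] = 2.0 * stats.norm.sf(np.abs(z))
    df["estimable"] = np.abs(df["coef"]) <= MONOTONE_BETA
    return df


def fit_cox(
    dataset: ModelDataset,
    cluster: bool = True,
    robust: bool = True,
    initial_coefs: Optional[dict] = None,
    fit_options: Optional[dict] = None,
) -> CoxFitResult:
    """Maximize the Cox partial likelihood on a counting-process dataset.

    Sequences are clustered by participant for the sandwich variance
    when ``cluster`` is True (set both flags False for a naive
    model-based variance).  ``initial_coefs`` warm-starts the Newton
    iterations (the partial likelihood is concave, so this affects
    speed only); ``fit_options`` passes solver settings (e.g.
    ``{"precision": 1e-9}``) through to the optimizer.  Raises
    ``ValueError`` when the dataset contains no events or no covariate
    variation at all; a diverging coefficient is returned flagged as
    non-estimable rather than raised.
    """
    df = dataset.to_frame()
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValueError(f"no events in dataset {dataset.model_tag!r}: cannot fit")
    covs = list(dataset.covariate_names)
    kept = [c for c in covs if df[c].nunique() > 1]
    if not kept:
        raise ValueError(f"no covariate variation in dataset {dataset.model_tag!r}")

    init = None
    if initial_coefs:
        init = np.array([float(initial_coefs.get(c, 0.0)) for c in kept])
    tol = float((fit_options or {}).get("precision", 1e-9))
    max_iter = int((fit_options or {}).get("max_steps", 60))

    fit = efron_cox_fit(
        df[kept].to_numpy(float),
        df["t_start"].to_numpy(float),
        df["t_stop"].to_numpy(float),
        df["event"].to_numpy(int),
        clusters=df["cluster_id"].to_numpy() if cluster else None,
        init=init,
        tol=tol,
        max_iter=max_iter,
    )
    converged = fit.converged
    se = fit.robust_se if (cluster and robust) else fit.naive_se
    coefs = pd.Series(fit.beta, index=kept)
    ses = pd.Series(se, index=kept)
    ll = fit.loglik

    # re-insert dropped (constant) covariates as non-estimable
    coefs = coefs.reindex(covs)
    ses = ses.reindex(covs)
    summary = _summary_from(coefs, ses)
    summary.loc[[c for c in covs if c not in kept], "estimable"] = False
    monotone = bool((np.abs(coefs) > MONOTONE_BETA).any()) or not converged
    # blank out diverged coefficients: no finite HR exists
    diverged = np.abs(summary["coef"]) > MONOTONE_BETA
    summary.loc[diverged, ["hazard_ratio", "ci95_low", "ci95_high", "p_value"]] = np.nan
    summary.loc[diverged, "estimable"] = False

    return CoxFitResult(
        model_tag=dataset.model_tag,
        summary=summary,
        n_rows=len(df),
        n_events=n_events,
        convergence_flag=converged,
        monotone_likelihood_flag=monotone,
        log_likelihood=ll,
    )


def interaction_stratum_hrs(result: CoxFitResult) -> dict[str, float]:
    """Stratum-specific medication HRs from an interaction fit.

    Without concomitant PPI the medication HR is ``exp(b_meds)``; with
    PPI it is ``exp(b_meds + b_interaction)``.
    """
    b_med = result.covariate("meds")["coef"]
    b_int = result.covariate("meds_x_ppi")["coef"]
    return {"no_ppi_hr": float(np.exp(b_med)), "ppi_hr": float(np.exp(b_med + b_int))}


# ---------------------------------------------------------------------------
# Analysis battery


@dataclass
class AnalysisPlan:
    """An ordered list of model specifications to fit."""

    specs: list

    def __iter__(self):
        return iter(self.specs)


def default_plan(include_part2: bool = True, include_sensitivity: bool = True) -> AnalysisPlan:
    """The full analysis battery.

    Combined part-1 models (all criteria, STARTs only, STOPPs only,
    each adjusted for age and sex only), the nine individual criteria in
    both the multivariable and the confounder-adjusted form, the six
    START part-2 models (multivariable and interaction) plus the
    all-STARTs part-2 models, and the bleeding-subpopulation
    sensitivity fits.
    """
    specs = [
        ModelSpec("ALL_COMBINED", "multivariable"),
        ModelSpec("STARTS_COMBINED", "multivariable"),
        ModelSpec("STOPPS_COMBINED", "multivariable"),
    ]
    for code in CRITERION_CODES:
        specs.append(ModelSpec(code, "multivariable"))
        specs.append(ModelSpec(code, "adjusted"))
    if include_part2:
        for code in START_CODES:
            specs.append(ModelSpec(code, "part2_multivariable"))
            specs.append(ModelSpec(code, "part2_interaction"))
        specs.append(ModelSpec("ALL_STARTS", "part2_multivariable"))
        specs.append(ModelSpec("ALL_STARTS", "part2_interaction"))
    if include_sensitivity:
        specs.append(ModelSpec("STARTS_COMBINED", "multivariable", "bleeding_subpopulation"))
        specs.append(ModelSpec("START_D3B", "multivariable", "bleeding_subpopulation"))
        specs.append(ModelSpec("START_D3C", "multivariable", "bleeding_subpopulation"))
    return AnalysisPlan(specs)


def _n_records(pip_records: Sequence[PIPRecord], criterion: str) -> int:
    if criterion == "ALL_COMBINED":
        return len(pip_records)
    if criterion in ("STARTS_COMBINED", "ALL_STARTS"):
        return sum(1 for r in pip_records if r.criterion_code in START_CODES)
    if criterion == "STOPPS_COMBINED":
        return sum(1 for r in pip_records if r.criterion_code.startswith("STOPP"))
    return sum(1 for r in pip_records if r.criterion_code == criterion)


def run_plan(
    cohort: Cohort,
    pip_records: Sequence[PIPRecord],
    bleedings: Sequence[BleedingEvent],
    plan: Optional[AnalysisPlan] = None,
    config: Optional[CriteriaConfig] = None,
    part2_intervals=None,
) -> tuple[pd.DataFrame, dict]:
    """Fit every model in the plan; never abort on a non-estimable entry.

    Returns a tidy results table (one row per model and covariate of
    interest, with record counts, HR, CI, p and flags) plus the raw
    :class:`CoxFitResult` objects keyed by model tag.
    """
    plan = plan or default_plan()
    # evaluate part-2 intervals once per criterion instead of per model
    if part2_intervals is None:
        from .criteria_engine import evaluate_cohort_part2

        needed = set()
        for spec in plan:
            if spec.form.startswith("part2"):
                needed |= set(START_CODES) if spec.criterion == "ALL_STARTS" else {spec.criterion}
        if needed:
            part2_intervals = {
                code: evaluate_cohort_part2(cohort, code, config) for code in sorted(needed)
            }
    rows = []
    fits: dict[str, CoxFitResult] = {}
    for spec in plan:
        n_rec = _n_records(pip_records, spec.criterion)
        base = {
            "criterion": spec.criterion,
            "form": spec.form,
            "population": spec.population,
            "n_records": n_rec,
        }
        try:
            ds = assemble_model_dataset(
                cohort, pip_records, bleedings, spec, config=config,
                part2_intervals=part2_intervals,
            )
            res = fit_cox(ds)
        except ValueError as err:
            rows.append({**base, "exposure": None, "hr": np.nan, "ci95_low": np.nan,
                         "ci95_high": np.nan, "p_value": np.nan, "n_events": 0,
                         "estimable": False, "note": str(err)})
            continue
        fits[res.model_tag] = res
        exposure = "meds" if spec.form.startswith("part2") else "pip"
        row = res.covariate(exposure)
        entry = {
            **base,
            "exposure": exposure,
            "hr": row["hazard_ratio"],
            "ci95_low": row["ci95_low"],
            "ci95_high": row["ci95_high"],
            "p_value": row["p_value"],
            "n_events": res.n_events,
            "estimable": bool(row["estimable"]),
            "note": "" if row["estimable"] else "monotone likelihood / non-estimable",
        }
        if spec.form == "part2_interaction" and row["estimable"]:
            inter = res.covariate("meds_x_ppi")
            if inter["estimable"]:
                strata = interaction_stratum_hrs(res)
                entry["ppi_hr"] = strata["ppi_hr"]
                entry["no_ppi_hr"] = strata["no_ppi_hr"]
                entry["interaction_coef"] = inter["coef"]
                entry["interaction_p"] = inter["p_value"]
        rows.append(entry)
    return pd.DataFrame(rows), fits
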