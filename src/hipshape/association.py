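"""Per-mode association models between hip shape and OA outcomes.

One logistic (binary outcomes) or Cox proportional-hazards (time to THR)
model is fitted per hip shape mode, with the mode's standardized score as
the single exposure plus the confounder set (age, sex, height, weight,
binary white/other ethnicity), optionally further adjusted for the alpha
angle or the lateral centre-edge angle.  Effects are reported as OR / HR
per 1 SD of mode score with Wald 95% CIs and two-sided Wald p-values;
multiple testing across the modes is controlled with a Bonferroni
threshold (0.05 / number of modes, i.e. p < 0.005 for ten modes).

Attenuation between a base and an adjusted model is computed on the
excess-odds scale: ``100 * (OR_base - OR_adj) / (OR_base - 1)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy.stats import norm as _norm

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "CONFOUNDERS",
    "fit_logistic_per_hsm",
    "fit_cox_per_hsm",
    "bonferroni_flag",
    "attenuation_percent",
    "describe_cohort",
    "percent",
    "results_to_frame",
]

CONFOUNDERS = ("age", "sex_male", "height", "weight", "ethnicity_white")


@dataclass
class AssociationResult:
    """Effect of one mode on one outcome under one adjustment model."""

    hsm: str
    outcome: str
    model: str                  # unadjusted / model2 / model2_aa / model2_lcea
    effect: float               # OR or HR per 1 SD of mode score
    ci_low: float
    ci_high: float
    p_value: float
    beta: float                 # log-odds / log-hazard per SD
    se: float
    n: int
    n_events: int
    estimable: bool = True
    note: str = ""


def _design(scores: pd.DataFrame, hsm: str, covariates: pd.DataFrame | None,
            extra: pd.Series | None) -> pd.DataFrame:
    X = pd.DataFrame({hsm: scores[hsm].to_numpy()})
    if covariates is not None:
        cov = covariates.copy()
        if "sex" in cov.columns and "sex_male" not in cov.columns:
            cov["sex_male"] = (cov["sex"] == "M").astype(float)
        for c in CONFOUNDERS:
            if c in cov.columns:
                X[c] = cov[c].to_numpy().astype(float)
    if extra is not None:
        X[extra.name or "extra"] = np.asarray(extra, float)
    return X


def fit_logistic_per_hsm(
    scores: pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    extra: pd.Series | None = None,
    outcome_name: str = "outcome",
    model_name: str = "model2",
) -> list[AssociationResult]:
    """One confounder-adjusted logistic model per mode score column.

    *scores* holds the standardized per-mode exposure columns (``hsm1``,
    ``hsm2``, ... or any non-``subject_id`` columns); each model uses one
    mode plus the confounders (and *extra*, e.g. an AA or LCEA series).
    Outcomes with fewer than two events or with failed/separated fits
    yield a flagged non-estimable result rather than an exception.
    """
    y = np.asarray(outcome, float)
    hsms = [c for c in scores.columns if c != "subject_id"]
    results: list[AssociationResult] = []
    n_events = int(np.nansum(y))
    for hsm in hsms:
        base = dict(hsm=hsm, outcome=outcome_name, model=model_name,
                    n=len(y), n_events=n_events)
        if len(np.unique(y[~np.isnan(y)])) < 2 or n_events < 2 or len(y) - n_events < 2:
            results.append(AssociationResult(
                effect=np.nan, ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                beta=np.nan, se=np.nan, estimable=False,
                note="outcome has < 2 events or is constant", **base))
            continue
        X = sm.add_constant(_design(scores, hsm, covariates, extra))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            beta = float(fit.params[hsm])
            se = float(fit.bse[hsm])
            ok = np.isfinite(beta) and np.isfinite(se) and se < 50 and abs(beta) < 50
        except Exception as exc:  # separation, singular design, ...
            results.append(AssociationResult(
                effect=np.nan, ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                beta=np.nan, se=np.nan, estimable=False, note=str(exc), **base))
            continue
        if not ok:
            results.append(AssociationResult(
                effect=np.nan, ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                beta=beta, se=se, estimable=False,
                note="non-finite or diverged Wald statistics (separation?)", **base))
            continue
        p = float(2.0 * _norm.sf(abs(beta / se)))
        results.append(AssociationResult(
            effect=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.959963984540054 * se)),
            ci_high=float(np.exp(beta + 1.959963984540054 * se)),
            p_value=p, beta=beta, se=se, **base))
    return results


def fit_cox_per_hsm(
    scores: pd.DataFrame,
    thr_time: pd.Series | np.ndarray,
    thr_event: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    extra: pd.Series | None = None,
    outcome_name: str = "thr",
    model_name: str = "model2",
) -> list[AssociationResult]:
    """One Cox proportional-hazards model per mode score column.

    HR per 1 SD with partial-likelihood Wald CI; ties handled by Efron's
    method (the lifelines default).  No events -> non-estimable flag.
    """
    t = np.asarray(thr_time, float)
    e = np.asarray(thr_event, float)
    if np.any(t < 0):
        raise ValueError("thr_time must be >= 0")
    hsms = [c for c in scores.columns if c != "subject_id"]
    n_events = int(e.sum())
    results: list[AssociationResult] = []
    for hsm in hsms:
        base = dict(hsm=hsm, outcome=outcome_name, model=model_name,
                    n=len(t), n_events=n_events)
        if n_events < 1:
            results.append(AssociationResult(
                effect=np.nan, ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                beta=np.nan, se=np.nan, estimable=False,
                note="no events", **base))
            continue
        df = _design(scores, hsm, covariates, extra)
        df["_time"] = t
        df["_event"] = e
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="_time", event_col="_event")
            beta = float(cph.params_[hsm])
            se = float(cph.standard_errors_[hsm])
            ok = np.isfinite(beta) and np.isfinite(se) and se < 50
        except Exception as exc:
            results.append(AssociationResult(
                effect=np.nan, ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                beta=np.nan, se=np.nan, estimable=False, note=str(exc), **base))
            continue
        if not ok:
            results.append(AssociationResult(
                effect=np.nan, ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                beta=beta, se=se, estimable=False, note="diverged fit", **base))
            continue
        p = float(2.0 * _norm.sf(abs(beta / se)))
        results.append(AssociationResult(
            effect=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.959963984540054 * se)),
            ci_high=float(np.exp(beta + 1.959963984540054 * se)),
            p_value=p, beta=beta, se=se, **base))
    return results


def bonferroni_flag(results: list[AssociationResult] | pd.DataFrame,
                    n_tests: int = 10, alpha: float = 0.05):
    """Mark results significant at the Bonferroni threshold alpha/n_tests.

    The comparison is strict (< threshold): p exactly at the threshold is
    not significant.  Works on a result list (adds ``significant``) or a
    results DataFrame (adds a column); returns its input.
    """
    thr = alpha / n_tests
    if isinstance(results, pd.DataFrame):
        results["significant"] = results["p_value"] < thr
        return results
    for r in results:
        r.significant = bool(np.isfinite(r.p_value) and r.p_value < thr)
    return results


def attenuation_percent(or_base: float, or_adjusted: float) -> float:
    """Attenuation of an OR/HR by further adjustment, on the excess-odds scale.

    ``100 * (OR_base - OR_adj) / (OR_base - 1)``: 0% means unchanged, 100%
    means fully attenuated to the null; the same excess term handles
    protective (< 1) effects.  Undefined (NaN) when the base OR is 1.
    """
    if or_base == 1.0:
        return float("nan")
    return 100.0 * (or_base - or_adjusted) / (or_base - 1.0)


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = asdict(r)
        d["significant"] = getattr(r, "significant", np.isfinite(r.p_value) and r.p_value < 0.005)
        rows.append(d)
    return pd.DataFrame(rows)


def percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage of *count* in *total*, rounded to *decimals* (1 dp default)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return float(np.round(100.0 * count / total, decimals))


def describe_cohort(cohort: pd.DataFrame, grades: pd.DataFrame | None = None) -> pd.DataFrame:
    """Descriptive characteristics table: overall and by sex.

    Continuous variables as mean (SD); categorical as n (%) with
    percentages to one decimal place.  If a grading table is supplied, the
    rHOA flags are included among the categorical rows.
    """
    df = cohort.copy()
    if grades is not None:
        df = df.merge(grades[["subject_id", "rhoa_grade2_only", "rhoa_ge3"]],
                      on="subject_id", how="left")
    groups = {"combined": df, "males": df[df["sex"] == "M"], "females": df[df["sex"] == "F"]}
    continuous = [c for c in ("age", "weight", "height", "nsa", "nnw", "alpha_angle", "lcea")
                  if c in df.columns]
    categorical = [c for c in ("rhoa_grade2_only", "rhoa_ge3", "hoa_hospital",
                               "thr_event", "ethnicity_white") if c in df.columns]
    rows = []
    for var in continuous:
        row = {"variable": var, "kind": "mean_sd"}
        for g, sub in groups.items():
            row[f"{g}_value"] = f"{sub[var].mean():.1f} ({sub[var].std():.1f})"
        rows.append(row)
    for var in categorical:
        row = {"variable": var, "kind": "n_pct"}
        for g, sub in groups.items():
            cnt = int(pd.to_numeric(sub[var]).sum())
            row[f"{g}_value"] = f"{cnt} ({percent(cnt, len(sub))})"
            row[f"{g}_n"] = cnt
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n"] = {g: len(sub) for g, sub in groups.items()}
    return out
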