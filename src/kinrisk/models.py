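"""Logistic models for prevalent and incident disease, with IPCW.

The analysis fits logistic regressions of prevalent and incident T2D on
the polygenic score (per in-sample sd), the FamRS categories (FamRS2 =
positive/strong positive, FamRS3 = very strong positive, vs average),
top-percentile PGS contrasts and the simplified parental-history flag,
under three adjustment sets: unadjusted; sex + age + BMI + physical
activity; and additionally the respective other score.  Incident
analyses exclude prevalent cases from the risk set and reweight by
inverse probability of censoring weights (IPCW): each participant gets
weight 1/S_C(t-), where S_C is the censoring survival function from a
Cox model (or Kaplan-Meier fallback) of death/loss before the
administrative end of follow-up.

Weights act as per-observation multipliers of the log-likelihood;
confidence intervals and p-values are Wald.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

BASE_COVARIATES = ("female", "age_baseline", "bmi", "physical_activity")
SEPARATION_BETA = 15.0
Z975 = 1.959963984540054


@dataclass(frozen=True)
class FitResult:
    term: str
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    converged: bool


@dataclass
class CensoringModel:
    method: str
    covariates: tuple
    event_times: np.ndarray
    baseline_survival: np.ndarray
    weights: pd.Series = field(repr=False, default=None)
    degenerate: bool = False
    coefficients: pd.Series | None = None


def _check_design(X: pd.DataFrame) -> None:
    for col in X.columns:
        vals = X[col].to_numpy(dtype=float)
        if np.all(vals == vals[0]):
            raise ValueError(f"design column {col!r} is constant")
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offending columns from the QR diagonal
        _, rr = np.linalg.qr(mat)
        diag = np.abs(np.diag(rr))
        tol = diag.max() * max(mat.shape) * np.finfo(float).eps
        bad = [
            (["(intercept)"] + list(X.columns))[j]
            for j in range(mat.shape[1])
            if diag[j] < tol
        ]
        raise ValueError(f"singular design; collinear column(s): {bad}")


def fit_logistic(
    X: pd.DataFrame,
    y,
    weights=None,
    robust: bool = False,
) -> pd.DataFrame:
    """Weighted logistic regression; one FitResult row per term.

    IRLS (statsmodels GLM/Binomial) to tight tolerance, max 100
    iterations; weights multiply each observation's log-likelihood.
    Suspected separation (|beta| > 15) is flagged as non-converged.
    ``robust`` switches to a sandwich (HC0) covariance.
    """
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    n_events = int(y.sum())
    if n_events < 1 or n_events >= len(y):
        raise ValueError("need at least one event and one non-event")
    _check_design(X)
    design = sm.add_constant(X.astype(float), prepend=True, has_constant="add")
    w = None if weights is None else np.asarray(weights, dtype=float)
    if w is not None and (w < 0).any():
        raise ValueError("weights must be non-negative")
    model = sm.GLM(y, design, family=sm.families.Binomial(), freq_weights=w)
    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        res = model.fit(maxiter=100, tol=1e-14)
        if robust:
            res = model.fit(maxiter=100, tol=1e-14, cov_type="HC0")
    warned = any("separation" in str(wm.message).lower() for wm in caught)
    separated = warned or bool(np.abs(res.params.to_numpy()).max() > SEPARATION_BETA)
    converged = bool(res.converged) and not separated
    if separated:
        log.warning("possible separation: max|beta| > %s", SEPARATION_BETA)
    def _exp(v: float) -> float:
        try:
            return math.exp(v)
        except OverflowError:
            return math.inf

    rows = []
    for term in design.columns:
        b = float(res.params[term])
        se = float(res.bse[term])
        rows.append(
            FitResult(
                term="(intercept)" if term == "const" else term,
                beta=b,
                se=se,
                odds_ratio=_exp(b),
                ci_low=_exp(b - Z975 * se),
                ci_high=_exp(b + Z975 * se),
                p_value=float(res.pvalues[term]),
                n=len(y),
                n_events=n_events,
                converged=converged,
            )
        )
    return pd.DataFrame(rows)


def predicted_probabilities(X: pd.DataFrame, y, weights=None) -> np.ndarray:
    """Fitted event probabilities from a logistic model (for NRI/IDI)."""
    y = np.asarray(y, dtype=float)
    design = sm.add_constant(X.astype(float), prepend=True, has_constant="add")
    w = None if weights is None else np.asarray(weights, dtype=float)
    res = sm.GLM(y, design, family=sm.families.Binomial(), freq_weights=w).fit(
        maxiter=100, tol=1e-14
    )
    return np.asarray(res.fittedvalues)


def _surv_left_limit(event_times, surv, t) -> np.ndarray:
    """S(t-): survival just before t, from a right-continuous step function."""
    t = np.asarray(t, dtype=float)
    # S(t-) equals the value after the last event time strictly < t
    idx = np.searchsorted(event_times, t, side="left") - 1
    s = np.ones(len(t))
    has = idx >= 0
    s[has] = surv[idx[has]]
    return s


def fit_censoring_and_weights(
    cohort: pd.DataFrame,
    covariates=BASE_COVARIATES,
    method: str = "cox",
) -> CensoringModel:
    """IPCW: model censoring (death or loss before the administrative end)
    and weight each person by 1/S_C(t-) at their own end-of-follow-up.

    Cox uses a lifelines partial-likelihood fit (Breslow ties for the
    coefficients) with a product-limit baseline
    S0(t) = prod_{t_j<=t} (1 - d_j / sum_risk exp(x'beta)) so that a null
    covariate effect reduces exactly to Kaplan-Meier; the Kaplan-Meier
    fallback ignores covariates.  With no censoring events all weights
    are 1 (degenerate model, logged).
    """
    if method not in ("cox", "kaplan_meier"):
        raise ValueError(f"unknown censoring method {method!r}")
    t = cohort["followup_time"].to_numpy(dtype=float)
    if (t <= 0).any():
        raise ValueError("followup_time must be positive")
    cens = (cohort["death"] | cohort["censored"]).to_numpy(dtype=bool)
    index = cohort.index
    if cens.sum() == 0:
        log.info("no censoring events; IPCW weights degenerate to 1")
        return CensoringModel(
            method,
            tuple(covariates),
            np.array([]),
            np.array([]),
            weights=pd.Series(1.0, index=index),
            degenerate=True,
        )

    if method == "cox":
        from lifelines import CoxPHFitter

        df = pd.DataFrame({c: cohort[c].astype(float) for c in covariates})
        df["T"] = t
        df["E"] = cens.astype(int)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="T", event_col="E")
        beta = cph.params_.reindex(list(covariates)).to_numpy()
        x = df[list(covariates)].to_numpy()
        risk = np.exp((x - x.mean(axis=0)) @ beta)
        coefs = cph.params_
    else:
        risk = np.ones(len(t))
        coefs = None

    order = np.argsort(t, kind="stable")
    ts, cs, rs = t[order], cens[order], risk[order]
    uniq = np.unique(ts[cs])
    # risk-set sums of exp(x'beta) and censoring-event counts at each time
    surv = np.empty(len(uniq))
    s = 1.0
    for k, tj in enumerate(uniq):
        at_risk = ts >= tj
        d_r = rs[at_risk & cs & (ts == tj)].sum()
        denom = rs[at_risk].sum()
        s *= max(1.0 - d_r / denom, 0.0)
        surv[k] = s
    # individual survival S_i(t) = S0(t)^{exp(x'beta)}; at beta=0 this is KM
    s_minus0 = _surv_left_limit(uniq, surv, t)
    s_minus = s_minus0**risk
    if (s_minus <= 0).any():
        raise ValueError("zero censoring survival; IPCW weight undefined")
    weights = pd.Series(1.0 / s_minus, index=index)
    return CensoringModel(
        method,
        tuple(covariates),
        uniq,
        surv,
        weights=weights,
        degenerate=False,
        coefficients=coefs,
    )


def build_analysis_frame(
    cohort: pd.DataFrame,
    famrs: pd.DataFrame | None = None,
    pgs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge cohort, FamRS and PGS tables and derive model columns."""
    df = cohort.copy()
    df["female"] = (df["sex"] == "F").astype(float)
    df["physical_activity"] = df["physical_activity"].astype(float)
    if famrs is not None:
        f = famrs.set_index("person_id")
        df["famrs_score"] = df["person_id"].map(f["score"])
        cj = df["person_id"].map(f["category_joined"])
        df["famrs2"] = (cj == "FamRS2").astype(float)
        df["famrs3"] = (cj == "FamRS3").astype(float)
        df["famrs_above_avg"] = (df["famrs_score"] > 0.5).astype(float)
        if "parental_history" in f.columns:
            df["parental_history"] = (
                df["person_id"].map(f["parental_history"]).astype(float)
            )
    if pgs is not None:
        p = pgs.set_index("person_id")
        df["pgs_raw"] = df["person_id"].map(p["raw_score"])
        df["pgs_z"] = df["person_id"].map(p["z_score"])
        for q in (20, 10, 5, 1):
            col = f"top{q}"
            if col in p.columns:
                df[col] = df["person_id"].map(p[col]).astype(float)
    return df


EXPOSURE_TERMS = {
    "pgs": ["pgs_z"],
    "famrs": ["famrs2", "famrs3"],
    "parental_history": ["parental_history"],
}
ADJUSTMENT_SETS = ("unadjusted", "base", "mutual")


def _prepare_outcome(df: pd.DataFrame, outcome: str, ipcw: bool, ipcw_method: str):
    """Risk set, outcome vector and weights for one outcome."""
    if outcome == "prevalent":
        sub = df
        y = sub["t2d_prevalent"].astype(int).to_numpy()
        w = None
    elif outcome == "incident":
        sub = df[~df["t2d_prevalent"]].copy()
        assert not sub["t2d_prevalent"].any(), "prevalent case in incident risk set"
        y = sub["t2d_incident"].astype(int).to_numpy()
        w = (
            fit_censoring_and_weights(sub, method=ipcw_method).weights.to_numpy()
            if ipcw
            else None
        )
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    return sub, y, w


def _model_columns(exposure: str, adjustment: str) -> list[str]:
    cols = list(EXPOSURE_TERMS[exposure])
    if adjustment in ("base", "mutual"):
        cols += list(BASE_COVARIATES)
    if adjustment == "mutual":
        other = {"pgs": ["famrs2", "famrs3"], "famrs": ["pgs_z"]}.get(exposure, [])
        cols += other
    return cols


def _tidy(fit: pd.DataFrame, keep_terms, **meta) -> pd.DataFrame:
    out = fit[fit["term"].isin(keep_terms)].copy()
    for k, v in reversed(meta.items()):
        out.insert(0, k, v)
    return out


def run_model_grid(
    cohort: pd.DataFrame,
    famrs: pd.DataFrame,
    pgs: pd.DataFrame,
    outcomes=("prevalent", "incident"),
    exposures=("pgs", "famrs"),
    adjustments=ADJUSTMENT_SETS,
    ipcw: bool = True,
    ipcw_method: str = "cox",
) -> pd.DataFrame:
    """The main model grid: exposure x adjustment x outcome, tidy output.

    PGS effects are per 1 in-sample sd; FamRS enters as FamRS2/FamRS3
    dummies against average risk.  Rows with missing covariates are
    excluded with a logged count.
    """
    df = build_analysis_frame(cohort, famrs, pgs)
    rows = []
    for outcome in outcomes:
        sub, y, w = _prepare_outcome(df, outcome, ipcw, ipcw_method)
        for exposure in exposures:
            for adjustment in adjustments:
                cols = _model_columns(exposure, adjustment)
                ok = sub[cols].notna().all(axis=1).to_numpy()
                if (~ok).sum():
                    log.info(
                        "%s/%s/%s: excluding %d rows with missing covariates",
                        outcome, exposure, adjustment, int((~ok).sum()),
                    )
                fit = fit_logistic(
                    sub.loc[ok, cols], y[ok], None if w is None else w[ok]
                )
                rows.append(
                    _tidy(
                        fit,
                        EXPOSURE_TERMS[exposure],
                        outcome=outcome,
                        exposure=exposure,
                        adjustment=adjustment,
                    )
                )
    return pd.concat(rows, ignore_index=True)


def top_percentile_models(
    cohort: pd.DataFrame,
    famrs: pd.DataFrame,
    pgs: pd.DataFrame,
    quantiles=(20, 10, 5),
    outcomes=("prevalent", "incident"),
    ipcw: bool = True,
    ipcw_method: str = "cox",
) -> pd.DataFrame:
    """Top-q% PGS vs remainder, adjusted for age, sex, BMI, PA and FamRS."""
    df = build_analysis_frame(cohort, famrs, pgs)
    rows = []
    for outcome in outcomes:
        sub, y, w = _prepare_outcome(df, outcome, ipcw, ipcw_method)
        for q in quantiles:
            flag = f"top{q}"
            cols = [flag] + list(BASE_COVARIATES) + ["famrs2", "famrs3"]
            n_exp_events = int(y[sub[flag].to_numpy(dtype=bool)].sum())
            if n_exp_events == 0 or n_exp_events == int(y.sum()):
                log.warning("%s/top%d: zero events in one group", outcome, q)
                rows.append(
                    pd.DataFrame(
                        [{
                            "outcome": outcome, "exposure": flag, "adjustment": "base+famrs",
                            "term": flag, "beta": np.nan, "se": np.nan,
                            "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                            "p_value": np.nan, "n": len(sub), "n_events": int(y.sum()),
                            "converged": False,
                        }]
                    )
                )
                continue
            fit = fit_logistic(sub[cols], y, w)
            rows.append(
                _tidy(fit, [flag], outcome=outcome, exposure=flag, adjustment="base+famrs")
            )
    return pd.concat(rows, ignore_index=True)


def age_stratified_models(
    cohort: pd.DataFrame,
    famrs: pd.DataFrame,
    pgs: pd.DataFrame,
    outcome: str = "prevalent",
    band_width: int = 10,
    age_start: float = 35.0,
    age_end: float = 85.0,
    min_events: int = 10,
    ipcw: bool = True,
    ipcw_method: str = "cox",
) -> pd.DataFrame:
    """Mutually adjusted above-average-FamRS and PGS effects per age band.

    Within each 10-year band only the two scores enter (no further
    covariates); FamRS is collapsed to average vs above average
    (FamRS > 0.5).  Bands with fewer events than ``min_events`` are
    skipped with a log entry.
    """
    df = build_analysis_frame(cohort, famrs, pgs)
    rows = []
    edges = np.arange(age_start, age_end, band_width)
    for lo in edges:
        hi = lo + band_width
        band = df[(df["age_baseline"] >= lo) & (df["age_baseline"] < hi)]
        if band.empty:
            log.info("age band [%g,%g): empty, skipped", lo, hi)
            continue
        sub, y, w = _prepare_outcome(band, outcome, ipcw, ipcw_method)
        if int(y.sum()) < min_events or int((1 - y).sum()) < 1:
            log.info(
                "age band [%g,%g): %d events < %d, skipped", lo, hi, int(y.sum()), min_events
            )
            continue
        fit = fit_logistic(sub[["famrs_above_avg", "pgs_z"]], y, w)
        out = _tidy(
            fit,
            ["famrs_above_avg", "pgs_z"],
            outcome=outcome,
            exposure="age_stratified",
            adjustment="mutual",
        )
        out.insert(1, "age_band", f"{int(lo)}-{int(hi) - 1}")
        rows.append(out)
    if not rows:
        return pd.DataFrame()
    return pd.concat(rows, ignore_index=True)
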