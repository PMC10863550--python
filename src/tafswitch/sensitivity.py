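"""Sensitivity analyses around the main counterfactual model.

SA1 — adherence censoring: eGFR rows dated after a person's first treatment
deviation (a nonswitcher dispensing TAF, or a switcher re-dispensing TDF,
after their index date) are removed and the main model is refitted.

SA2 — inverse-probability-of-missingness weighting: a logistic model of
being included in the complete-case analysis (having any post-index eGFR)
yields stabilized weights — marginal inclusion probability over
covariate-conditional probability — that scale each person's likelihood
contribution in the Bayesian model.

SA3 — multiple imputation: outcomes binned to the a priori timepoints (and
any incomplete covariates) are imputed with chained equations; a separate
linear regression per timepoint estimates the switch coefficient, pooled
across imputations by Rubin's rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import LogisticRegression

from .counterfactual_outcome import (
    OutcomeModelSpec,
    OutcomePosterior,
    compute_att,
    fit_outcome_model,
)
from .tvps_matching import INSURANCE_LEVELS, RACE_LEVELS

log = logging.getLogger(__name__)

__all__ = [
    "censor_at_deviation",
    "fit_missingness_weights",
    "weighted_outcome_model",
    "mi_per_timepoint_regression",
    "rubin_pool",
    "bin_to_timepoints",
]


# --------------------------------------------------------------------------- SA1
def censor_at_deviation(
    dataset: pd.DataFrame, dispensings: pd.DataFrame, indexed: pd.DataFrame
) -> pd.DataFrame:
    """Drop eGFR rows after a person's first deviation from their index arm.

    Deviation = first TAF dispense strictly after the index date for
    nonswitchers, first TDF dispense strictly after the index date for
    switchers; dispensing gaps alone are not deviations.  Rows dated after
    (strictly) the deviation are removed; persons left without post-index
    follow-up drop out entirely.  The result is always a subset of the input.
    """
    disp = dispensings.copy()
    disp["date"] = pd.to_datetime(disp["date"])
    idx = indexed.set_index("person_id")
    deviation = {}
    for pid, arm, index_date in idx[["arm", "index_date"]].itertuples():
        bad_drug = "TDF" if arm == "switcher" else "TAF"
        d = disp.loc[
            (disp["person_id"] == pid)
            & (disp["drug"] == bad_drug)
            & (disp["date"] > pd.Timestamp(index_date))
        ]
        if len(d):
            deviation[pid] = d["date"].min()
    if not deviation:
        return dataset.copy()
    log.info("sa1: %d persons deviate from their index exposure", len(deviation))
    dev = dataset["person_id"].map(deviation)
    keep = dev.isna() | (pd.to_datetime(dataset["date"]) <= dev)
    out = dataset.loc[keep]
    has_followup = set(out.loc[out["months_since_index"] > 0, "person_id"])
    out = out.loc[out["person_id"].isin(has_followup)].reset_index(drop=True)
    log.info(
        "sa1: retained %d/%d rows, %d persons",
        len(out),
        len(dataset),
        out["person_id"].nunique(),
    )
    return out


# --------------------------------------------------------------------------- SA2
def _weight_design(cov: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=cov.index)
    for c in ("age", "male", "ever_smoker", "weight_at_index", "egfr_at_index"):
        if c in cov:
            X[c] = cov[c].astype(float)
    if "race_ethnicity" in cov:
        for lvl in RACE_LEVELS:
            X[f"race_{lvl.replace(' ', '_')}"] = (cov["race_ethnicity"] == lvl).astype(float)
    if "insurance" in cov:
        for lvl in INSURANCE_LEVELS:
            X[f"insurance_{lvl}"] = (cov["insurance"] == lvl).astype(float)
    # drop constant columns so the logistic fit stays identifiable
    return X.loc[:, X.nunique() > 1]


def fit_missingness_weights(
    cohort: pd.DataFrame,
    included_col: str = "included",
    covariate_cols: list[str] | None = None,
    truncate_pct: tuple = (1.0, 99.0),
) -> pd.DataFrame:
    """Stabilized inverse-probability-of-missingness weights.

    ``cohort`` has one row per matched person with an inclusion flag
    (any post-index eGFR) and baseline covariates.  The stabilized weight
    for included persons is marginal P(included) / logistic
    P(included | covariates); extreme weights are truncated at
    ``truncate_pct`` percentiles (logged).  Perfect separation raises.
    """
    y = cohort[included_col].astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError("inclusion flag is constant; weights are undefined")
    if covariate_cols is None:
        X = _weight_design(cohort)
    else:
        X = cohort[covariate_cols].astype(float)
    Xa = X.to_numpy(float)
    mu, sd = Xa.mean(axis=0), Xa.std(axis=0)
    sd[sd == 0] = 1.0
    model = LogisticRegression(penalty="l2", C=1e4, solver="lbfgs", max_iter=5000)
    model.fit((Xa - mu) / sd, y)
    p_cond = model.predict_proba((Xa - mu) / sd)[:, 1]
    # perfect separation: the covariates classify inclusion without error,
    # so conditional probabilities degenerate and weights are undefined
    if p_cond[y == 1].min() > p_cond[y == 0].max():
        raise ValueError(
            "missingness model shows perfect separation: covariates fully "
            "determine inclusion"
        )
    p_marg = y.mean()
    w = np.where(y == 1, p_marg / p_cond, (1 - p_marg) / (1 - p_cond))
    lo, hi = np.percentile(w, truncate_pct)
    n_trunc = int(np.sum((w < lo) | (w > hi)))
    if n_trunc:
        log.info("sa2: truncated %d weights to [%.3f, %.3f]", n_trunc, lo, hi)
    w = np.clip(w, lo, hi)
    out = pd.DataFrame(
        {
            "person_id": cohort["person_id"].to_numpy(),
            "included": y,
            "p_conditional": p_cond,
            "stabilized_weight": w,
        }
    )
    log.info("sa2: stabilized weights mean %.4f", out["stabilized_weight"].mean())
    return out


def weighted_outcome_model(
    dataset: pd.DataFrame,
    weights: pd.DataFrame | pd.Series,
    spec: OutcomeModelSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, OutcomePosterior]:
    """Main Bayesian model with person-level likelihood weights; returns
    (att_summary, att_draws, posterior)."""
    if isinstance(weights, pd.DataFrame):
        weights = weights.set_index("person_id")["stabilized_weight"]
    posterior = fit_outcome_model(dataset, spec=spec, seed=seed, weights=weights)
    summary, draws = compute_att(posterior)
    return summary, draws, posterior


# --------------------------------------------------------------------------- SA3
def rubin_pool(estimates, variances) -> dict:
    """Rubin's rules for ``m`` per-imputation estimates and variances.

    total variance T = W + (1 + 1/m) B with W the mean within-imputation
    variance and B the between-imputation variance; the interval uses the
    standard small-m degrees of freedom.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = q.size
    qbar = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1)) if m > 1 else 0.0
    total = within + (1.0 + 1.0 / m) * between
    if between > 0:
        df = (m - 1) * (1.0 + within / ((1.0 + 1.0 / m) * between)) ** 2
        crit = stats.t.ppf(0.975, df)
    else:
        df = np.inf
        crit = stats.norm.ppf(0.975)
    half = crit * np.sqrt(total)
    return {
        "estimate": qbar,
        "within": within,
        "between": between,
        "total_variance": total,
        "df": float(df),
        "ci_lo": qbar - half,
        "ci_hi": qbar + half,
        "m": int(m),
    }


def bin_to_timepoints(
    dataset: pd.DataFrame,
    timepoints,
    window_months: float = 42.0 / 30.4375,
    seed: int = 0,
) -> pd.DataFrame:
    """Wide per-person outcome layout: one eGFR per a priori timepoint.

    Each observation is assigned to the nearest timepoint within the window
    (default +/-6 weeks); among competitors for the same person-timepoint the
    closest wins, distance ties broken by a seeded random draw.  Unfilled
    cells are NaN (imputed downstream).
    """
    rng = np.random.default_rng(seed)
    tp = np.asarray(timepoints, dtype=float)
    rows = dataset[["person_id", "months_since_index", "egfr"]].copy()
    dist = np.abs(rows["months_since_index"].to_numpy()[:, None] - tp[None, :])
    nearest = np.argmin(dist, axis=1)
    rows["timepoint"] = tp[nearest]
    rows["dist"] = dist[np.arange(len(rows)), nearest]
    rows = rows.loc[rows["dist"] <= window_months].copy()
    rows["tiebreak"] = rng.random(len(rows))
    rows = rows.sort_values(["person_id", "timepoint", "dist", "tiebreak"], kind="stable")
    best = rows.groupby(["person_id", "timepoint"], sort=True).first().reset_index()
    wide = best.pivot(index="person_id", columns="timepoint", values="egfr")
    wide.columns = [f"egfr_m{c:g}" for c in wide.columns]
    for t in tp:
        col = f"egfr_m{t:g}"
        if col not in wide.columns:
            wide[col] = np.nan
    return wide[[f"egfr_m{t:g}" for t in tp]]


def mi_per_timepoint_regression(
    dataset: pd.DataFrame,
    timepoints=None,
    m: int = 10,
    seed: int = 0,
    window_months: float = 42.0 / 30.4375,
    max_iter: int = 10,
) -> pd.DataFrame:
    """SA3: chained-equation MI + per-timepoint linear regressions.

    The wide outcome matrix (one column per timepoint) and the numeric
    baseline covariates are imputed ``m`` times with an iterative
    Bayesian-ridge imputer drawing from the posterior predictive (chained
    equations); within each imputation and timepoint, eGFR is regressed on
    switch status and the baseline covariates and the switch coefficients
    are pooled by Rubin's rules.  A timepoint with no observed outcome in
    the binning basis is flagged unavailable (NaN row).
    """
    timepoints = tuple(timepoints if timepoints is not None else OutcomeModelSpec().timepoints)
    wide = bin_to_timepoints(dataset, timepoints, window_months, seed)
    base = dataset.drop_duplicates("person_id").set_index("person_id")
    base = base.reindex(wide.index.union(base.index))
    wide = wide.reindex(base.index)
    covX = pd.DataFrame(index=base.index)
    covX["switch"] = (base["arm"] == "switcher").astype(float)
    for c in ("age", "male", "ever_smoker", "weight_at_index", "egfr_at_index",
              "egfr_at_eligible", "duration_tdf_to_eligible", "hypertension_at_index"):
        covX[c] = base[c].astype(float)
    for lvl in RACE_LEVELS:
        covX[f"race_{lvl.replace(' ', '_')}"] = (base["race_ethnicity"] == lvl).astype(float)
    for lvl in INSURANCE_LEVELS:
        covX[f"insurance_{lvl}"] = (base["insurance"] == lvl).astype(float)

    out_cols = [f"egfr_m{t:g}" for t in timepoints]
    unavailable = [c for c in out_cols if wide[c].notna().sum() == 0]
    if unavailable:
        log.warning("sa3: timepoints with no observed outcomes: %s", unavailable)
    imp_cols = [c for c in out_cols if c not in unavailable]
    frame = pd.concat([wide[imp_cols], covX], axis=1)
    rng = np.random.default_rng(seed)
    per_tp: dict[str, list] = {c: [] for c in imp_cols}
    reg_cols = [c for c in covX.columns if covX[c].nunique() > 1 and c != "switch"]
    for _ in range(m):
        any_missing = frame.isna().any().any()
        if any_missing:
            imputer = IterativeImputer(
                sample_posterior=True,
                random_state=int(rng.integers(0, 2**31 - 1)),
                max_iter=max_iter,
            )
            filled = pd.DataFrame(
                imputer.fit_transform(frame), index=frame.index, columns=frame.columns
            )
        else:
            filled = frame.copy()
        for c in imp_cols:
            Xr = sm.add_constant(
                filled[["switch"] + reg_cols].to_numpy(float), has_constant="add"
            )
            fit = sm.OLS(filled[c].to_numpy(float), Xr).fit()
            per_tp[c].append((fit.params[1], fit.bse[1] ** 2))  # switch is column 1
    rows = []
    for t in timepoints:
        c = f"egfr_m{t:g}"
        if c in unavailable:
            rows.append(
                {
                    "timepoint_months": t,
                    "estimate": np.nan,
                    "ci_lo": np.nan,
                    "ci_hi": np.nan,
                    "within": np.nan,
                    "between": np.nan,
                    "m": m,
                    "available": False,
                }
            )
            continue
        ests = [e for e, _ in per_tp[c]]
        vars_ = [v for _, v in per_tp[c]]
        pooled = rubin_pool(ests, vars_)
        rows.append(
            {
                "timepoint_months": t,
                "estimate": pooled["estimate"],
                "ci_lo": pooled["ci_lo"],
                "ci_hi": pooled["ci_hi"],
                "within": pooled["within"],
                "between": pooled["between"],
                "m": m,
                "available": True,
            }
        )
    return pd.DataFrame(rows)
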