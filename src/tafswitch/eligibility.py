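"""Underlying-cohort construction: switch-eligible dates, exclusions,
covariate assembly at the eligible date, and random-forest single imputation.

Cohort entry ("switch-eligible date") is the later of the date cumulative TDF
supply reaches 183 days (pills received — gaps between fills do not reset the
count) and the policy date on which TAF became available for PrEP.  Persons
who initiated TAF with under six months of TDF use, who carried a baseline
CKD / abnormal-lab flag, or who never entered the cohort before
disenrollment or study end are excluded, each with exactly one recorded
reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

log = logging.getLogger(__name__)

__all__ = [
    "compute_switch_eligible_date",
    "switch_eligible_dates",
    "apply_exclusions",
    "build_covariates",
    "impute_covariates_rf",
    "comorbidity_status",
    "EXCLUSION_REASONS",
]

EXCLUSION_REASONS = (
    "under_6mo_tdf_before_taf",
    "disenrolled",
    "baseline_ckd_or_lab_abnormality",
    "none",
)

SUPPLY_THRESHOLD_DAYS = 183
DEFAULT_POLICY_DATE = "2019-10-01"


def _threshold_day(dates: np.ndarray, supplies: np.ndarray, threshold: int):
    """Day (as datetime64[D]) on which cumulative supply reaches ``threshold``
    under sequential consumption with carryover, or None.

    Pills are consumed one per day starting at each fill or at exhaustion of
    the prior supply, whichever is later; the threshold date is the day the
    ``threshold``-th day of supply is consumed.
    """
    order = np.argsort(dates, kind="stable")
    dates, supplies = dates[order], supplies[order]
    cum = 0
    cover_end = None  # first day not covered by prior fills
    for d, s in zip(dates, supplies):
        start = d if cover_end is None or d > cover_end else cover_end
        if cum + s >= threshold:
            return start + np.timedelta64(int(threshold - cum), "D")
        cum += int(s)
        cover_end = start + np.timedelta64(int(s), "D")
    return None


def compute_switch_eligible_date(
    dispensings: pd.DataFrame,
    policy_date: str | np.datetime64 = DEFAULT_POLICY_DATE,
    end_date: str | np.datetime64 | None = None,
    threshold_days: int = SUPPLY_THRESHOLD_DAYS,
):
    """Switch-eligible date for one person's dispensing history, or None.

    Returns ``max(day cumulative TDF supply reaches threshold, policy_date)``;
    None if the threshold is never reached before ``end_date``
    (disenrollment or study end).  Invariant to row order.
    """
    tdf = dispensings.loc[dispensings["drug"] == "TDF"]
    if tdf.empty:
        return None
    dates = pd.to_datetime(tdf["date"]).to_numpy(dtype="datetime64[D]")
    supplies = tdf["days_supplied"].to_numpy(dtype=int)
    if np.any(supplies <= 0):
        raise ValueError("days_supplied must be positive")
    raw = _threshold_day(dates, supplies, threshold_days)
    if raw is None:
        return None
    elig = max(raw, np.datetime64(policy_date, "D"))
    if end_date is not None and elig > np.datetime64(end_date, "D"):
        return None  # cohort entry never occurs before disenrollment/study end
    return elig


def switch_eligible_dates(
    persons: pd.DataFrame,
    dispensings: pd.DataFrame,
    policy_date: str = DEFAULT_POLICY_DATE,
    study_end: str = "2022-06-30",
    threshold_days: int = SUPPLY_THRESHOLD_DAYS,
) -> pd.Series:
    """Vectorised wrapper: person_id -> eligible date (NaT if absent)."""
    end = np.datetime64(study_end, "D")
    disen = persons.set_index("person_id")["disenrollment_date"]
    out = {}
    for pid, grp in dispensings.groupby("person_id", sort=True):
        person_end = end
        d = disen.get(pid, pd.NaT)
        if pd.notna(d):
            person_end = min(end, np.datetime64(pd.Timestamp(d), "D"))
        e = compute_switch_eligible_date(grp, policy_date, person_end, threshold_days)
        out[pid] = pd.Timestamp(e) if e is not None else pd.NaT
    ser = pd.Series(out, name="switch_eligible_date")
    ser = ser.reindex(persons["person_id"])
    ser.index.name = "person_id"
    return ser


def apply_exclusions(
    persons: pd.DataFrame,
    dispensings: pd.DataFrame,
    labs: pd.DataFrame | None = None,
    policy_date: str = DEFAULT_POLICY_DATE,
    study_end: str = "2022-06-30",
    threshold_days: int = SUPPLY_THRESHOLD_DAYS,
) -> pd.DataFrame:
    """Label every person included/excluded with exactly one reason.

    Reason priority: TAF initiation with under ``threshold_days`` of prior
    TDF supply; baseline CKD / lab-abnormality flag; no cohort entry before
    disenrollment or study end (binned as ``disenrolled``).  Returns a frame
    with person_id, switch_eligible_date, included, exclusion_reason.
    """
    elig = switch_eligible_dates(persons, dispensings, policy_date, study_end, threshold_days)
    disp = dispensings.copy()
    disp["date"] = pd.to_datetime(disp["date"])
    first_taf = disp.loc[disp["drug"] == "TAF"].groupby("person_id")["date"].min()

    # cumulative TDF supply dispensed strictly before the first TAF date
    tdf = disp.loc[disp["drug"] == "TDF", ["person_id", "date", "days_supplied"]]
    supply_before_taf = (
        tdf.merge(first_taf.rename("taf_date"), on="person_id")
        .query("date < taf_date")
        .groupby("person_id")["days_supplied"]
        .sum()
    )

    rows = []
    for _, p in persons.iterrows():
        pid = p["person_id"]
        e = elig.get(pid, pd.NaT)
        # TAF initiation before cohort entry (which requires >= threshold days
        # of TDF supply and the policy date) keeps a person out of the cohort
        pre_entry_taf = pid in first_taf.index and (
            supply_before_taf.get(pid, 0) < threshold_days
            or pd.isna(e)
            or first_taf[pid] < e
        )
        if pre_entry_taf:
            reason = "under_6mo_tdf_before_taf"
        elif int(p.get("baseline_ckd_flag", 0)):
            reason = "baseline_ckd_or_lab_abnormality"
        elif pd.isna(e):
            reason = "disenrolled"
        else:
            reason = "none"
        rows.append(
            {
                "person_id": pid,
                "switch_eligible_date": e if reason == "none" else pd.NaT,
                "included": reason == "none",
                "exclusion_reason": reason,
            }
        )
    result = pd.DataFrame(rows)
    counts = result["exclusion_reason"].value_counts().to_dict()
    log.info("eligibility: %d persons, reasons %s", len(result), counts)
    return result


def _last_on_or_before(values: pd.DataFrame, value_col: str, at: pd.Series, lookback: int):
    """Most recent ``value_col`` on or before ``at`` within ``lookback`` days."""
    left = at.rename("at_date").reset_index()  # person_id, at_date
    left["at_date"] = pd.to_datetime(left["at_date"]).astype("datetime64[ns]")
    left = left.dropna(subset=["at_date"]).sort_values("at_date", kind="stable")
    right = values.copy()
    right["date"] = pd.to_datetime(right["date"]).astype("datetime64[ns]")
    right = right.sort_values("date", kind="stable")
    merged = pd.merge_asof(
        left,
        right,
        left_on="at_date",
        right_on="date",
        by="person_id",
        direction="backward",
        tolerance=pd.Timedelta(days=lookback),
    )
    return merged.set_index("person_id")[value_col]


def build_covariates(
    persons: pd.DataFrame,
    eligibility: pd.DataFrame,
    egfr: pd.DataFrame,
    weights: pd.DataFrame,
    comorbidities: pd.DataFrame,
    lookback_days: int = 365,
) -> pd.DataFrame:
    """Covariate profile at the switch-eligible date for included persons.

    Weight and eGFR "at" the eligible date are the most recent measurement on
    or before that date within ``lookback_days``; missing values remain NaN
    for downstream imputation.  Comorbidity onset dates are carried as
    columns so status can be resolved as a step function at any time.
    """
    inc = eligibility.loc[eligibility["included"]].copy()
    cov = inc[["person_id", "switch_eligible_date"]].merge(
        persons[
            [
                "person_id",
                "age_at_tdf_init",
                "sex",
                "race_ethnicity",
                "insurance",
                "ever_smoker",
                "first_tdf_dispense",
                "disenrollment_date",
            ]
        ],
        on="person_id",
        validate="one_to_one",
    )
    cov["switch_eligible_date"] = pd.to_datetime(cov["switch_eligible_date"])
    cov["year_eligibility_met"] = cov["switch_eligible_date"].dt.year
    at = cov.set_index("person_id")["switch_eligible_date"]
    cov = cov.set_index("person_id")
    cov["weight_at_eligible"] = _last_on_or_before(
        weights.rename(columns={"weight_kg": "val"}), "val", at, lookback_days
    )
    cov["egfr_at_eligible"] = _last_on_or_before(
        egfr.rename(columns={"egfr": "val"}), "val", at, lookback_days
    )
    com = comorbidities.copy()
    com["onset_date"] = pd.to_datetime(com["onset_date"])
    for cond in ("diabetes", "dyslipidemia", "hypertension"):
        onsets = com.loc[com["condition"] == cond].groupby("person_id")["onset_date"].min()
        cov[f"{cond}_onset"] = onsets.reindex(cov.index)
    return cov.reset_index()


def comorbidity_status(cov: pd.DataFrame, condition: str, at) -> np.ndarray:
    """Absorbing indicator: onset on or before ``at`` (scalar or per-row)."""
    onset = pd.to_datetime(cov[f"{condition}_onset"])
    at_ts = pd.to_datetime(pd.Series(at, index=cov.index) if np.ndim(at) == 0 else at)
    return ((onset.notna()) & (onset <= at_ts)).to_numpy(dtype=float)


@dataclass
class ImputationResult:
    completed: pd.DataFrame
    mask: pd.DataFrame  # True where a cell was imputed


def impute_covariates_rf(
    covariates: pd.DataFrame,
    seed: int = 0,
    columns: list[str] | None = None,
    n_estimators: int = 50,
    n_iter: int = 2,
) -> ImputationResult:
    """Single random-forest imputation (missForest-style) of covariate gaps.

    Missing cells in ``columns`` (default: every column with any NaN, except
    identifiers and dates) are filled by iterated random forests trained on
    the remaining covariates; observed cells are never altered.  Deterministic
    for a fixed seed.  A column that is entirely missing cannot be imputed
    and raises ``ValueError``.
    """
    df = covariates.copy()
    skip = {c for c in df.columns if c == "person_id" or "date" in c or c.endswith("_onset")}
    if columns is None:
        columns = [c for c in df.columns if c not in skip and df[c].isna().any()]
    for c in columns:
        if df[c].isna().all():
            raise ValueError(f"column {c!r} is entirely missing; cannot impute")
    mask = pd.DataFrame(False, index=df.index, columns=df.columns)
    for c in columns:
        mask[c] = df[c].isna()
    if not columns:
        return ImputationResult(df, mask)

    predictors = [c for c in df.columns if c not in skip]
    work = df[predictors].copy()
    cat_cols = [c for c in predictors if not pd.api.types.is_numeric_dtype(work[c])]
    for c in cat_cols:
        work[c] = pd.Categorical(work[c]).codes.astype(float)
        work.loc[work[c] < 0, c] = np.nan
    # initial fill: mean/mode
    init = work.copy()
    for c in predictors:
        fill = init[c].mode().iloc[0] if c in cat_cols else init[c].mean()
        init[c] = init[c].fillna(fill)
    rng = np.random.default_rng(seed)
    for _ in range(n_iter):
        for c in columns:
            miss = mask[c].to_numpy()
            if not miss.any():
                continue
            X_cols = [p for p in predictors if p != c]
            X_obs, y_obs = init.loc[~miss, X_cols], work.loc[~miss, c]
            X_mis = init.loc[miss, X_cols]
            rf_seed = int(rng.integers(0, 2**31 - 1))
            if c in cat_cols:
                model = RandomForestClassifier(
                    n_estimators=n_estimators, random_state=rf_seed, n_jobs=1
                )
                model.fit(X_obs, y_obs.astype(int))
                init.loc[miss, c] = model.predict(X_mis).astype(float)
            else:
                model = RandomForestRegressor(
                    n_estimators=n_estimators, random_state=rf_seed, n_jobs=1
                )
                model.fit(X_obs, y_obs)
                init.loc[miss, c] = model.predict(X_mis)
    for c in columns:
        miss = mask[c]
        if c in cat_cols:
            cats = pd.Categorical(df[c]).categories
            df.loc[miss, c] = cats[init.loc[miss, c].astype(int)]
        else:
            df.loc[miss, c] = init.loc[miss, c]
    n_imputed = int(mask.to_numpy().sum())
    log.info("rf imputation: filled %d cells in %s", n_imputed, columns)
    return ImputationResult(df, mask)
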