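"""Time-varying propensity-score risk-set matching.

The switch propensity is an extended Cox model on the hazard of switching
from TDF to TAF, fitted on the eligible cohort in counting-process layout
(time zero = switch-eligible date, intervals split at comorbidity onsets).
Matching then walks switch events in calendar order: at each event the risk
set — persons already eligible, still TDF-only on that date, and not yet
consumed by an earlier set — is scored with covariate values current at the
event date, and up to ``ratio`` nearest controls by absolute difference in
the Cox linear predictor are taken without replacement.  A person consumed
as a control who later switches is dropped from the switcher stream and
stays a nonswitcher, which is what makes the index-date assignment immune to
immortal-time bias: controls receive their matched switcher's
eligibility-to-switch interval added to their own eligible date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxTimeVaryingFitter
from lifelines.exceptions import ConvergenceError

log = logging.getLogger(__name__)

__all__ = [
    "TvpsModel",
    "encode_time_invariant",
    "build_counting_process",
    "fit_tvps_model",
    "sequential_match",
    "assign_index_dates",
    "standardized_mean_differences",
    "TIME_VARYING_COVARIATES",
]

RACE_REFERENCE = "White NH"
INSURANCE_REFERENCE = "commercial"
RACE_LEVELS = ("Asian NH", "Black NH", "Hispanic", "Other NH")
INSURANCE_LEVELS = ("Medicaid", "Medicare", "other")
TIME_VARYING_COVARIATES = ("diabetes", "dyslipidemia", "hypertension")


def encode_time_invariant(cov: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns for the time-invariant covariate list.

    Categorical covariates are dummy-coded against fixed references
    (race: White NH, insurance: commercial) so the encoding does not depend
    on which levels happen to be present.
    """
    out = pd.DataFrame(index=cov.index)
    out["age"] = cov["age_at_tdf_init"].astype(float)
    out["male"] = (cov["sex"] == "male").astype(float)
    out["ever_smoker"] = cov["ever_smoker"].astype(float)
    out["year_eligibility_met"] = cov["year_eligibility_met"].astype(float)
    out["weight_at_eligible"] = cov["weight_at_eligible"].astype(float)
    out["egfr_at_eligible"] = cov["egfr_at_eligible"].astype(float)
    for lvl in RACE_LEVELS:
        out[f"race_{lvl.replace(' ', '_')}"] = (cov["race_ethnicity"] == lvl).astype(float)
    for lvl in INSURANCE_LEVELS:
        out[f"insurance_{lvl}"] = (cov["insurance"] == lvl).astype(float)
    return out


@dataclass
class TvpsModel:
    """Fitted switch-hazard score.  Matching uses only differences of the
    linear predictor, so the baseline hazard never enters."""

    params: pd.Series  # coefficient per design column (incl. comorbidity indicators)
    dropped: list = field(default_factory=list)
    summary: pd.DataFrame | None = None

    def linear_predictor(self, design: pd.DataFrame, cov: pd.DataFrame, at_date) -> np.ndarray:
        """Score rows of ``design`` (+ comorbidity onsets in ``cov``) at a date."""
        lp = np.zeros(len(design))
        for name, beta in self.params.items():
            if name in TIME_VARYING_COVARIATES:
                onset = pd.to_datetime(cov[f"{name}_onset"])
                cur = ((onset.notna()) & (onset <= pd.Timestamp(at_date))).to_numpy(float)
                lp += beta * cur
            else:
                lp += beta * design[name].to_numpy(float)
        return lp


def build_counting_process(
    cov: pd.DataFrame,
    switch_dates: pd.Series,
    end_dates: pd.Series,
) -> pd.DataFrame:
    """Counting-process layout for the extended Cox fit.

    One or more rows per person: (id, start, stop, event, covariates), with
    time in days since the person's switch-eligible date and intervals split
    at comorbidity onsets.  ``switch_dates``/``end_dates`` are indexed by
    person_id; a switch on the eligible date itself contributes a half-day
    interval so the event is retained.
    """
    design = encode_time_invariant(cov)
    rows = []
    for i, (_, person) in enumerate(cov.iterrows()):
        pid = person["person_id"]
        elig = pd.Timestamp(person["switch_eligible_date"])
        sw = switch_dates.get(pid, pd.NaT)
        end = pd.Timestamp(end_dates[pid])
        has_event = pd.notna(sw) and pd.Timestamp(sw) <= end
        stop = (pd.Timestamp(sw) - elig).days if has_event else (end - elig).days
        if stop <= 0:
            stop = 0.5  # same-day switch: keep the event with a token interval
        cuts = [0.0]
        for cond in TIME_VARYING_COVARIATES:
            onset = person[f"{cond}_onset"]
            if pd.notna(onset):
                t = (pd.Timestamp(onset) - elig).days
                if 0 < t < stop:
                    cuts.append(float(t))
        cuts = sorted(set(cuts)) + [float(stop)]
        base = design.iloc[i].to_dict()
        for a, b in zip(cuts[:-1], cuts[1:]):
            row = dict(base)
            row.update(id=pid, start=a, stop=b, event=False)
            for cond in TIME_VARYING_COVARIATES:
                onset = person[f"{cond}_onset"]
                t = (pd.Timestamp(onset) - elig).days if pd.notna(onset) else np.inf
                row[cond] = float(t <= a)
            rows.append(row)
        if has_event:
            rows[-1]["event"] = True
    return pd.DataFrame(rows)


def fit_tvps_model(cp: pd.DataFrame, penalizer: float = 0.01) -> TvpsModel:
    """Maximum-partial-likelihood fit of the extended Cox switch model.

    Zero-variance covariates are dropped with a logged warning; no events or
    nonconvergence raise with the offending column named.  A small ridge
    penalizer (default 0.01) stabilises sparse dummy levels and is exposed in
    the pipeline config.
    """
    if cp.empty or not cp["event"].any():
        raise ValueError("TV-PS model unidentifiable: no switch events in the cohort")
    covar_cols = [c for c in cp.columns if c not in ("id", "start", "stop", "event")]
    dropped = [c for c in covar_cols if cp[c].nunique() <= 1]
    for c in dropped:
        log.warning("tvps: dropping zero-variance covariate %r", c)
    keep = [c for c in covar_cols if c not in dropped]
    ctv = CoxTimeVaryingFitter(penalizer=penalizer)
    try:
        ctv.fit(
            cp[["id", "start", "stop", "event"] + keep],
            id_col="id",
            event_col="event",
            start_col="start",
            stop_col="stop",
        )
    except ConvergenceError as err:
        raise ValueError(f"TV-PS model failed to converge: {err}") from err
    params = ctv.params_
    wild = params[params.abs() > 50]
    if not wild.empty:
        raise ValueError(
            f"TV-PS model shows separation in covariate(s) {list(wild.index)}"
        )
    log.info("tvps: fitted %d covariates on %d events", len(params), int(cp["event"].sum()))
    return TvpsModel(params=params, dropped=dropped, summary=ctv.summary)


def sequential_match(
    model: TvpsModel,
    cohort: pd.DataFrame,
    ratio: int = 4,
    seed: int = 0,
    caliper: float | None = None,
):
    """Iterative 1:``ratio`` matching without replacement in switch-date order.

    ``cohort`` has one row per eligible person with columns
    switch_eligible_date, switch_date (NaT for never), end_date, the encoded
    time-invariant design columns, and ``*_onset`` dates.  Same-day events
    and equal-distance ties are broken by a seeded random draw.

    Returns ``(matched_sets, info)`` where ``matched_sets`` is a long frame
    (set_id, switcher_id, switch_date, control_id, score_distance,
    control_rank) and ``info`` records reclassified and discarded switchers.
    """
    cohort = cohort.reset_index(drop=True)
    design = encode_time_invariant(cohort)
    rng = np.random.default_rng(seed)
    elig = pd.to_datetime(cohort["switch_eligible_date"]).to_numpy()
    sw = pd.to_datetime(cohort["switch_date"]).to_numpy()
    end = pd.to_datetime(cohort["end_date"]).to_numpy()

    is_event = ~pd.isna(sw)
    event_idx = np.flatnonzero(is_event)
    day_key = sw[event_idx].astype("datetime64[D]").astype(int)
    tiebreak = rng.random(len(event_idx))
    event_idx = event_idx[np.lexsort((tiebreak, day_key))]

    consumed = np.zeros(len(cohort), dtype=bool)
    used_as_control = np.zeros(len(cohort), dtype=bool)
    sets, reclassified, discarded = [], [], []
    set_id = 0
    for s in event_idx:
        e = sw[s]
        if used_as_control[s]:
            reclassified.append(cohort.at[s, "person_id"])
            continue
        if consumed[s]:  # defensive; switchers appear once in the stream
            continue
        risk = (
            (~consumed)
            & (elig <= e)
            & (end >= e)
            & (pd.isna(sw) | (sw > e))
        )
        risk[s] = False
        ridx = np.flatnonzero(risk)
        if len(ridx) == 0:
            discarded.append(cohort.at[s, "person_id"])
            log.info("match: switcher %s discarded (empty risk set)", cohort.at[s, "person_id"])
            continue
        pool = cohort.iloc[ridx]
        lp = model.linear_predictor(design.iloc[ridx], pool, e)
        lp_s = model.linear_predictor(design.iloc[[s]], cohort.iloc[[s]], e)[0]
        dist = np.abs(lp - lp_s)
        if caliper is not None:
            inside = dist <= caliper
            ridx, dist = ridx[inside], dist[inside]
            if len(ridx) == 0:
                discarded.append(cohort.at[s, "person_id"])
                log.info(
                    "match: switcher %s discarded (no control within caliper)",
                    cohort.at[s, "person_id"],
                )
                continue
        order = np.lexsort((rng.random(len(dist)), dist))[:ratio]
        chosen = ridx[order]
        consumed[s] = True
        consumed[chosen] = True
        used_as_control[chosen] = True
        for rank, (c, d) in enumerate(zip(chosen, dist[order]), start=1):
            sets.append(
                {
                    "set_id": set_id,
                    "switcher_id": cohort.at[s, "person_id"],
                    "switch_date": pd.Timestamp(e),
                    "control_id": cohort.at[c, "person_id"],
                    "score_distance": float(d),
                    "control_rank": rank,
                }
            )
        set_id += 1
    matched = pd.DataFrame(
        sets,
        columns=[
            "set_id",
            "switcher_id",
            "switch_date",
            "control_id",
            "score_distance",
            "control_rank",
        ],
    )
    info = {
        "n_switch_events": int(len(event_idx)),
        "n_matched_sets": set_id,
        "reclassified_switchers": reclassified,
        "discarded_switchers": discarded,
    }
    log.info(
        "match: %d sets from %d events (%d reclassified, %d discarded)",
        set_id,
        len(event_idx),
        len(reclassified),
        len(discarded),
    )
    return matched, info


def assign_index_dates(
    matched_sets: pd.DataFrame,
    cohort: pd.DataFrame,
    study_end: str = "2022-06-30",
) -> pd.DataFrame:
    """Interval-preserving index dates for the matched cohort.

    Switchers follow up from their switch date; each control follows up from
    their own eligible date plus the matched switcher's eligibility-to-switch
    interval, which equalises immortal time across arms.  Controls whose
    computed index date falls after their disenrollment or the study end are
    dropped (logged); a set losing all controls drops its switcher too.
    """
    info = cohort.set_index("person_id")
    elig = pd.to_datetime(info["switch_eligible_date"])
    end = pd.to_datetime(info["end_date"]).clip(upper=pd.Timestamp(study_end))
    rows = []
    dropped_controls = 0
    for sid, grp in matched_sets.groupby("set_id", sort=True):
        s = grp["switcher_id"].iloc[0]
        sw_date = pd.Timestamp(grp["switch_date"].iloc[0])
        interval = (sw_date - elig[s]).days
        controls = []
        for c in grp["control_id"]:
            idx_date = elig[c] + pd.Timedelta(days=interval)
            if idx_date > end[c]:
                dropped_controls += 1
                log.info("index: control %s dropped (index date beyond follow-up)", c)
                continue
            controls.append((c, idx_date))
        if not controls:
            log.info("index: set %s dropped (all controls beyond follow-up)", sid)
            continue
        rows.append(
            {
                "person_id": s,
                "arm": "switcher",
                "set_id": sid,
                "eligible_date": elig[s],
                "index_date": sw_date,
            }
        )
        for c, idx_date in controls:
            rows.append(
                {
                    "person_id": c,
                    "arm": "nonswitcher",
                    "set_id": sid,
                    "eligible_date": elig[c],
                    "index_date": idx_date,
                }
            )
    out = pd.DataFrame(
        rows, columns=["person_id", "arm", "set_id", "eligible_date", "index_date"]
    )
    if dropped_controls:
        log.info("index: dropped %d controls with out-of-window index dates", dropped_controls)
    return out


def standardized_mean_differences(
    treated: pd.DataFrame, control: pd.DataFrame, columns=None
) -> pd.Series:
    """Absolute standardized mean differences over design columns."""
    if columns is None:
        columns = [c for c in treated.columns if pd.api.types.is_numeric_dtype(treated[c])]
    out = {}
    for c in columns:
        t, u = treated[c].astype(float), control[c].astype(float)
        pooled = np.sqrt((t.var(ddof=1) + u.var(ddof=1)) / 2.0)
        out[c] = 0.0 if pooled == 0 or np.isnan(pooled) else abs(t.mean() - u.mean()) / pooled
    return pd.Series(out, name="smd")
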