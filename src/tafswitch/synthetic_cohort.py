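"""Synthetic EHR cohort generator for the TDF->TAF switching analysis.

Emulates the data-generating setting the pipeline assumes: adults initiating
TDF-based PrEP whose decision to switch to TAF depends on observed
confounders (older age, lower eGFR, comorbidity burden raise the switch
hazard), an underlying person-level eGFR trajectory with a negative drift on
TDF and a configurable true switch effect, irregular Poisson-process lab
visits thinned by a covariate-dependent (MAR) missingness model, and
treatment deviations (switch-back to TDF, late switching by never-switchers).

eGFR is simulated on the eGFR scale and inverted through the CKD-EPI 2021
equation, so the emitted lab table carries serum creatinine exactly as a real
EHR would; the pipeline must recompute eGFR itself.

All randomness flows from a single master seed.  Stream splitting is
documented in :data:`_STREAMS`: each named process draws from
``default_rng(SeedSequence([seed, stream_id]))`` so adding draws to one
process never perturbs another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .renal_metrics import egfr_ckdepi_2021, invert_egfr

__all__ = [
    "TrueEffect",
    "SimulationTruth",
    "LongitudinalTables",
    "generate_cohort",
    "inject_deviations",
    "RACE_CATEGORIES",
    "INSURANCE_CATEGORIES",
]

RACE_CATEGORIES = ("Asian NH", "Black NH", "Hispanic", "White NH", "Other NH")
INSURANCE_CATEGORIES = ("commercial", "Medicaid", "Medicare", "other")
CONDITIONS = ("diabetes", "dyslipidemia", "hypertension")

DAYS_PER_MONTH = 365.25 / 12.0

# named substreams of the master seed (SeedSequence([seed, id]))
_STREAMS = {
    "demographics": 0,
    "trajectory": 1,
    "comorbidity": 2,
    "switch": 3,
    "visits": 4,
    "missingness": 5,
    "dispensing": 6,
    "deviations": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class TrueEffect:
    """Piecewise-linear true switch effect, months since switch -> eGFR units.

    ``breakpoints`` are (month, effect) pairs with nondecreasing months;
    a repeated month encodes a right-continuous jump.  Values are held
    constant beyond the outermost breakpoints.
    """

    breakpoints: tuple = ((0.0, 0.0),)

    @classmethod
    def zero(cls) -> "TrueEffect":
        return cls(((0.0, 0.0),))

    @classmethod
    def step(cls, size: float, onset_month: float = 3.0) -> "TrueEffect":
        """Effect of ``size`` eGFR units from ``onset_month`` onward, 0 before."""
        return cls(((0.0, 0.0), (onset_month, 0.0), (onset_month, size)))

    def __call__(self, months):
        xs = np.array([b[0] for b in self.breakpoints], dtype=float)
        vs = np.array([b[1] for b in self.breakpoints], dtype=float)
        if np.any(np.diff(xs) < 0):
            raise ValueError("true-effect breakpoints must have nondecreasing months")
        m = np.asarray(months, dtype=float)
        # np.interp is right-continuous at repeated x, which encodes jumps
        out = np.interp(m, xs, vs)
        return float(out) if np.ndim(months) == 0 else out


def _default_confounding() -> dict:
    # log-hazard-ratio coefficients on the switch hazard.  Besides age, the
    # measured eligibility-date eGFR and comorbidity burden, switching is
    # modestly more likely for smokers, Medicare/Medicaid members and
    # non-Hispanic White persons, mirroring the covariate imbalance
    # observed between switchers and nonswitchers in insured PrEP cohorts
    return {
        "age_per_10y": 0.4,
        "egfr_per_15": -0.4,
        "comorbidity": 0.3,
        "smoker": 0.25,
        "medicare_medicaid": 0.7,
        "race_white": 0.25,
    }


def _default_missingness() -> dict:
    # logit P(lab observed at a visit); centered covariates as documented below
    return {"intercept": 0.7, "age_per_10y": -0.15, "egfr_per_15": 0.35}


def _default_deviations() -> dict:
    # per-year hazards; modest, matching the rarity of observed crossover
    return {"switch_back": 0.06, "late_switch": 0.03}


def _default_race_probs() -> dict:
    return {"Asian NH": 0.11, "Black NH": 0.05, "Hispanic": 0.35, "White NH": 0.40, "Other NH": 0.09}


def _default_insurance_probs() -> dict:
    return {"commercial": 0.80, "Medicaid": 0.05, "Medicare": 0.03, "other": 0.12}


def _default_comorbidity_rates() -> dict:
    return {"diabetes": 0.012, "dyslipidemia": 0.008, "hypertension": 0.010}


@dataclass
class SimulationTruth:
    """Full parameterisation of the synthetic cohort; recorded verbatim in the
    output manifest so every run is reproducible from its manifest alone."""

    n_persons: int = 600
    seed: int = 0
    # calendar window for TDF initiation; follow-up runs to study_end
    enrollment_start: str = "2016-01-01"
    enrollment_end: str = "2021-06-30"
    study_end: str = "2022-06-30"
    policy_date: str = "2019-10-01"
    true_effect: TrueEffect = field(default_factory=TrueEffect.zero)
    # log-hazard-ratio coefficients on the switch hazard (units in key names)
    confounding_strength: dict = field(default_factory=_default_confounding)
    switch_base_hazard: float = 0.05  # events / person-year at covariate center
    baseline_egfr_mean: float = 97.0
    baseline_egfr_sd: float = 14.0
    egfr_age_slope: float = 0.6  # eGFR units lost per year of age above 38
    egfr_slope_per_year: float = -1.5  # drift on TDF
    residual_sd: float = 6.0  # lab measurement noise, eGFR units
    visit_rate: float = 4.0  # lab visits / person-year (quarterly PrEP monitoring)
    missingness_model: dict = field(default_factory=_default_missingness)
    deviation_rates: dict = field(default_factory=_default_deviations)
    age_mean: float = 38.0
    age_sd: float = 11.0
    male_fraction: float = 0.98
    race_probs: dict = field(default_factory=_default_race_probs)
    insurance_probs: dict = field(default_factory=_default_insurance_probs)
    smoker_prob: float = 0.25
    weight_mean: float = 85.0
    weight_sd: float = 16.0
    weight_missing_prob: float = 0.10  # persons with no weight record near baseline
    comorbidity_rates: dict = field(default_factory=_default_comorbidity_rates)
    comorbidity_age_coef: float = 0.04
    baseline_ckd_prob: float = 0.03
    disenroll_rate: float = 0.05  # / person-year
    early_taf_prob: float = 0.03  # initiate TAF with <6 months of TDF (excluded later)

    def validate(self) -> None:
        for name, probs, cats in (
            ("race_probs", self.race_probs, RACE_CATEGORIES),
            ("insurance_probs", self.insurance_probs, INSURANCE_CATEGORIES),
        ):
            if set(probs) != set(cats):
                raise ValueError(f"{name} must have exactly the categories {cats}")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} frequencies must sum to 1 (got {total})")
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        for rate_name in ("visit_rate", "residual_sd", "baseline_egfr_sd"):
            if getattr(self, rate_name) < 0:
                raise ValueError(f"{rate_name} must be nonnegative")

    def manifest(self) -> dict:
        out = dataclasses.asdict(self)
        out["true_effect"] = {"breakpoints": [list(b) for b in self.true_effect.breakpoints]}
        out["true_effect_at_0"] = float(self.true_effect(0.0))
        return out

    @classmethod
    def from_manifest(cls, manifest: dict) -> "SimulationTruth":
        data = dict(manifest)
        data.pop("true_effect_at_0", None)
        eff = data.get("true_effect")
        if isinstance(eff, dict):
            data["true_effect"] = TrueEffect(tuple(tuple(b) for b in eff["breakpoints"]))
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})


@dataclass
class LongitudinalTables:
    dispensings: pd.DataFrame  # person_id, date, drug in {TDF, TAF}, days_supplied
    labs: pd.DataFrame  # person_id, date, serum_creatinine
    weights: pd.DataFrame  # person_id, date, weight_kg
    comorbidity_onsets: pd.DataFrame  # person_id, condition, onset_date

    def copy(self) -> "LongitudinalTables":
        return LongitudinalTables(
            self.dispensings.copy(),
            self.labs.copy(),
            self.weights.copy(),
            self.comorbidity_onsets.copy(),
        )


def _truncnorm(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, bad.sum())
        bad = (x < lo) | (x > hi)
    return x


def _fill_schedule(rng, start: int, stop: int, fill_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Dispense dates (day offsets) and supplies from ``start`` until ``stop``.

    Fills are consumed sequentially; the next fill arrives at exhaustion,
    occasionally with a short gap (pills received, not persistence, drive
    eligibility downstream, so gaps are harmless realism).
    """
    dates, supplies = [], []
    t = start
    while t < stop:
        dates.append(t)
        supplies.append(fill_len)
        gap = 0 if rng.random() < 0.8 else int(rng.integers(1, 21))
        t = t + fill_len + gap
    return np.array(dates, dtype=int), np.array(supplies, dtype=int)


def generate_cohort(truth: SimulationTruth):
    """Generate (persons, LongitudinalTables, manifest) for ``truth``.

    Deterministic given ``truth`` (byte-identical tables for equal seeds).
    The manifest records every generator parameter plus derived per-person
    ground truth needed by recovery tests (true switch dates, latent
    intercepts).
    """
    truth.validate()
    n = truth.n_persons
    epoch = np.datetime64("2014-01-01")

    def day(date_str):
        return int((np.datetime64(date_str) - epoch).astype(int))

    enroll_lo, enroll_hi = day(truth.enrollment_start), day(truth.enrollment_end)
    study_end = day(truth.study_end)
    policy = day(truth.policy_date)

    rng_demo = _rng(truth.seed, "demographics")
    rng_traj = _rng(truth.seed, "trajectory")
    rng_com = _rng(truth.seed, "comorbidity")
    rng_sw = _rng(truth.seed, "switch")
    rng_vis = _rng(truth.seed, "visits")
    rng_miss = _rng(truth.seed, "missingness")
    rng_disp = _rng(truth.seed, "dispensing")

    # ---- person-level attributes -------------------------------------------------
    person_id = np.array([f"P{i:05d}" for i in range(n)])
    age = _truncnorm(rng_demo, truth.age_mean, truth.age_sd, 18.0, 80.0, n).round(1)
    sex = np.where(rng_demo.random(n) < truth.male_fraction, "male", "female")
    race = rng_demo.choice(
        RACE_CATEGORIES, size=n, p=[truth.race_probs[c] for c in RACE_CATEGORIES]
    )
    insurance = rng_demo.choice(
        INSURANCE_CATEGORIES, size=n, p=[truth.insurance_probs[c] for c in INSURANCE_CATEGORIES]
    )
    smoker = rng_demo.random(n) < truth.smoker_prob
    baseline_ckd = rng_demo.random(n) < truth.baseline_ckd_prob
    first_tdf = rng_demo.integers(enroll_lo, enroll_hi + 1, n)
    disenroll_offset = rng_demo.exponential(365.25 / truth.disenroll_rate, n).astype(int)
    disenroll = first_tdf + disenroll_offset
    enroll_end = np.minimum(disenroll, study_end)
    weight0 = _truncnorm(rng_demo, truth.weight_mean, truth.weight_sd, 40.0, 180.0, n).round(1)
    weight_unmeasured = rng_demo.random(n) < truth.weight_missing_prob

    # ---- latent eGFR trajectory --------------------------------------------------
    b0 = (
        truth.baseline_egfr_mean
        - truth.egfr_age_slope * (age - 38.0)
        + rng_traj.normal(0.0, truth.baseline_egfr_sd, n)
    )
    b0 = np.clip(b0, 20.0, 160.0)

    # ---- comorbidity onsets (exponential hazards scaled by age) ------------------
    com_rows = []
    onset_day = {c: np.full(n, np.iinfo(np.int64).max, dtype=np.int64) for c in CONDITIONS}
    for cond in CONDITIONS:
        base = truth.comorbidity_rates[cond]
        rate = base * np.exp(truth.comorbidity_age_coef * (age - 40.0))  # / yr
        prevalent = rng_com.random(n) < -np.expm1(-rate * np.maximum(age - 20.0, 0.0))
        incident_yrs = rng_com.exponential(1.0 / np.maximum(rate, 1e-9))
        for i in range(n):
            if prevalent[i]:
                d = int(first_tdf[i])
            else:
                d = int(first_tdf[i] + incident_yrs[i] * 365.25)
                if d > enroll_end[i]:
                    continue
            onset_day[cond][i] = d
            com_rows.append((person_id[i], cond, d))

    # ---- visit schedule and observed (pre-switch-effect) eGFR -------------------
    # Visits follow a person-level Poisson process; each visit's lab is observed
    # with a probability from the MAR missingness model evaluated on the
    # underlying (no-switch) trajectory.  A monitoring lab is planted at the
    # switch-eligible date (PrEP renewal requires labs), and the switch hazard
    # below depends on that *measured* value — confounding acts through
    # covariates the downstream analysis can observe, which is the identifying
    # assumption of the matching + adjustment design.
    miss = truth.missingness_model
    elig_gen = np.maximum(first_tdf + 183, policy)
    visit_days: list[np.ndarray] = []
    visit_obs: list[np.ndarray] = []
    visit_noise: list[np.ndarray] = []
    egfr_elig_obs = np.full(n, np.nan)

    def latent_pre(i, d):
        return b0[i] + truth.egfr_slope_per_year * (d - first_tdf[i]) / 365.25

    for i in range(n):
        span_days = int(enroll_end[i] - first_tdf[i])
        if span_days <= 0:
            visit_days.append(np.empty(0, dtype=int))
            visit_obs.append(np.empty(0, dtype=bool))
            visit_noise.append(np.empty(0))
            continue
        n_visits = rng_vis.poisson(truth.visit_rate * span_days / 365.25)
        vd = np.sort(rng_vis.integers(0, span_days, n_visits)) + int(first_tdf[i])
        noise = rng_vis.normal(0.0, truth.residual_sd, n_visits)
        pre = latent_pre(i, vd.astype(float)) if n_visits else np.empty(0)
        lp = (
            miss["intercept"]
            + miss["age_per_10y"] * (age[i] - 38.0) / 10.0
            + miss["egfr_per_15"] * (pre - 95.0) / 15.0
        )
        obs = rng_miss.random(n_visits) < 1.0 / (1.0 + np.exp(-lp))
        if elig_gen[i] < enroll_end[i]:
            # planted monitoring lab at the eligible date, always observed
            e_noise = rng_vis.normal(0.0, truth.residual_sd)
            vd = np.append(vd, int(elig_gen[i]))
            noise = np.append(noise, e_noise)
            obs = np.append(obs, True)
            order = np.argsort(vd, kind="stable")
            vd, noise, obs = vd[order], noise[order], obs[order]
            egfr_elig_obs[i] = latent_pre(i, float(elig_gen[i])) + e_noise
        visit_days.append(vd)
        visit_obs.append(obs)
        visit_noise.append(noise)

    # ---- switch process ----------------------------------------------------------
    # hazard starts at the switch-eligible date and depends on age, the measured
    # eGFR at that date, and current comorbidity count (time-varying)
    conf = truth.confounding_strength
    switch_day = np.full(n, -1, dtype=np.int64)  # -1 = never
    step = 30
    for i in range(n):
        if truth.early_taf_prob > 0 and rng_sw.random() < truth.early_taf_prob:
            d = int(first_tdf[i] + rng_sw.integers(30, 150))
            if d < enroll_end[i]:
                switch_day[i] = d
            continue
        t = int(elig_gen[i])
        if t >= enroll_end[i]:
            continue
        lp_const = (
            np.log(truth.switch_base_hazard)
            + conf["age_per_10y"] * (age[i] - 38.0) / 10.0
            + conf["egfr_per_15"] * (egfr_elig_obs[i] - 95.0) / 15.0
            + conf.get("smoker", 0.0) * float(smoker[i])
            + conf.get("medicare_medicaid", 0.0) * float(insurance[i] in ("Medicare", "Medicaid"))
            + conf.get("race_white", 0.0) * float(race[i] == "White NH")
            + conf.get("weight_per_10kg", 0.0) * (weight0[i] - 85.0) / 10.0
        )
        while t < enroll_end[i]:
            ncom = sum(onset_day[c][i] <= t for c in CONDITIONS)
            lam = np.exp(lp_const + conf["comorbidity"] * ncom)
            p = -np.expm1(-lam * step / 365.25)
            if rng_sw.random() < p:
                switch_day[i] = t + int(rng_sw.integers(0, step))
                switch_day[i] = min(switch_day[i], int(enroll_end[i]) - 1)
                break
            t += step

    # ---- dispensings -------------------------------------------------------------
    disp_rows = []
    fill_len = np.where(rng_disp.random(n) < 0.7, 30, 90)
    for i in range(n):
        stop_tdf = switch_day[i] if switch_day[i] >= 0 else enroll_end[i]
        d, s = _fill_schedule(rng_disp, int(first_tdf[i]), int(stop_tdf), int(fill_len[i]))
        disp_rows.extend(zip([person_id[i]] * len(d), d, ["TDF"] * len(d), s))
        if switch_day[i] >= 0:
            d, s = _fill_schedule(rng_disp, int(switch_day[i]), int(enroll_end[i]), int(fill_len[i]))
            disp_rows.extend(zip([person_id[i]] * len(d), d, ["TAF"] * len(d), s))

    # ---- emit labs (with post-switch effect applied) and weights -----------------
    lab_rows, weight_rows = [], []
    for i in range(n):
        for vd, observed, noise in zip(visit_days[i], visit_obs[i], visit_noise[i]):
            if observed:
                egfr_obs = latent_pre(i, float(vd)) + noise
                if switch_day[i] >= 0 and vd >= switch_day[i]:
                    egfr_obs += truth.true_effect((vd - switch_day[i]) / DAYS_PER_MONTH)
                egfr_obs = max(egfr_obs, 8.0)
                age_at_lab = age[i] + (vd - first_tdf[i]) / 365.25
                scr = invert_egfr(egfr_obs, age_at_lab, str(sex[i]))
                lab_rows.append((person_id[i], int(vd), round(float(scr), 3)))
            if not weight_unmeasured[i] and rng_vis.random() < 0.6:
                w = weight0[i] + 0.2 * (vd - first_tdf[i]) / 365.25 + rng_vis.normal(0, 2.0)
                weight_rows.append((person_id[i], int(vd), round(float(w), 1)))

    def to_date(days):
        return epoch + np.asarray(days, dtype="timedelta64[D]")

    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "age_at_tdf_init": age,
            "sex": sex,
            "race_ethnicity": race,
            "insurance": insurance,
            "ever_smoker": smoker.astype(int),
            "first_tdf_dispense": to_date(first_tdf),
            "disenrollment_date": np.where(
                disenroll <= study_end, to_date(disenroll), np.datetime64("NaT")
            ),
            "baseline_ckd_flag": baseline_ckd.astype(int),
        }
    )
    dispensings = pd.DataFrame(
        disp_rows, columns=["person_id", "date", "drug", "days_supplied"]
    )
    dispensings["date"] = to_date(dispensings["date"].to_numpy())
    labs = pd.DataFrame(lab_rows, columns=["person_id", "date", "serum_creatinine"])
    labs["date"] = to_date(labs["date"].to_numpy(dtype=int) if len(labs) else [])
    weights = pd.DataFrame(weight_rows, columns=["person_id", "date", "weight_kg"])
    weights["date"] = to_date(weights["date"].to_numpy(dtype=int) if len(weights) else [])
    comorbidities = pd.DataFrame(com_rows, columns=["person_id", "condition", "onset_date"])
    comorbidities["onset_date"] = to_date(
        comorbidities["onset_date"].to_numpy(dtype=int) if len(comorbidities) else []
    )
    # normalise all date columns to pandas ns-resolution timestamps
    for df, cols in (
        (persons, ["first_tdf_dispense", "disenrollment_date"]),
        (dispensings, ["date"]),
        (labs, ["date"]),
        (weights, ["date"]),
        (comorbidities, ["onset_date"]),
    ):
        for c in cols:
            df[c] = pd.to_datetime(df[c]).astype("datetime64[ns]")

    manifest = truth.manifest()
    manifest["ground_truth"] = {
        "true_switch_day": {
            str(person_id[i]): (
                str(to_date(switch_day[i]).astype("datetime64[D]")) if switch_day[i] >= 0 else None
            )
            for i in range(n)
        },
        "latent_intercept": {str(person_id[i]): float(b0[i]) for i in range(n)},
        "egfr_at_eligible_observed": {
            str(person_id[i]): (
                float(egfr_elig_obs[i]) if np.isfinite(egfr_elig_obs[i]) else None
            )
            for i in range(n)
        },
    }
    tables = LongitudinalTables(dispensings, labs, weights, comorbidities)
    return persons, tables, manifest


def inject_deviations(
    tables: LongitudinalTables,
    truth: SimulationTruth,
    persons: pd.DataFrame | None = None,
) -> LongitudinalTables:
    """Overlay treatment deviations, consistently in exposure AND outcome.

    Switch-back: each switcher reverts to TDF after an exponential waiting
    time (``deviation_rates['switch_back']`` / year) from their TAF start;
    TAF fills after the revert date become TDF fills, and their labs after
    the revert date have the switch effect removed (immediate washout).
    Late switching: each never-switcher starts TAF after an exponential
    waiting time (``deviation_rates['late_switch']`` / year) measured from
    roughly one year after their eligible date; their later TDF fills become
    TAF and their labs gain the switch effect from the new start.  Lab
    adjustment goes through the exact eGFR <-> creatinine round trip, so the
    emitted table stays on the creatinine scale.

    ``persons`` (for age and sex at the lab date) is required when the
    effect is nonzero and any deviation fires.  With both rates zero the
    input is returned unchanged.
    """
    rates = truth.deviation_rates
    sb, ls = float(rates.get("switch_back", 0.0)), float(rates.get("late_switch", 0.0))
    out = tables.copy()
    if sb <= 0 and ls <= 0:
        return out
    rng = _rng(truth.seed, "deviations")
    disp = out.dispensings
    labs = out.labs
    day0 = pd.Timestamp("2014-01-01")
    disp_day = (pd.to_datetime(disp["date"]) - day0).dt.days
    lab_day = (pd.to_datetime(labs["date"]) - day0).dt.days if len(labs) else pd.Series(dtype=int)
    first_taf = disp_day.where(disp["drug"] == "TAF").groupby(disp["person_id"]).min()
    first_any = disp_day.groupby(disp["person_id"]).min()
    last_day = disp_day.groupby(disp["person_id"]).max()
    demo = (
        persons.set_index("person_id")[["sex", "age_at_tdf_init", "first_tdf_dispense"]]
        if persons is not None
        else None
    )
    new_drug = disp["drug"].copy()
    new_scr = labs["serum_creatinine"].astype(float).copy()

    def shift_labs(pid, from_day, taf_start_day, sign):
        """Add (+1) or remove (-1) the switch effect on labs from ``from_day``."""
        if demo is None:
            raise ValueError("persons table required to adjust outcomes for deviations")
        sel = (labs["person_id"] == pid) & (lab_day >= from_day)
        if not sel.any():
            return
        row = demo.loc[pid]
        elapsed = (lab_day[sel] - (pd.Timestamp(row["first_tdf_dispense"]) - day0).days) / 365.25
        age = row["age_at_tdf_init"] + elapsed.to_numpy(float)
        egfr = egfr_ckdepi_2021(new_scr[sel].to_numpy(float), age, str(row["sex"]))
        delta = truth.true_effect((lab_day[sel].to_numpy(float) - taf_start_day) / DAYS_PER_MONTH)
        shifted = np.maximum(egfr + sign * delta, 8.0)
        new_scr[sel] = np.round(invert_egfr(shifted, age, str(row["sex"])), 3)

    for pid in sorted(first_any.index):
        rows = disp["person_id"] == pid
        if pid in first_taf.index and pd.notna(first_taf[pid]):
            if sb > 0:
                revert = int(first_taf[pid] + rng.exponential(365.25 / sb))
                mask = rows & (disp["drug"] == "TAF") & (disp_day >= revert)
                if revert < last_day[pid] and mask.any():
                    new_drug[mask] = "TDF"
                    # deviation takes effect at the first rewritten fill
                    revert_fill = int(disp_day[mask].min())
                    shift_labs(pid, revert_fill, float(first_taf[pid]), sign=-1)
        elif ls > 0:
            start = int(first_any[pid] + 183 + 365 + rng.exponential(365.25 / ls))
            mask = rows & (disp_day >= start)
            if start < last_day[pid] and mask.any():
                new_drug[mask] = "TAF"
                start_fill = int(disp_day[mask].min())
                shift_labs(pid, start_fill, float(start_fill), sign=+1)
    out.dispensings = disp.assign(drug=new_drug)
    out.labs = labs.assign(serum_creatinine=new_scr)
    return out
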