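"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tafswitch.synthetic_cohort import INSURANCE_CATEGORIES, RACE_CATEGORIES
from tafswitch.tvps_matching import TIME_VARYING_COVARIATES, encode_time_invariant

# --------------------------------------------------------------------------
# constructed long-format outcome datasets drawn from the mixed model's own
# generative process (known fixed effects, random intercepts, residual noise)
# --------------------------------------------------------------------------


def make_outcome_dataset(
    n_sets: int = 15,
    controls_per_set: int = 3,
    effect: float = 3.0,
    seed: int = 0,
    sigma: float = 1.0,
    tau_u: float = 3.0,
    tau_v: float = 1.0,
    obs_per_person: tuple = (3, 7),
    max_month: float = 18.0,
    egfr_coef: float = 0.2,
    time_slope: float = -0.1,
    diabetes_effect: float = 0.0,
) -> pd.DataFrame:
    """Long-format outcome dataset with a constant additive switch effect.

    ``diabetes_effect`` adds a person-level covariate ("diabetes") that
    shifts the outcome but is NOT part of the outcome model's fixed-effect
    list — used to study missingness mechanisms the model does not adjust
    for.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    index0 = pd.Timestamp("2020-06-01")
    for s in range(n_sets):
        v = rng.normal(0, tau_v)
        for arm in ["switcher"] + ["nonswitcher"] * controls_per_set:
            u = rng.normal(0, tau_u)
            age = rng.uniform(22, 65)
            egfr_idx = rng.normal(95, 12)
            diabetes = float(rng.random() < 0.3)
            base = {
                "person_id": f"T{pid:04d}",
                "set_id": s,
                "arm": arm,
                "age": age,
                "male": float(rng.random() < 0.95),
                "insurance": rng.choice(INSURANCE_CATEGORIES),
                "race_ethnicity": rng.choice(RACE_CATEGORIES),
                "ever_smoker": float(rng.random() < 0.25),
                "weight_at_index": rng.normal(85, 15),
                "egfr_at_index": egfr_idx,
                "egfr_at_eligible": egfr_idx + rng.normal(0, 3),
                "duration_tdf_to_eligible": rng.uniform(200, 1200),
                "hypertension_at_index": float(rng.random() < 0.1),
                "diabetes": diabetes,
            }
            k = rng.integers(obs_per_person[0], obs_per_person[1] + 1)
            months = np.sort(rng.uniform(0.25, max_month, k))
            for m in months:
                y = (
                    90.0
                    + effect * (arm == "switcher")
                    + egfr_coef * (egfr_idx - 95.0)
                    + time_slope * m
                    + diabetes_effect * diabetes
                    + u
                    + v
                    + rng.normal(0, sigma)
                )
                rows.append(
                    {
                        **base,
                        "months_since_index": m,
                        "egfr": y,
                        "date": index0 + pd.Timedelta(days=int(m * 30.4375)),
                    }
                )
            pid += 1
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# independent brute-force oracle for date-ordered greedy risk-set matching
# --------------------------------------------------------------------------


def oracle_sequential_match(params: pd.Series, cohort: pd.DataFrame, ratio: int = 4):
    """Exhaustive date-ordered greedy matching, written independently of the
    implementation: explicit per-person eligibility scans and per-covariate
    score accumulation.  Assumes distinct switch dates and distinct score
    distances (no tie-breaking required)."""
    people = cohort.to_dict("records")
    events = sorted(
        (p for p in people if not pd.isna(p["switch_date"])),
        key=lambda p: pd.Timestamp(p["switch_date"]),
    )

    def score(person, at):
        total = 0.0
        design = encode_time_invariant(pd.DataFrame([person]))
        for name, beta in params.items():
            if name in TIME_VARYING_COVARIATES:
                onset = person.get(f"{name}_onset")
                val = float(pd.notna(onset) and pd.Timestamp(onset) <= pd.Timestamp(at))
            else:
                val = float(design[name].iloc[0])
            total += beta * val
        return total

    consumed, used_as_control = set(), set()
    sets = []
    for ev in events:
        sid = ev["person_id"]
        e = pd.Timestamp(ev["switch_date"])
        if sid in used_as_control:
            continue
        candidates = []
        for p in people:
            pid = p["person_id"]
            if pid == sid or pid in consumed:
                continue
            if pd.Timestamp(p["switch_eligible_date"]) > e:
                continue
            if pd.Timestamp(p["end_date"]) < e:
                continue
            if not pd.isna(p["switch_date"]) and pd.Timestamp(p["switch_date"]) <= e:
                continue
            candidates.append((abs(score(p, e) - score(ev, e)), pid))
        if not candidates:
            continue
        chosen = [pid for _, pid in sorted(candidates)[:ratio]]
        consumed.add(sid)
        consumed.update(chosen)
        used_as_control.update(chosen)
        sets.append((sid, tuple(chosen)))
    return sets


def random_small_cohort(rng: np.random.Generator, n_max: int = 10) -> pd.DataFrame:
    """Random toy cohort (n <= 10) with distinct dates and continuous scores."""
    n = int(rng.integers(3, n_max + 1))
    base = pd.Timestamp("2020-01-01")
    elig_days = rng.choice(200, size=n, replace=False)
    rows = []
    switch_pool = rng.choice(np.arange(250, 600), size=n, replace=False)
    for i in range(n):
        has_switch = rng.random() < 0.5
        end = base + pd.Timedelta(days=int(700 + rng.integers(0, 200)))
        onset = (
            base + pd.Timedelta(days=int(rng.integers(0, 600)))
            if rng.random() < 0.4
            else pd.NaT
        )
        rows.append(
            {
                "person_id": f"R{i}",
                "switch_eligible_date": base + pd.Timedelta(days=int(elig_days[i])),
                "switch_date": (
                    base + pd.Timedelta(days=int(switch_pool[i])) if has_switch else pd.NaT
                ),
                "end_date": end,
                "age_at_tdf_init": rng.uniform(20, 70),
                "sex": rng.choice(["male", "female"]),
                "race_ethnicity": rng.choice(RACE_CATEGORIES),
                "insurance": rng.choice(INSURANCE_CATEGORIES),
                "ever_smoker": int(rng.random() < 0.3),
                "year_eligibility_met": 2020,
                "weight_at_eligible": rng.uniform(55, 120),
                "egfr_at_eligible": rng.uniform(60, 130),
                "diabetes_onset": onset,
                "dyslipidemia_onset": pd.NaT,
                "hypertension_onset": pd.NaT,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rng_session():
    return np.random.default_rng(20240917)
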