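"""CKD-EPI 2021 creatinine eGFR: forward evaluation and exact inversion.

All renal outcomes in this package are expressed as estimated glomerular
filtration rate (eGFR, mL/min/1.73 m^2) computed from serum creatinine, age
and sex with the race-free CKD-EPI 2021 creatinine equation:

    eGFR = 142 * min(Scr/kappa, 1)^alpha * max(Scr/kappa, 1)^-1.200
               * 0.9938^age * (1.012 if female)

with kappa = 0.7 (female) / 0.9 (male) and alpha = -0.241 (female) /
-0.302 (male).  The equation is strictly decreasing in creatinine, so it
inverts in closed form; the inverse is used by the cohort simulator to emit
creatinine values whose recomputed eGFR equals a simulated latent trajectory.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["egfr_ckdepi_2021", "invert_egfr", "egfr_table", "SCR_RANGE"]

_SCALE = 142.0
_AGE_BASE = 0.9938
_FEMALE_FACTOR = 1.012
_KAPPA_F, _KAPPA_M = 0.7, 0.9
_ALPHA_F, _ALPHA_M = -0.241, -0.302
_EXP_HIGH = -1.200

#: plausible serum-creatinine range (mg/dL); inversion targets mapping outside
#: this bracket are treated as out of the attainable range.
SCR_RANGE = (0.05, 20.0)


def _female_mask(sex, shape) -> np.ndarray:
    sex_arr = np.broadcast_to(np.asarray(sex, dtype=object), shape)
    valid = np.isin(sex_arr, ("male", "female"))
    if not valid.all():
        bad = np.unique(sex_arr[~valid])
        raise ValueError(f"sex must be 'male' or 'female', got {bad!r}")
    return sex_arr == "female"


def egfr_ckdepi_2021(scr, age, sex):
    """Race-free CKD-EPI 2021 creatinine eGFR.

    Parameters
    ----------
    scr : float or array-like
        Serum creatinine, mg/dL.  Must be > 0.
    age : float or array-like
        Age in years.  Adults only (>= 18).
    sex : str or array-like
        ``"male"`` or ``"female"``.

    Returns
    -------
    float or ndarray
        eGFR in mL/min/1.73 m^2.
    """
    scr_a = np.asarray(scr, dtype=float)
    age_a = np.asarray(age, dtype=float)
    scalar = scr_a.ndim == 0 and age_a.ndim == 0 and np.ndim(sex) == 0
    scr_a, age_a = np.atleast_1d(scr_a), np.atleast_1d(age_a)
    scr_a, age_a = np.broadcast_arrays(scr_a, age_a)
    if not np.all(np.isfinite(scr_a)) or np.any(scr_a <= 0):
        raise ValueError("serum creatinine must be finite and > 0")
    if not np.all(np.isfinite(age_a)) or np.any(age_a < 18):
        raise ValueError("age must be finite and >= 18 (adult equation)")
    female = _female_mask(sex, scr_a.shape)
    kappa = np.where(female, _KAPPA_F, _KAPPA_M)
    alpha = np.where(female, _ALPHA_F, _ALPHA_M)
    ratio = scr_a / kappa
    egfr = (
        _SCALE
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** _EXP_HIGH
        * _AGE_BASE**age_a
        * np.where(female, _FEMALE_FACTOR, 1.0)
    )
    return float(egfr[0]) if scalar else egfr


def invert_egfr(target_egfr, age, sex):
    """Serum creatinine (mg/dL) whose CKD-EPI 2021 eGFR equals ``target_egfr``.

    The equation is a continuous, strictly decreasing piecewise power law in
    creatinine, so each branch inverts algebraically.  Targets whose solution
    falls outside the plausible creatinine range :data:`SCR_RANGE` raise
    ``ValueError`` (unattainable for that age/sex).
    """
    tgt = np.asarray(target_egfr, dtype=float)
    age_a = np.asarray(age, dtype=float)
    scalar = tgt.ndim == 0 and age_a.ndim == 0 and np.ndim(sex) == 0
    tgt, age_a = np.atleast_1d(tgt), np.atleast_1d(age_a)
    tgt, age_a = np.broadcast_arrays(tgt, age_a)
    if not np.all(np.isfinite(tgt)) or np.any(tgt <= 0):
        raise ValueError("target eGFR must be finite and > 0")
    if np.any(age_a < 18):
        raise ValueError("age must be >= 18")
    female = _female_mask(sex, tgt.shape)
    kappa = np.where(female, _KAPPA_F, _KAPPA_M)
    alpha = np.where(female, _ALPHA_F, _ALPHA_M)
    # value at scr = kappa: both power terms are 1
    pivot = _SCALE * _AGE_BASE**age_a * np.where(female, _FEMALE_FACTOR, 1.0)
    # target below pivot -> scr/kappa > 1 branch, above pivot -> < 1 branch
    ratio = np.where(
        tgt <= pivot,
        (tgt / pivot) ** (1.0 / _EXP_HIGH),
        (tgt / pivot) ** (1.0 / alpha),
    )
    scr = ratio * kappa
    lo, hi = SCR_RANGE
    if np.any(scr < lo) or np.any(scr > hi):
        raise ValueError(
            "target eGFR outside the attainable range for this age/sex "
            f"(implied creatinine outside [{lo}, {hi}] mg/dL)"
        )
    return float(scr[0]) if scalar else scr


def egfr_table(labs: pd.DataFrame, persons: pd.DataFrame) -> pd.DataFrame:
    """Recompute eGFR for a serum-creatinine lab table.

    ``labs`` needs columns person_id, date, serum_creatinine; ``persons``
    needs person_id, sex, age_at_tdf_init, first_tdf_dispense.  Age at the
    lab date is age at TDF initiation plus elapsed years.  Returns a frame
    with columns person_id, date, egfr sorted by (person_id, date).
    """
    merged = labs.merge(
        persons[["person_id", "sex", "age_at_tdf_init", "first_tdf_dispense"]],
        on="person_id",
        how="left",
        validate="many_to_one",
    )
    if merged["sex"].isna().any():
        missing = merged.loc[merged["sex"].isna(), "person_id"].unique()
        raise ValueError(f"labs reference unknown person_ids: {missing[:5]}")
    elapsed_yr = (
        pd.to_datetime(merged["date"]) - pd.to_datetime(merged["first_tdf_dispense"])
    ).dt.days / 365.25
    age = merged["age_at_tdf_init"].to_numpy(float) + elapsed_yr.to_numpy(float)
    out = merged[["person_id", "date"]].copy()
    out["egfr"] = egfr_ckdepi_2021(
        merged["serum_creatinine"].to_numpy(float), age, merged["sex"].to_numpy()
    )
    return out.sort_values(["person_id", "date"], kind="stable").reset_index(drop=True)
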