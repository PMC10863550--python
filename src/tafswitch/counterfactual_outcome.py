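"""Bayesian longitudinal eGFR model and counterfactual ATT estimation.

The outcome model is a Bayesian linear mixed model for post-index eGFR:

    egfr_ij = x_ij' beta + u_person(i) + v_set(i) + eps_ij,
    eps ~ N(0, sigma^2),  u ~ N(0, tau_u^2),  v ~ N(0, tau_v^2)

with fixed effects for switch status, age, male sex, insurance, race and
ethnicity, smoking, weight and eGFR at the switch-eligible date, duration
from TDF start to the eligible date, hypertension and eGFR at the index
date, a natural cubic spline in months since index, and all pairwise
interactions among {switch status, eGFR at index, time spline}.  Random
intercepts are included for person and matched set.

Priors are weakly informative: N(0, 10^2) on standardized-scale
coefficients and half-t(3) on the three standard deviations (via the
Huang–Wand inverse-gamma mixture, which keeps every conditional conjugate).
Posterior draws come from a blocked Gibbs sampler; split-R-hat and effective
sample size are computed with arviz and non-convergence raises rather than
returning silently.

The estimand is the ATT: for each posterior draw, mean predicted eGFR over
the switchers' covariate rows under switch = 1 minus switch = 0 at each a
priori timepoint (months 0.5, 3, 6, 9, 12, 15, 18), random effects
marginalized at zero.  Posterior summaries report the median, 95% credible
interval, probability of direction (fraction of draws > 0) and the fraction
of draws inside the +/-2 eGFR-unit region of practical equivalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .synthetic_cohort import DAYS_PER_MONTH
from .tvps_matching import INSURANCE_LEVELS, RACE_LEVELS

log = logging.getLogger(__name__)

__all__ = [
    "OutcomeModelSpec",
    "build_outcome_dataset",
    "natural_spline_basis",
    "DesignBuilder",
    "fit_outcome_model",
    "OutcomePosterior",
    "compute_att",
    "probability_of_direction",
    "rope_fraction",
    "DEFAULT_TIMEPOINTS",
]

DEFAULT_TIMEPOINTS = (0.5, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0)


@dataclass
class OutcomeModelSpec:
    """Knobs of the outcome model; defaults are sized for desk-scale runs."""

    spline_df: int = 4
    time_boundary: tuple = (0.0, 18.0)
    include_interactions: bool = True
    prior_sd_beta: float = 10.0  # on standardized design columns
    prior_sd_intercept: float = 100.0
    prior_scale_sigma: float = 20.0  # half-t(3) scale for residual sd
    prior_scale_re: float = 10.0  # half-t(3) scale for random-effect sds
    chains: int = 2
    draws: int = 1000
    warmup: int = 500
    # error gate on fixed-effect split-R-hat; the statistic's own sampling
    # noise at 2x1000 draws is ~0.005, so the gate sits above the iid band
    # while still catching genuinely slow mixing (>= 1.02 in practice)
    rhat_tol: float = 1.02
    timepoints: tuple = DEFAULT_TIMEPOINTS
    rope: tuple = (-2.0, 2.0)


def natural_spline_basis(x, df: int = 4, boundary=(0.0, 18.0)):
    """Natural cubic spline basis (no intercept column).

    Knots are the two boundary knots plus ``df - 1`` equally spaced interior
    knots; the basis is linear beyond the boundaries.  Returns an
    ``(n, df)`` array.
    """
    if df < 2:
        raise ValueError("spline_df must be >= 2")
    x = np.asarray(x, dtype=float)
    knots = np.linspace(boundary[0], boundary[1], df + 1)
    K = len(knots)

    def trunc(k):
        return np.clip(x - knots[k], 0.0, None) ** 3

    def d(k):
        return (trunc(k) - trunc(K - 1)) / (knots[K - 1] - knots[k])

    cols = [x] + [d(k) - d(K - 2) for k in range(K - 2)]
    return np.column_stack(cols)


BASELINE_CONTINUOUS = (
    "age",
    "weight_at_index",
    "egfr_at_eligible",
    "egfr_at_index",
    "duration_tdf_to_eligible",
)
BASELINE_BINARY = ("male", "ever_smoker", "hypertension_at_index")


def build_outcome_dataset(
    indexed: pd.DataFrame,
    egfr: pd.DataFrame,
    covariates: pd.DataFrame,
    weights_table: pd.DataFrame | None = None,
    max_months: float = 18.0,
    lookback_days: int = 365,
) -> pd.DataFrame:
    """Long-format modeling dataset for the matched, indexed cohort.

    Joins post-index eGFR values (0 <= months since index <= ``max_months``)
    to baseline covariates resolved at the index date.  Persons with no eGFR
    strictly after the index date are excluded (a lab exactly at the index
    date is retained as months 0 but does not count as follow-up); exclusion
    counts are logged.  Weight/eGFR at index fall back to their
    eligible-date values when no measurement lies within the lookback.
    """
    if indexed.empty:
        raise ValueError("indexed cohort is empty")
    cov = covariates.set_index("person_id")
    base = indexed.merge(
        covariates[
            [
                "person_id",
                "age_at_tdf_init",
                "sex",
                "race_ethnicity",
                "insurance",
                "ever_smoker",
                "first_tdf_dispense",
                "weight_at_eligible",
                "egfr_at_eligible",
                "hypertension_onset",
            ]
        ],
        on="person_id",
        validate="one_to_one",
    )
    base["index_date"] = pd.to_datetime(base["index_date"])
    base["age"] = base["age_at_tdf_init"].astype(float)
    base["male"] = (base["sex"] == "male").astype(float)
    base["ever_smoker"] = base["ever_smoker"].astype(float)
    base["duration_tdf_to_eligible"] = (
        pd.to_datetime(base["eligible_date"]) - pd.to_datetime(base["first_tdf_dispense"])
    ).dt.days.astype(float)
    base["hypertension_at_index"] = (
        base["hypertension_onset"].notna()
        & (pd.to_datetime(base["hypertension_onset"]) <= base["index_date"])
    ).astype(float)

    def at_index(values: pd.DataFrame, col: str) -> pd.Series:
        v = values[["person_id", "date", col]].copy()
        v["date"] = pd.to_datetime(v["date"]).astype("datetime64[ns]")
        left = base[["person_id", "index_date"]].copy()
        left["index_date"] = left["index_date"].astype("datetime64[ns]")
        left = left.sort_values("index_date", kind="stable")
        merged = pd.merge_asof(
            left,
            v.sort_values("date", kind="stable"),
            left_on="index_date",
            right_on="date",
            by="person_id",
            direction="backward",
            tolerance=pd.Timedelta(days=lookback_days),
        )
        return merged.set_index("person_id")[col]

    egfr_idx = at_index(egfr.rename(columns={"egfr": "v"}), "v")
    base["egfr_at_index"] = base["person_id"].map(egfr_idx)
    n_fallback = int(base["egfr_at_index"].isna().sum())
    base["egfr_at_index"] = base["egfr_at_index"].fillna(base["egfr_at_eligible"])
    if weights_table is not None and len(weights_table):
        w_idx = at_index(weights_table.rename(columns={"weight_kg": "v"}), "v")
        base["weight_at_index"] = base["person_id"].map(w_idx)
    else:
        base["weight_at_index"] = np.nan
    base["weight_at_index"] = base["weight_at_index"].fillna(base["weight_at_eligible"])
    if n_fallback:
        log.info("outcome: %d persons use eligible-date eGFR as index baseline", n_fallback)

    labs = egfr.merge(base[["person_id", "index_date"]], on="person_id")
    labs["date"] = pd.to_datetime(labs["date"])
    labs["months_since_index"] = (
        (labs["date"] - labs["index_date"]).dt.days / DAYS_PER_MONTH
    )
    labs = labs.loc[
        (labs["months_since_index"] >= 0) & (labs["months_since_index"] <= max_months)
    ]
    has_followup = set(labs.loc[labs["months_since_index"] > 0, "person_id"])
    n_dropped = base["person_id"].nunique() - len(
        set(base["person_id"]) & has_followup
    )
    labs = labs.loc[labs["person_id"].isin(has_followup)]
    log.info(
        "outcome: %d persons dropped with no post-index eGFR; %d rows retained",
        n_dropped,
        len(labs),
    )
    cols = [
        "person_id",
        "set_id",
        "arm",
        "age",
        "male",
        "insurance",
        "race_ethnicity",
        "ever_smoker",
        "weight_at_index",
        "egfr_at_index",
        "egfr_at_eligible",
        "duration_tdf_to_eligible",
        "hypertension_at_index",
    ]
    out = labs[["person_id", "date", "months_since_index", "egfr"]].merge(
        base[cols], on="person_id", validate="many_to_one"
    )
    if out.empty:
        raise ValueError("outcome dataset is empty after follow-up exclusions")
    out = out.sort_values(["person_id", "date"], kind="stable").reset_index(drop=True)
    return out


class DesignBuilder:
    """Fixed-effect design for the outcome model.

    Captures standardization constants and spline knots from the fit data so
    counterfactual prediction rows are transformed identically.  Continuous
    covariates and spline columns are standardized; binary indicators and
    dummies are left on their natural scale.
    """

    def __init__(self, spec: OutcomeModelSpec):
        self.spec = spec
        self.centers: dict[str, tuple[float, float]] = {}
        self.columns: list[str] = []
        self.kept: list[str] | None = None

    def fit(self, data: pd.DataFrame) -> "DesignBuilder":
        X, names = self._raw(data, fit=True)
        self.columns = names
        self.kept = None
        # zero-variance columns (e.g. a dummy level absent from this cohort)
        # carry no information and alias the intercept
        constant = [
            n for j, n in enumerate(names) if n != "intercept" and np.ptp(X[:, j]) == 0
        ]
        if constant:
            log.warning("design: dropping zero-variance columns %s", constant)
            self.kept = [n for n in names if n not in constant]
            X = X[:, [names.index(n) for n in self.kept]]
            names = self.kept
        # rank check with the guarded fallback for the doubly listed eGFR terms
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            without = [n for n in names if n != "egfr_at_eligible_z"]
            Xw = X[:, [names.index(n) for n in without]]
            if np.linalg.matrix_rank(Xw) == Xw.shape[1]:
                log.warning(
                    "design: eGFR at eligible date aliased with eGFR at index; dropped"
                )
                self.kept = without
            else:
                aliased = self._aliased(X, names)
                raise ValueError(f"rank-deficient outcome design; aliased terms: {aliased}")
        return self

    @staticmethod
    def _aliased(X, names):
        keep, aliased = [], []
        for j, n in enumerate(names):
            cand = X[:, keep + [j]]
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                keep.append(j)
            else:
                aliased.append(n)
        return aliased

    def _z(self, name: str, values: np.ndarray, fit: bool) -> np.ndarray:
        if fit:
            mu, sd = float(np.mean(values)), float(np.std(values))
            self.centers[name] = (mu, sd if sd > 0 else 1.0)
        mu, sd = self.centers[name]
        return (values - mu) / sd

    def _raw(self, data: pd.DataFrame, fit: bool, months=None, switch=None):
        n = len(data)
        m = (
            np.full(n, float(months))
            if months is not None
            else data["months_since_index"].to_numpy(float)
        )
        sw = (
            np.full(n, float(switch))
            if switch is not None
            else (data["arm"] == "switcher").astype(float).to_numpy()
        )
        cols, names = [np.ones(n)], ["intercept"]
        cols.append(sw)
        names.append("switch")
        for c in BASELINE_CONTINUOUS:
            cols.append(self._z(c, data[c].to_numpy(float), fit))
            names.append(f"{c}_z")
        for c in BASELINE_BINARY:
            cols.append(data[c].to_numpy(float))
            names.append(c)
        for lvl in RACE_LEVELS:
            cols.append((data["race_ethnicity"] == lvl).to_numpy(float))
            names.append(f"race_{lvl.replace(' ', '_')}")
        for lvl in INSURANCE_LEVELS:
            cols.append((data["insurance"] == lvl).to_numpy(float))
            names.append(f"insurance_{lvl}")
        basis = natural_spline_basis(m, self.spec.spline_df, self.spec.time_boundary)
        spline_cols = []
        for j in range(basis.shape[1]):
            zc = self._z(f"time_s{j + 1}", basis[:, j], fit)
            cols.append(zc)
            names.append(f"time_s{j + 1}")
            spline_cols.append(zc)
        if self.spec.include_interactions:
            egfr_z = cols[names.index("egfr_at_index_z")]
            for j, zc in enumerate(spline_cols):
                cols.append(sw * zc)
                names.append(f"switch:time_s{j + 1}")
            for j, zc in enumerate(spline_cols):
                cols.append(egfr_z * zc)
                names.append(f"egfr_at_index_z:time_s{j + 1}")
            cols.append(sw * egfr_z)
            names.append("switch:egfr_at_index_z")
        return np.column_stack(cols), names

    def design(self, data: pd.DataFrame, months=None, switch=None) -> np.ndarray:
        X, names = self._raw(data, fit=False, months=months, switch=switch)
        if self.kept is not None:
            X = X[:, [names.index(k) for k in self.kept]]
        return X

    @property
    def names(self) -> list[str]:
        return self.kept if self.kept is not None else self.columns


@dataclass
class OutcomePosterior:
    beta: np.ndarray  # (chains, draws, p)
    sigma2: np.ndarray  # (chains, draws)
    tau2_person: np.ndarray
    tau2_set: np.ndarray
    builder: DesignBuilder
    dataset: pd.DataFrame
    spec: OutcomeModelSpec
    diagnostics: dict = field(default_factory=dict)

    @property
    def beta_flat(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])


def _inv_gamma(rng, shape, scale):
    return scale / rng.gamma(shape)


def _group_sums(M, codes, J):
    out = np.zeros((J, M.shape[1]))
    np.add.at(out, codes, M)
    return out


def _gibbs_chain(X, y, code1, J1, code2, J2, w, prior_prec, spec, rng):
    """One chain of the blocked Gibbs sampler.

    The fixed-effect block is drawn with both random-effect blocks
    marginalized out (collapsed update).  Persons are nested in matched
    sets, so the marginal residual covariance is block-diagonal by set and
    inverts with a two-level Woodbury identity whose ingredients are
    per-person and per-set weighted design sums — precomputable because the
    likelihood weights are fixed.  Collapsing removes the fixed-effect /
    random-intercept coupling that makes a vanilla Gibbs sweep on mixed
    models mix slowly.
    """
    n, p = X.shape
    nu = 3.0  # half-t degrees of freedom via Huang–Wand mixture
    Xw = X * w[:, None]
    XtWX = Xw.T @ X
    S1w = np.bincount(code1, weights=w, minlength=J1)
    G1 = _group_sums(Xw, code1, J1)  # per-person sums of w * x
    # person -> set map (persons are nested in matched sets)
    p2s = np.zeros(J1, dtype=int)
    p2s[code1] = code2
    # person-level weight (weights are constant within person): probability-
    # weighted pseudo-likelihood scales a person's whole marginal
    # contribution, i.e. both their residual precision and their random-
    # intercept precision, so weighting survives the random-effect layer
    wp = np.ones(J1)
    wp[code1] = w
    beta = np.zeros(p)
    u = np.zeros(J1)
    v = np.zeros(J2)
    sigma2 = float(np.var(y)) or 1.0
    tau2_u = tau2_v = 1.0
    a_sig = a_u = a_v = 1.0
    A_sig2, A_re2 = spec.prior_scale_sigma**2, spec.prior_scale_re**2
    total = spec.warmup + spec.draws
    out_beta = np.empty((spec.draws, p))
    out_sig = np.empty(spec.draws)
    out_tu = np.empty(spec.draws)
    out_tv = np.empty(spec.draws)
    D = np.diag(prior_prec)
    for it in range(total):
        # ---- beta | sigma2, tau_u, tau_v (u and v marginalized) ----------
        # two-level Woodbury on the nested covariance
        #   V_j = (1/w_j) (sigma^2 W_j^-1 + tau_u^2 11') within person,
        #   plus tau_v^2 11' within set
        pj = wp / tau2_u  # person random-intercept prior precision
        c = pj + S1w / sigma2  # per-person denominator
        Gs = G1 / sigma2
        # person-level pieces of A^-1 (A = sigma^2 W^-1 + tau_u^2/w 11')
        XtAiX = XtWX / sigma2 - Gs.T @ (Gs / c[:, None])
        hX_person = Gs * (pj / c)[:, None]  # X_j' A_j^-1 1
        hs_person = S1w / sigma2 * (pj / c)  # 1' A_j^-1 1
        hX_set = _group_sums(hX_person, p2s, J2)
        hs_set = np.bincount(p2s, weights=hs_person, minlength=J2)
        d = 1.0 / tau2_v + hs_set
        Q = XtAiX - hX_set.T @ (hX_set / d[:, None]) + D
        t1 = np.bincount(code1, weights=w * y, minlength=J1) / sigma2
        XtAir = Xw.T @ y / sigma2 - Gs.T @ (t1 / c)
        tr_person = t1 * (pj / c)  # 1' A_j^-1 y_j
        tr_set = np.bincount(p2s, weights=tr_person, minlength=J2)
        lin = XtAir - hX_set.T @ (tr_set / d)
        L = np.linalg.cholesky(Q)
        beta = np.linalg.solve(Q, lin) + np.linalg.solve(L.T, rng.standard_normal(p))
        fitted = X @ beta
        # ---- v | beta (u still marginalized): exact blocked draw ---------
        tr_resid = tr_set - hX_set @ beta  # 1' A_s^-1 (y - X beta) per set
        v = tr_resid / d + rng.standard_normal(J2) / np.sqrt(d)
        # ---- u | beta, v (prior N(0, tau_u^2 / w_j)) ---------------------
        r1 = y - fitted - v[code2]
        prec1 = S1w / sigma2 + pj
        u = np.bincount(code1, weights=w * r1, minlength=J1) / sigma2 / prec1
        u = u + rng.standard_normal(J1) / np.sqrt(prec1)
        resid = y - fitted - u[code1] - v[code2]
        ssr = float(np.sum(w * resid**2))
        sigma2 = _inv_gamma(rng, (nu + n) / 2.0, nu / a_sig + ssr / 2.0)
        a_sig = _inv_gamma(rng, (nu + 1) / 2.0, nu / sigma2 + 1.0 / A_sig2)
        tau2_u = _inv_gamma(rng, (nu + J1) / 2.0, nu / a_u + float(wp @ (u * u)) / 2.0)
        a_u = _inv_gamma(rng, (nu + 1) / 2.0, nu / tau2_u + 1.0 / A_re2)
        tau2_v = _inv_gamma(rng, (nu + J2) / 2.0, nu / a_v + float(v @ v) / 2.0)
        a_v = _inv_gamma(rng, (nu + 1) / 2.0, nu / tau2_v + 1.0 / A_re2)
        if it >= spec.warmup:
            k = it - spec.warmup
            out_beta[k] = beta
            out_sig[k] = sigma2
            out_tu[k] = tau2_u
            out_tv[k] = tau2_v
    return out_beta, out_sig, out_tu, out_tv


def fit_outcome_model(
    dataset: pd.DataFrame,
    spec: OutcomeModelSpec | None = None,
    seed: int = 0,
    weights: pd.Series | None = None,
) -> OutcomePosterior:
    """Blocked Gibbs fit of the Bayesian mixed model.

    ``weights`` (person_id -> stabilized weight) scale each person's
    likelihood contribution (inverse-probability-of-missingness weighting);
    a modeled person without a weight is an error.  Convergence is checked
    with split-R-hat on the fixed effects (tolerance ``spec.rhat_tol``);
    variance components are logged but not gated, as scale parameters mix
    more slowly without affecting the ATT contrast.
    """
    spec = spec or OutcomeModelSpec()
    if dataset.empty:
        raise ValueError("outcome dataset is empty")
    builder = DesignBuilder(spec).fit(dataset)
    X = builder.design(dataset)
    y = dataset["egfr"].to_numpy(float)
    code1, persons = pd.factorize(dataset["person_id"], sort=True)
    code2, sets = pd.factorize(dataset["set_id"], sort=True)
    if weights is not None:
        mapped = dataset["person_id"].map(weights)
        if mapped.isna().any():
            missing = dataset.loc[mapped.isna(), "person_id"].unique()
            raise ValueError(f"missing stabilized weight for person(s): {missing[:5]}")
        w = mapped.to_numpy(float)
    else:
        w = np.ones(len(dataset))
    prior_prec = np.full(X.shape[1], 1.0 / spec.prior_sd_beta**2)
    prior_prec[builder.names.index("intercept")] = 1.0 / spec.prior_sd_intercept**2
    chains = []
    for c in range(spec.chains):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 104729 + c]))
        chains.append(
            _gibbs_chain(
                X, y, code1, len(persons), code2, len(sets), w, prior_prec, spec, rng
            )
        )
    beta = np.stack([c[0] for c in chains])
    sigma2 = np.stack([c[1] for c in chains])
    tau2_u = np.stack([c[2] for c in chains])
    tau2_v = np.stack([c[3] for c in chains])
    post = az.from_dict(posterior={"beta": beta, "sigma2": sigma2})
    rhat = az.rhat(post)
    ess = az.ess(post)
    rhat_beta = float(np.nanmax(rhat["beta"].values))
    diag = {
        "rhat_beta_max": rhat_beta,
        "rhat_sigma2": float(rhat["sigma2"].values),
        "ess_beta_min": float(np.nanmin(ess["beta"].values)),
    }
    log.info("outcome model diagnostics: %s", diag)
    if spec.chains > 1 and rhat_beta > spec.rhat_tol:
        raise RuntimeError(
            f"outcome model failed to converge: max split-R-hat {rhat_beta:.4f} "
            f"> {spec.rhat_tol} on fixed effects"
        )
    return OutcomePosterior(
        beta=beta,
        sigma2=sigma2,
        tau2_person=tau2_u,
        tau2_set=tau2_v,
        builder=builder,
        dataset=dataset,
        spec=spec,
        diagnostics=diag,
    )


def probability_of_direction(draws) -> float:
    """Fraction of posterior draws that are strictly positive."""
    d = np.asarray(draws, dtype=float)
    if d.size == 0:
        raise ValueError("empty draw set")
    return float(np.mean(d > 0))


def rope_fraction(draws, bounds=(-2.0, 2.0)) -> float:
    """Fraction of posterior draws inside the closed interval ``bounds``."""
    lo, hi = bounds
    if not lo < hi:
        raise ValueError(f"ROPE bounds must satisfy lo < hi, got {bounds}")
    d = np.asarray(draws, dtype=float)
    if d.size == 0:
        raise ValueError("empty draw set")
    return float(np.mean((d >= lo) & (d <= hi)))


def compute_att(
    posterior: OutcomePosterior,
    timepoints=None,
    rope=None,
):
    """Counterfactual switch-vs-no-switch eGFR differences for switchers.

    For every draw and timepoint, predicts mean eGFR over the switchers'
    baseline covariate rows under both scenarios (random effects at zero)
    and differences the scenario means.  Returns ``(summary, att_draws)``
    where ``summary`` has one row per timepoint (median, 95% CrI, PDI, ROPE
    fraction, n_draws) and ``att_draws`` is a ``(n_timepoints, n_draws)``
    array.
    """
    spec = posterior.spec
    timepoints = tuple(timepoints if timepoints is not None else spec.timepoints)
    rope = tuple(rope if rope is not None else spec.rope)
    ds = posterior.dataset
    switchers = ds.loc[ds["arm"] == "switcher"].drop_duplicates("person_id")
    if switchers.empty:
        raise ValueError("no switchers in the outcome dataset")
    max_obs = float(ds["months_since_index"].max())
    B = posterior.beta_flat
    rows, draws_out = [], []
    for m in timepoints:
        if m > max_obs:
            log.warning(
                "ATT at month %.1f extrapolates beyond observed follow-up (%.1f)", m, max_obs
            )
        X1 = posterior.builder.design(switchers, months=m, switch=1)
        X0 = posterior.builder.design(switchers, months=m, switch=0)
        contrast = (X1 - X0).mean(axis=0)
        att = B @ contrast
        lo, hi = np.percentile(att, [2.5, 97.5])
        rows.append(
            {
                "timepoint_months": m,
                "median_diff": float(np.median(att)),
                "cri_lo": float(lo),
                "cri_hi": float(hi),
                "pdi": probability_of_direction(att),
                "rope_fraction": rope_fraction(att, rope),
                "n_draws": int(att.size),
            }
        )
        draws_out.append(att)
    return pd.DataFrame(rows), np.vstack(draws_out)
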