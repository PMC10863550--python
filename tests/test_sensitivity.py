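"""Adherence censoring (SA1), missingness weights (SA2), MI pooling (SA3)."""


import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from conftest import make_outcome_dataset

from tafswitch.counterfactual_outcome import OutcomeModelSpec, compute_att, fit_outcome_model
from tafswitch.sensitivity import (
    bin_to_timepoints,
    censor_at_deviation,
    fit_missingness_weights,
    mi_per_timepoint_regression,
    rubin_pool,
    weighted_outcome_model,
)

FAST = OutcomeModelSpec(chains=2, draws=400, warmup=200, rhat_tol=1.05)


def _indexed_from(ds):
    base = ds.drop_duplicates("person_id")
    return pd.DataFrame(
        {
            "person_id": base["person_id"],
            "arm": base["arm"],
            "set_id": base["set_id"],
            "index_date": pd.Timestamp("2020-06-01"),
        }
    )


class TestCensorAtDeviation:
    def _dispensings(self, rows):
        return pd.DataFrame(rows, columns=["person_id", "date", "drug", "days_supplied"]).assign(
            date=lambda d: pd.to_datetime(d["date"])
        )

    def test_no_deviations_identity(self):
        ds = make_outcome_dataset(n_sets=4, seed=1)
        indexed = _indexed_from(ds)
        disp = self._dispensings(
            [(p, "2020-07-01", "TAF" if a == "switcher" else "TDF", 30)
             for p, a in indexed[["person_id", "arm"]].itertuples(index=False)]
        )
        out = censor_at_deviation(ds, disp, indexed)
        pd.testing.assert_frame_equal(out, ds)

    def test_nonswitcher_taf_censors_later_rows(self):
        ds = make_outcome_dataset(n_sets=4, seed=2)
        indexed = _indexed_from(ds)
        pid = indexed.loc[indexed["arm"] == "nonswitcher", "person_id"].iloc[0]
        dev_date = pd.Timestamp("2020-06-01") + pd.Timedelta(days=int(7 * 30.4375))
        disp = self._dispensings([(pid, dev_date, "TAF", 30)])
        out = censor_at_deviation(ds, disp, indexed)
        kept = out.loc[out["person_id"] == pid, "months_since_index"]
        orig = ds.loc[ds["person_id"] == pid, "months_since_index"]
        assert (kept <= 7.1).all()
        assert set(orig[orig <= 7.0]).issubset(set(kept))
        # untouched persons keep all rows
        other = indexed.loc[indexed["person_id"] != pid, "person_id"]
        assert len(out[out["person_id"].isin(other)]) == len(ds[ds["person_id"].isin(other)])

    def test_switcher_back_to_tdf_censored(self):
        ds = make_outcome_dataset(n_sets=4, seed=3)
        indexed = _indexed_from(ds)
        pid = indexed.loc[indexed["arm"] == "switcher", "person_id"].iloc[0]
        dev_date = pd.Timestamp("2020-06-01") + pd.Timedelta(days=int(4 * 30.4375))
        disp = self._dispensings([(pid, dev_date, "TDF", 30)])
        out = censor_at_deviation(ds, disp, indexed)
        assert (out.loc[out["person_id"] == pid, "months_since_index"] <= 4.1).all()

    def test_result_is_subset(self):
        ds = make_outcome_dataset(n_sets=6, seed=4)
        indexed = _indexed_from(ds)
        rng = np.random.default_rng(0)
        rows = []
        for p, a in indexed[["person_id", "arm"]].itertuples(index=False):
            if rng.random() < 0.4:
                bad = "TDF" if a == "switcher" else "TAF"
                d = pd.Timestamp("2020-06-01") + pd.Timedelta(days=int(rng.integers(30, 500)))
                rows.append((p, d, bad, 30))
        disp = self._dispensings(rows)
        out = censor_at_deviation(ds, disp, indexed)
        merged = out.merge(ds, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()
        assert len(out) <= len(ds)


class TestMissingnessWeights:
    def test_mcar_weights_near_one(self):
        rng = np.random.default_rng(1)
        n = 500
        cohort = pd.DataFrame(
            {
                "person_id": [f"P{i}" for i in range(n)],
                "age": rng.uniform(20, 70, n),
                "male": rng.integers(0, 2, n).astype(float),
                "egfr_at_index": rng.normal(95, 12, n),
                "included": rng.random(n) < 0.8,  # independent of covariates
            }
        )
        w = fit_missingness_weights(cohort, covariate_cols=["age", "male", "egfr_at_index"])
        inc = w.loc[w["included"] == 1, "stabilized_weight"]
        assert np.max(np.abs(inc - 1.0)) < 0.2
        assert inc.mean() == pytest.approx(1.0, abs=0.05)

    def test_toy_closed_form_by_sex(self):
        """Saturated binary covariate: the logistic fit reproduces the cell
        proportions, so weights equal hand-computed marginal/conditional
        ratios."""
        cohort = pd.DataFrame(
            {
                "person_id": list("ABCDEFGH"),
                "male": [1, 1, 1, 1, 0, 0, 0, 0],
                "included": [1, 1, 1, 0, 1, 0, 0, 0],
            }
        )
        w = fit_missingness_weights(
            cohort, covariate_cols=["male"], truncate_pct=(0.0, 100.0)
        ).set_index("person_id")
        p_marg = 0.5
        assert w.loc["A", "stabilized_weight"] == pytest.approx(p_marg / 0.75, abs=0.01)
        assert w.loc["E", "stabilized_weight"] == pytest.approx(p_marg / 0.25, abs=0.02)

    def test_perfect_separation_is_an_error(self):
        cohort = pd.DataFrame(
            {
                "person_id": [f"P{i}" for i in range(40)],
                "flag": [1.0] * 20 + [0.0] * 20,
                "included": [1] * 20 + [0] * 20,
            }
        )
        with pytest.raises(ValueError, match="separation"):
            fit_missingness_weights(cohort, covariate_cols=["flag"])

    def test_constant_inclusion_is_an_error(self):
        cohort = pd.DataFrame(
            {"person_id": ["A", "B"], "x": [0.0, 1.0], "included": [1, 1]}
        )
        with pytest.raises(ValueError, match="constant"):
            fit_missingness_weights(cohort, covariate_cols=["x"])


class TestWeightedModel:
    def test_unit_weights_reproduce_main_model(self):
        ds = make_outcome_dataset(n_sets=10, seed=5)
        main, _ = compute_att(fit_outcome_model(ds, spec=FAST, seed=5))
        ones = pd.Series(1.0, index=ds["person_id"].unique())
        weighted, _, _ = weighted_outcome_model(ds, ones, spec=FAST, seed=5)
        assert np.allclose(main["median_diff"], weighted["median_diff"], atol=1e-10)

    def test_doubling_weights_leaves_estimates_unchanged(self):
        ds = make_outcome_dataset(n_sets=12, seed=6)
        ones = pd.Series(1.0, index=ds["person_id"].unique())
        a, _, _ = weighted_outcome_model(ds, ones, spec=FAST, seed=6)
        b, _, _ = weighted_outcome_model(ds, 2.0 * ones, spec=FAST, seed=6)
        assert np.all(np.abs(a["median_diff"] - b["median_diff"]) < 0.3)

    def test_ipw_reduces_bias_from_unmodeled_missingness(self):
        """Inclusion depends on a covariate (diabetes) that shifts the
        outcome but is absent from the outcome model; weighting it in the
        missingness model moves the ATT back toward the truth."""
        gaps_u, gaps_w = [], []
        for seed in range(5):
            ds = make_outcome_dataset(
                n_sets=30, effect=3.0, sigma=1.5, tau_u=1.0, seed=40 + seed,
                diabetes_effect=-8.0,
            )
            persons = ds.drop_duplicates("person_id").set_index("person_id")
            rng = np.random.default_rng(seed)
            # diabetics in the switcher arm are mostly excluded -> arms differ
            # in unmodeled case mix unless reweighted
            p_incl = np.where(
                (persons["diabetes"] > 0) & (persons["arm"] == "switcher"), 0.25, 0.95
            )
            included = rng.random(len(persons)) < p_incl
            inc_ids = set(persons.index[included])
            cohort = persons.reset_index()[["person_id", "age", "male", "diabetes", "arm"]]
            cohort["switch"] = (cohort["arm"] == "switcher").astype(float)
            cohort["diab_x_switch"] = cohort["diabetes"] * cohort["switch"]
            cohort["included"] = cohort["person_id"].isin(inc_ids).astype(int)
            w = fit_missingness_weights(
                cohort,
                covariate_cols=["age", "male", "diabetes", "switch", "diab_x_switch"],
            )
            sub = ds.loc[ds["person_id"].isin(inc_ids)]
            unw, _ = compute_att(fit_outcome_model(sub, spec=FAST, seed=seed))
            wtd, _, _ = weighted_outcome_model(sub, w, spec=FAST, seed=seed)
            gaps_u.append(abs(unw["median_diff"].mean() - 3.0))
            gaps_w.append(abs(wtd["median_diff"].mean() - 3.0))
        assert np.mean(gaps_w) < np.mean(gaps_u)


class TestRubinAndMI:
    def test_rubin_identity_on_three_imputation_toy(self):
        q = [1.0, 1.5, 2.0]
        u = [0.30, 0.20, 0.25]
        pooled = rubin_pool(q, u)
        # independent scalar recomputation
        m = 3
        qbar = sum(q) / m
        within = sum(u) / m
        between = sum((x - qbar) ** 2 for x in q) / (m - 1)
        assert pooled["estimate"] == pytest.approx(qbar)
        assert pooled["total_variance"] == pytest.approx(within + (1 + 1 / m) * between)
        assert pooled["between"] == pytest.approx(between)
        assert pooled["within"] == pytest.approx(within)

    def test_rubin_zero_between_gives_normal_interval(self):
        pooled = rubin_pool([2.0, 2.0], [0.25, 0.25])
        assert pooled["between"] == 0.0
        assert pooled["ci_lo"] == pytest.approx(2.0 - 1.959964 * 0.5, abs=1e-4)

    def test_binning_nearest_within_window(self):
        ds = pd.DataFrame(
            {
                "person_id": ["A"] * 3,
                "months_since_index": [0.6, 2.5, 8.0],
                "egfr": [90.0, 91.0, 92.0],
            }
        )
        wide = bin_to_timepoints(ds, (0.5, 3.0, 6.0, 9.0))
        assert wide.loc["A", "egfr_m0.5"] == 90.0
        assert wide.loc["A", "egfr_m3"] == 91.0
        assert np.isnan(wide.loc["A", "egfr_m6"])  # 8.0 is nearer to 9 than 6
        assert wide.loc["A", "egfr_m9"] == 92.0

    def test_complete_data_mi_degenerates_to_single_regression(self):
        """With a lab at every timepoint for every person and m = 2, the
        pooled estimate equals the complete-data OLS coefficient and the
        between-imputation variance is zero."""
        rng = np.random.default_rng(3)
        rows = []
        tps = (0.5, 3.0, 6.0)
        for i in range(60):
            arm = "switcher" if i % 4 == 0 else "nonswitcher"
            base = {
                "person_id": f"P{i:03d}",
                "set_id": i // 4,
                "arm": arm,
                "age": rng.uniform(25, 60),
                "male": 1.0,
                "insurance": "commercial",
                "race_ethnicity": "White NH",
                "ever_smoker": 0.0,
                "weight_at_index": rng.normal(85, 10),
                "egfr_at_index": rng.normal(95, 10),
                "egfr_at_eligible": rng.normal(95, 10),
                "duration_tdf_to_eligible": rng.uniform(300, 900),
                "hypertension_at_index": 0.0,
            }
            for t in tps:
                rows.append(
                    {
                        **base,
                        "months_since_index": t,
                        "egfr": 90 + 3.0 * (arm == "switcher") + rng.normal(0, 2),
                        "date": pd.Timestamp("2020-06-01") + pd.Timedelta(days=int(t * 30)),
                    }
                )
        ds = pd.DataFrame(rows)
        out = mi_per_timepoint_regression(ds, timepoints=tps, m=2, seed=0)
        assert out["available"].all()
        # independent complete-data regression at month 3
        wide = bin_to_timepoints(ds, tps)
        base = ds.drop_duplicates("person_id").set_index("person_id").loc[wide.index]
        X = pd.DataFrame(
            {
                "switch": (base["arm"] == "switcher").astype(float),
                "age": base["age"],
                "weight_at_index": base["weight_at_index"],
                "egfr_at_index": base["egfr_at_index"],
                "egfr_at_eligible": base["egfr_at_eligible"],
                "duration_tdf_to_eligible": base["duration_tdf_to_eligible"],
            }
        )
        fit = sm.OLS(wide["egfr_m3"].to_numpy(), sm.add_constant(X.to_numpy())).fit()
        got = out.set_index("timepoint_months").loc[3.0]
        assert got["estimate"] == pytest.approx(fit.params[1], abs=1e-6)
        assert got["between"] == pytest.approx(0.0, abs=1e-12)

    def test_mi_recovers_effect_under_mar_holes(self):
        """MAR missingness carved into the wide outcome matrix: pooled CIs
        cover the true +3 effect in most seeds."""
        cover = 0
        n_seeds = 8
        for seed in range(n_seeds):
            ds = make_outcome_dataset(
                n_sets=25, effect=3.0, sigma=1.5, tau_u=1.0, tau_v=0.0,
                obs_per_person=(6, 9), seed=60 + seed, egfr_coef=0.3,
            )
            rng = np.random.default_rng(seed)
            # lower-eGFR persons lose observations (MAR given a covariate)
            p_miss = 1 / (1 + np.exp((ds["egfr_at_index"] - 90) / 8))
            ds = ds.loc[rng.random(len(ds)) > 0.6 * p_miss]
            out = mi_per_timepoint_regression(ds, timepoints=(3.0, 6.0, 9.0), m=5, seed=seed)
            mid = out.set_index("timepoint_months").loc[6.0]
            if mid["ci_lo"] <= 3.0 <= mid["ci_hi"]:
                cover += 1
        assert cover >= n_seeds - 2

    def test_all_missing_timepoint_flagged_unavailable(self):
        ds = make_outcome_dataset(n_sets=6, seed=9, max_month=6.0)
        out = mi_per_timepoint_regression(ds, timepoints=(3.0, 15.0), m=2, seed=1)
        row = out.set_index("timepoint_months").loc[15.0]
        assert not row["available"]
        assert np.isnan(row["estimate"])
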