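"""Extended Cox TV-PS model and risk-set matching."""


import pandas as pd
import pytest
from conftest import oracle_sequential_match, random_small_cohort

from tafswitch.eligibility import apply_exclusions, build_covariates, impute_covariates_rf
from tafswitch.renal_metrics import egfr_table
from tafswitch.synthetic_cohort import SimulationTruth, generate_cohort
from tafswitch.tvps_matching import (
    TvpsModel,
    assign_index_dates,
    build_counting_process,
    encode_time_invariant,
    fit_tvps_model,
    sequential_match,
    standardized_mean_differences,
)


def simulate_matching_cohort(seed, n=400, **truth_kwargs):
    """Generate + eligibility + covariates, returning the matching frame."""
    truth = SimulationTruth(n_persons=n, seed=seed, **truth_kwargs)
    persons, tables, _ = generate_cohort(truth)
    egfr = egfr_table(tables.labs, persons)
    eligibility = apply_exclusions(persons, tables.dispensings)
    cov = build_covariates(persons, eligibility, egfr, tables.weights, tables.comorbidity_onsets)
    cov = impute_covariates_rf(cov, seed=seed).completed
    disp = tables.dispensings
    first_taf = (
        disp.loc[disp["drug"] == "TAF"].groupby("person_id")["date"].min()
    )
    cov["switch_date"] = cov["person_id"].map(first_taf)
    end = (
        persons.set_index("person_id")["disenrollment_date"]
        .fillna(pd.Timestamp(truth.study_end))
        .clip(upper=pd.Timestamp(truth.study_end))
    )
    cov["end_date"] = cov["person_id"].map(end)
    return cov


@pytest.fixture(scope="module")
def matching_cohort():
    return simulate_matching_cohort(seed=21)


@pytest.fixture(scope="module")
def fitted_model(matching_cohort):
    cp = build_counting_process(
        matching_cohort,
        matching_cohort.set_index("person_id")["switch_date"],
        matching_cohort.set_index("person_id")["end_date"],
    )
    return fit_tvps_model(cp)


class TestCountingProcess:
    def test_intervals_split_at_onsets_and_event_marked(self, matching_cohort):
        cp = build_counting_process(
            matching_cohort,
            matching_cohort.set_index("person_id")["switch_date"],
            matching_cohort.set_index("person_id")["end_date"],
        )
        assert (cp["stop"] > cp["start"]).all()
        n_events = cp["event"].sum()
        assert n_events == matching_cohort["switch_date"].notna().sum()
        # a person with a mid-follow-up onset contributes 0 -> 1 transition
        multi = cp.groupby("id").filter(lambda g: len(g) > 1)
        assert not multi.empty
        some = multi.groupby("id")["diabetes"].nunique()
        assert (some > 1).any() or (multi.groupby("id")["hypertension"].nunique() > 1).any()


class TestFit:
    def test_no_events_is_an_error(self, matching_cohort):
        quiet = matching_cohort.copy()
        quiet["switch_date"] = pd.NaT
        cp = build_counting_process(
            quiet,
            quiet.set_index("person_id")["switch_date"],
            quiet.set_index("person_id")["end_date"],
        )
        with pytest.raises(ValueError, match="no switch events"):
            fit_tvps_model(cp)

    def test_zero_variance_covariate_dropped(self, matching_cohort):
        cp = build_counting_process(
            matching_cohort,
            matching_cohort.set_index("person_id")["switch_date"],
            matching_cohort.set_index("person_id")["end_date"],
        )
        cp["constant_junk"] = 1.0
        model = fit_tvps_model(cp)
        assert "constant_junk" in model.dropped
        assert "constant_junk" not in model.params.index

    def test_recovers_confounder_signs_across_seeds(self):
        """Lower baseline eGFR and older age raise the simulated switch
        hazard; the fitted coefficients carry those signs in most seeds."""
        egfr_signs, age_signs = [], []
        for seed in range(30, 40):
            cohort = simulate_matching_cohort(seed)
            cp = build_counting_process(
                cohort,
                cohort.set_index("person_id")["switch_date"],
                cohort.set_index("person_id")["end_date"],
            )
            model = fit_tvps_model(cp)
            egfr_signs.append(model.params["egfr_at_eligible"] < 0)
            age_signs.append(model.params["age"] > 0)
        assert sum(egfr_signs) >= 8
        assert sum(age_signs) >= 8


def toy_cohort(rows):
    cols = [
        "person_id",
        "switch_eligible_date",
        "switch_date",
        "end_date",
        "egfr_at_eligible",
    ]
    df = pd.DataFrame(rows, columns=cols)
    for c in ("switch_eligible_date", "switch_date", "end_date"):
        df[c] = pd.to_datetime(df[c])
    df["age_at_tdf_init"] = 40.0
    df["sex"] = "male"
    df["race_ethnicity"] = "White NH"
    df["insurance"] = "commercial"
    df["ever_smoker"] = 0
    df["year_eligibility_met"] = 2020
    df["weight_at_eligible"] = 80.0
    for cond in ("diabetes", "dyslipidemia", "hypertension"):
        df[f"{cond}_onset"] = pd.NaT
    return df


def score_model(egfr_beta=-0.05):
    params = pd.Series({"egfr_at_eligible": egfr_beta})
    return TvpsModel(params=params)


class TestSequentialMatch:
    def test_identical_control_matched_at_distance_zero(self):
        cohort = toy_cohort(
            [
                ("S", "2020-01-01", "2020-06-01", "2022-06-30", 90.0),
                ("C", "2020-01-01", None, "2022-06-30", 90.0),
            ]
        )
        matched, info = sequential_match(score_model(), cohort, ratio=4, seed=0)
        assert len(matched) == 1
        assert matched["control_id"].iloc[0] == "C"
        assert matched["score_distance"].iloc[0] == 0.0

    def test_control_later_switching_stays_nonswitcher(self):
        """B serves as control at month 3; B's own switch at month 8 yields no
        matched set and B stays a nonswitcher."""
        cohort = toy_cohort(
            [
                ("A", "2020-01-01", "2020-03-01", "2022-06-30", 90.0),
                ("B", "2020-01-01", "2020-08-01", "2022-06-30", 91.0),
                ("C", "2020-01-01", None, "2022-06-30", 120.0),
            ]
        )
        matched, info = sequential_match(score_model(), cohort, ratio=1, seed=0)
        assert set(matched["switcher_id"]) == {"A"}
        assert matched.loc[matched["switcher_id"] == "A", "control_id"].iloc[0] == "B"
        assert info["reclassified_switchers"] == ["B"]

    def test_risk_set_excludes_prior_switchers_and_consumed(self):
        cohort = toy_cohort(
            [
                ("S1", "2020-01-01", "2020-02-01", "2022-06-30", 90.0),
                ("S2", "2020-01-01", "2020-05-01", "2022-06-30", 90.0),
                ("S3", "2020-01-01", "2020-08-01", "2022-06-30", 80.0),
                ("C1", "2020-01-01", None, "2022-06-30", 90.5),
                ("C2", "2020-01-01", None, "2022-06-30", 95.0),
            ]
        )
        matched, info = sequential_match(score_model(), cohort, ratio=1, seed=0)
        m = matched.set_index("switcher_id")["control_id"]
        # S2 has not switched yet at S1's event and is the closest (distance 0):
        # future switchers are valid controls before their own switch
        assert m["S1"] == "S2"
        assert info["reclassified_switchers"] == ["S2"]
        # at S3's event, S1 (already switched) and S2 (consumed) are excluded
        assert m["S3"] == "C1"

    def test_empty_risk_set_discards_switcher(self):
        cohort = toy_cohort(
            [
                ("S", "2020-01-01", "2020-06-01", "2022-06-30", 90.0),
                ("L", "2021-01-01", None, "2022-06-30", 90.0),  # not yet eligible
            ]
        )
        matched, info = sequential_match(score_model(), cohort, ratio=2, seed=0)
        assert matched.empty
        assert info["discarded_switchers"] == ["S"]

    def test_no_conditioning_on_the_future(self):
        """Perturbing data dated after the switch event (a later comorbidity
        onset) leaves the selected controls unchanged."""
        cohort = toy_cohort(
            [
                ("S", "2020-01-01", "2020-06-01", "2022-06-30", 90.0),
                ("C1", "2020-01-01", None, "2022-06-30", 92.0),
                ("C2", "2020-01-01", None, "2022-06-30", 100.0),
            ]
        )
        model = TvpsModel(params=pd.Series({"egfr_at_eligible": -0.05, "diabetes": 5.0}))
        base, _ = sequential_match(model, cohort, ratio=1, seed=0)
        perturbed = cohort.copy()
        perturbed.loc[perturbed["person_id"] == "C1", "diabetes_onset"] = pd.Timestamp(
            "2021-01-01"
        )  # after the event date
        after, _ = sequential_match(model, perturbed, ratio=1, seed=0)
        pd.testing.assert_frame_equal(base, after)
        # an onset BEFORE the event date does change the score and selection
        perturbed.loc[perturbed["person_id"] == "C1", "diabetes_onset"] = pd.Timestamp(
            "2020-02-01"
        )
        changed, _ = sequential_match(model, perturbed, ratio=1, seed=0)
        assert changed["control_id"].iloc[0] == "C2"

    def test_matches_brute_force_oracle_on_small_cohorts(self, rng_session):
        params = pd.Series(
            {"egfr_at_eligible": -0.04, "age": 0.05, "weight_at_eligible": 0.01, "diabetes": 0.6}
        )
        model = TvpsModel(params=params)
        for _ in range(25):
            cohort = random_small_cohort(rng_session)
            matched, _ = sequential_match(model, cohort, ratio=4, seed=1)
            got = [
                (sid, tuple(grp.sort_values("control_rank")["control_id"]))
                for sid, grp in matched.groupby("switcher_id", sort=False)
            ]
            got = sorted(got)
            expected = sorted(oracle_sequential_match(params, cohort, ratio=4))
            assert got == expected

    def test_without_replacement_roles_exclusive(self, matching_cohort, fitted_model):
        matched, _ = sequential_match(fitted_model, matching_cohort, ratio=4, seed=3)
        switchers = set(matched["switcher_id"])
        controls = list(matched["control_id"])
        assert len(controls) == len(set(controls))
        assert not switchers & set(controls)
        sizes = matched.groupby("set_id").size()
        assert sizes.between(1, 4).all()


class TestIndexDates:
    def test_interval_preservation(self):
        cohort = toy_cohort(
            [
                ("S", "2020-01-01", "2020-04-10", "2022-06-30", 90.0),
                ("C", "2020-02-01", None, "2022-06-30", 90.0),
            ]
        )
        matched, _ = sequential_match(score_model(), cohort, ratio=1, seed=0)
        idx = assign_index_dates(matched, cohort).set_index("person_id")
        assert idx.loc["S", "index_date"] == pd.Timestamp("2020-04-10")
        assert idx.loc["C", "index_date"] == pd.Timestamp("2020-05-11")  # +100 days

    def test_zero_interval(self):
        cohort = toy_cohort(
            [
                ("S", "2020-03-01", "2020-03-01", "2022-06-30", 90.0),
                ("C", "2020-02-01", None, "2022-06-30", 90.0),
            ]
        )
        matched, _ = sequential_match(score_model(), cohort, ratio=1, seed=0)
        idx = assign_index_dates(matched, cohort).set_index("person_id")
        assert idx.loc["C", "index_date"] == pd.Timestamp("2020-02-01")

    def test_control_index_beyond_study_end_dropped(self):
        cohort = toy_cohort(
            [
                ("S", "2020-01-01", "2022-06-01", "2022-06-30", 90.0),
                ("C", "2021-06-01", None, "2022-06-30", 90.0),  # index would be 2023
                ("C2", "2020-01-02", None, "2022-06-30", 91.0),
            ]
        )
        matched, _ = sequential_match(score_model(), cohort, ratio=4, seed=0)
        idx = assign_index_dates(matched, cohort, study_end="2022-06-30")
        assert "C" not in set(idx["person_id"])
        assert "C2" in set(idx["person_id"])

    def test_interval_invariant_on_simulated_run(self, matching_cohort, fitted_model):
        matched, _ = sequential_match(fitted_model, matching_cohort, ratio=4, seed=5)
        idx = assign_index_dates(matched, matching_cohort)
        elig = matching_cohort.set_index("person_id")["switch_eligible_date"]
        for sid, grp in idx.groupby("set_id"):
            sw = grp.loc[grp["arm"] == "switcher"].iloc[0]
            interval = (sw["index_date"] - pd.Timestamp(elig[sw["person_id"]])).days
            for _, c in grp.loc[grp["arm"] == "nonswitcher"].iterrows():
                c_int = (c["index_date"] - pd.Timestamp(elig[c["person_id"]])).days
                assert c_int == interval


def test_balance_improves_on_confounded_cohort(matching_cohort, fitted_model):
    matched, _ = sequential_match(fitted_model, matching_cohort, ratio=4, seed=1)
    design = encode_time_invariant(matching_cohort)
    is_sw = matching_cohort["switch_date"].notna().to_numpy()
    pre = standardized_mean_differences(design.loc[is_sw], design.loc[~is_sw])
    in_sw = matching_cohort["person_id"].isin(set(matched["switcher_id"])).to_numpy()
    in_ct = matching_cohort["person_id"].isin(set(matched["control_id"])).to_numpy()
    post = standardized_mean_differences(design.loc[in_sw], design.loc[in_ct])
    # the strongly confounded covariates shrink
    assert post["egfr_at_eligible"] < pre["egfr_at_eligible"]
    assert post["age"] < pre["age"]
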