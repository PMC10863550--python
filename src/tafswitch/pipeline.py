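"""End-to-end pipeline: simulate -> eligibility -> TV-PS matching -> Bayesian
counterfactual model -> sensitivity analyses -> report.

Every run is driven by a :class:`PipelineConfig`, fully serialized into the
run manifest together with attrition counts at each filter, so a run is
reproducible from its manifest alone.  All tables are delimited text with
ISO-8601 dates; the ATT summary is written both as CSV (one row per
timepoint x analysis, mirroring the four-analysis layout) and JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import eligibility as elig_mod
from . import sensitivity as sa_mod
from .counterfactual_outcome import (
    OutcomeModelSpec,
    build_outcome_dataset,
    compute_att,
    fit_outcome_model,
)
from .renal_metrics import egfr_table
from .synthetic_cohort import (
    LongitudinalTables,
    SimulationTruth,
    generate_cohort,
    inject_deviations,
)
from .tvps_matching import (
    assign_index_dates,
    build_counting_process,
    encode_time_invariant,
    fit_tvps_model,
    sequential_match,
    standardized_mean_differences,
)

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "attrition_report",
    "simulate_to_dir",
    "load_tables",
]

REQUIRED_TABLES = {
    "persons": [
        "person_id",
        "age_at_tdf_init",
        "sex",
        "race_ethnicity",
        "insurance",
        "ever_smoker",
        "first_tdf_dispense",
        "disenrollment_date",
        "baseline_ckd_flag",
    ],
    "dispensings": ["person_id", "date", "drug", "days_supplied"],
    "labs": ["person_id", "date", "serum_creatinine"],
    "weights": ["person_id", "date", "weight_kg"],
    "comorbidities": ["person_id", "condition", "onset_date"],
}


class PipelineError(RuntimeError):
    """Stage-labeled pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "runs/run"
    input_dir: str | None = None  # read the five tables instead of simulating
    truth: SimulationTruth = field(default_factory=SimulationTruth)
    apply_deviations: bool = True
    policy_date: str = "2019-10-01"
    threshold_days: int = 183
    lookback_days: int = 365
    study_end: str = "2022-06-30"
    ratio: int = 4
    caliper: float | None = None
    cox_penalizer: float = 0.01
    model: OutcomeModelSpec = field(default_factory=OutcomeModelSpec)
    mi_m: int = 10
    weight_truncate_pct: tuple = (1.0, 99.0)
    run_sensitivity: bool = True
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["truth"] = self.truth.manifest()
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "truth" in data and isinstance(data["truth"], dict):
            data["truth"] = SimulationTruth.from_manifest(data["truth"])
        if "model" in data and isinstance(data["model"], dict):
            md = dict(data["model"])
            for key in ("time_boundary", "timepoints", "rope"):
                if key in md and isinstance(md[key], list):
                    md[key] = tuple(md[key])
            data["model"] = OutcomeModelSpec(**md)
        if isinstance(data.get("weight_truncate_pct"), list):
            data["weight_truncate_pct"] = tuple(data["weight_truncate_pct"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[c]):
            out[c] = out[c].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def load_tables(input_dir) -> tuple[pd.DataFrame, LongitudinalTables]:
    """Read and schema-check the five cohort tables before any computation."""
    input_dir = Path(input_dir)
    frames = {}
    for name, cols in REQUIRED_TABLES.items():
        path = input_dir / f"{name}.csv"
        if not path.exists():
            raise PipelineError("load", f"missing required input table {path}")
        df = pd.read_csv(path)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise PipelineError("load", f"table {name} lacks required columns {missing}")
        for c in df.columns:
            if "date" in c:
                df[c] = pd.to_datetime(df[c], errors="coerce")
        frames[name] = df
    tables = LongitudinalTables(
        frames["dispensings"], frames["labs"], frames["weights"], frames["comorbidities"]
    )
    return frames["persons"], tables


def simulate_to_dir(truth: SimulationTruth, out_dir, apply_deviations: bool = True) -> dict:
    """Generate a cohort and write the five tables plus the truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    persons, tables, manifest = generate_cohort(truth)
    if apply_deviations:
        tables = inject_deviations(tables, truth, persons)
    _write_csv(persons, out / "persons.csv")
    _write_csv(tables.dispensings, out / "dispensings.csv")
    _write_csv(tables.labs, out / "labs.csv")
    _write_csv(tables.weights, out / "weights.csv")
    _write_csv(tables.comorbidity_onsets, out / "comorbidities.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _trajectory_figure(dataset: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = {"switcher": "#c0392b", "nonswitcher": "#2c6fbb"}
    for arm, grp in dataset.groupby("arm"):
        ax.scatter(
            grp["months_since_index"], grp["egfr"], s=6, alpha=0.25, color=colors[arm], label=None
        )
        bins = np.arange(0, 19.5, 1.5)
        mids = 0.5 * (bins[:-1] + bins[1:])
        means = [
            grp.loc[
                (grp["months_since_index"] >= a) & (grp["months_since_index"] < b), "egfr"
            ].mean()
            for a, b in zip(bins[:-1], bins[1:])
        ]
        ax.plot(mids, means, color=colors[arm], lw=2, label=arm)
    ax.set_xlabel("months since index date")
    ax.set_ylabel("eGFR (mL/min/1.73 m$^2$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig):
    """Execute the full analysis; returns a dict of results and paths.

    Stage failures raise :class:`PipelineError` naming the stage; outputs
    produced before the failure remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    attrition: list[tuple[str, int]] = []
    results: dict = {"out_dir": str(out)}

    # ---- data ------------------------------------------------------------
    if config.input_dir is not None:
        persons, tables = load_tables(config.input_dir)
    else:
        truth = dataclasses.replace(config.truth, seed=config.seed)
        try:
            persons, tables, _ = generate_cohort(truth)
            if config.apply_deviations:
                tables = inject_deviations(tables, truth, persons)
        except Exception as err:
            raise PipelineError("simulate", str(err)) from err
    _write_csv(persons, out / "persons.csv")
    _write_csv(tables.dispensings, out / "dispensings.csv")
    attrition.append(("persons_total", int(len(persons))))

    # ---- eGFR recomputation ----------------------------------------------
    try:
        egfr = egfr_table(tables.labs, persons)
    except Exception as err:
        raise PipelineError("egfr", str(err)) from err
    _write_csv(egfr, out / "egfr.csv")

    # ---- eligibility ------------------------------------------------------
    try:
        eligibility = elig_mod.apply_exclusions(
            persons,
            tables.dispensings,
            tables.labs,
            policy_date=config.policy_date,
            study_end=config.study_end,
            threshold_days=config.threshold_days,
        )
        covariates = elig_mod.build_covariates(
            persons,
            eligibility,
            egfr,
            tables.weights,
            tables.comorbidity_onsets,
            lookback_days=config.lookback_days,
        )
        imputation = elig_mod.impute_covariates_rf(covariates, seed=config.seed)
        covariates = imputation.completed
    except Exception as err:
        raise PipelineError("eligibility", str(err)) from err
    _write_csv(eligibility, out / "eligibility.csv")
    _write_csv(covariates, out / "covariates.csv")
    attrition.append(("eligible", int(eligibility["included"].sum())))

    # ---- TV-PS matching ---------------------------------------------------
    try:
        disp = tables.dispensings.copy()
        disp["date"] = pd.to_datetime(disp["date"])
        first_taf = disp.loc[disp["drug"] == "TAF"].groupby("person_id")["date"].min()
        cohort = covariates.copy()
        cohort["switch_date"] = cohort["person_id"].map(first_taf)
        disen = pd.to_datetime(
            persons.set_index("person_id")["disenrollment_date"]
        )
        end = disen.fillna(pd.Timestamp(config.study_end)).clip(
            upper=pd.Timestamp(config.study_end)
        )
        cohort["end_date"] = cohort["person_id"].map(end)
        n_events = int(cohort["switch_date"].notna().sum())
        attrition.append(("switch_events_observed", n_events))
        if n_events == 0:
            raise ValueError(
                "no switch events among eligible persons; matching cannot proceed"
            )
        cp = build_counting_process(
            cohort,
            cohort.set_index("person_id")["switch_date"],
            cohort.set_index("person_id")["end_date"],
        )
        model = fit_tvps_model(cp, penalizer=config.cox_penalizer)
        matched, match_info = sequential_match(
            model,
            cohort,
            ratio=config.ratio,
            seed=config.seed,
            caliper=config.caliper,
        )
        if matched.empty:
            raise ValueError("no matched sets were formed")
        indexed = assign_index_dates(matched, cohort, study_end=config.study_end)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("matching", str(err)) from err
    _write_csv(matched, out / "matched_sets.csv")
    _write_csv(indexed, out / "indexed_cohort.csv")
    attrition.append(("switchers_reclassified_as_controls", len(match_info["reclassified_switchers"])))
    attrition.append(("switchers_matched", int((indexed["arm"] == "switcher").sum())))
    attrition.append(("controls_matched", int((indexed["arm"] == "nonswitcher").sum())))
    results.update(
        tvps_model=model, matched_sets=matched, indexed_cohort=indexed, match_info=match_info
    )

    # ---- outcome dataset + main model ------------------------------------
    try:
        dataset = build_outcome_dataset(
            indexed,
            egfr,
            covariates,
            weights_table=tables.weights,
            max_months=float(config.model.time_boundary[1]),
            lookback_days=config.lookback_days,
        )
        posterior = fit_outcome_model(dataset, spec=config.model, seed=config.seed)
        att_main, draws_main = compute_att(posterior)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("outcome", str(err)) from err
    att_main.insert(0, "analysis", "main")
    analyzable = dataset["person_id"].nunique()
    attrition.append(("with_postindex_egfr", int(analyzable)))
    attrition.append(
        ("analyzable_switchers", int(dataset.loc[dataset["arm"] == "switcher", "person_id"].nunique()))
    )
    results.update(dataset=dataset, posterior=posterior, att={"main": (att_main, draws_main)})

    summaries = [att_main]
    if config.run_sensitivity:
        # ---- SA1: adherence censoring ------------------------------------
        try:
            sa1_data = sa_mod.censor_at_deviation(dataset, tables.dispensings, indexed)
            sa1_post = fit_outcome_model(sa1_data, spec=config.model, seed=config.seed)
            att_sa1, draws_sa1 = compute_att(sa1_post)
        except Exception as err:
            raise PipelineError("sa1", str(err)) from err
        att_sa1.insert(0, "analysis", "sa1")
        summaries.append(att_sa1)
        results["att"]["sa1"] = (att_sa1, draws_sa1)

        # ---- SA2: missingness weights ------------------------------------
        try:
            base_cov = indexed[["person_id", "arm"]].merge(
                covariates, on="person_id", validate="one_to_one"
            )
            base_cov["age"] = base_cov["age_at_tdf_init"].astype(float)
            base_cov["male"] = (base_cov["sex"] == "male").astype(float)
            base_cov["included"] = base_cov["person_id"].isin(dataset["person_id"]).astype(int)
            weights = sa_mod.fit_missingness_weights(
                base_cov,
                covariate_cols=None,
                truncate_pct=config.weight_truncate_pct,
            )
            att_sa2, draws_sa2, _ = sa_mod.weighted_outcome_model(
                dataset, weights, spec=config.model, seed=config.seed
            )
        except Exception as err:
            raise PipelineError("sa2", str(err)) from err
        att_sa2.insert(0, "analysis", "sa2")
        summaries.append(att_sa2)
        results["att"]["sa2"] = (att_sa2, draws_sa2)
        results["missingness_weights"] = weights

        # ---- SA3: MI + per-timepoint regressions -------------------------
        try:
            sa3 = sa_mod.mi_per_timepoint_regression(
                dataset,
                timepoints=config.model.timepoints,
                m=config.mi_m,
                seed=config.seed,
            )
        except Exception as err:
            raise PipelineError("sa3", str(err)) from err
        att_sa3 = pd.DataFrame(
            {
                "analysis": "sa3",
                "timepoint_months": sa3["timepoint_months"],
                "median_diff": sa3["estimate"],
                "cri_lo": sa3["ci_lo"],
                "cri_hi": sa3["ci_hi"],
                "pdi": np.nan,
                "rope_fraction": np.nan,
                "n_draws": sa3["m"],
            }
        )
        summaries.append(att_sa3)
        results["att"]["sa3"] = (att_sa3, None)

    att_summary = pd.concat(summaries, ignore_index=True)
    _write_csv(att_summary, out / "att_summary.csv")
    with open(out / "att_summary.json", "w") as fh:
        json.dump(
            json.loads(att_summary.to_json(orient="records")), fh, indent=2
        )
    results["att_summary"] = att_summary

    # ---- balance diagnostics ---------------------------------------------
    design = encode_time_invariant(cohort)
    for cond in ("diabetes", "dyslipidemia", "hypertension"):
        onset = pd.to_datetime(cohort[f"{cond}_onset"])
        at = pd.to_datetime(cohort["switch_eligible_date"])
        design[cond] = (onset.notna() & (onset <= at)).astype(float)
    is_switch_obs = cohort["switch_date"].notna().to_numpy()
    matched_sw = set(matched["switcher_id"])
    matched_ct = set(matched["control_id"])
    smd_pre = standardized_mean_differences(
        design.loc[is_switch_obs], design.loc[~is_switch_obs]
    )
    smd_post = standardized_mean_differences(
        design.loc[cohort["person_id"].isin(matched_sw).to_numpy()],
        design.loc[cohort["person_id"].isin(matched_ct).to_numpy()],
    )
    balance = pd.DataFrame({"smd_pre": smd_pre, "smd_post": smd_post})
    balance.index.name = "covariate"
    balance.reset_index().to_csv(out / "balance.csv", index=False)
    results["balance"] = balance

    if config.make_figures:
        try:
            _trajectory_figure(dataset, out / "egfr_trajectories.png")
        except Exception as err:  # figures are best-effort
            log.warning("figure generation failed: %s", err)

    manifest = {
        "config": config.to_dict(),
        "attrition": attrition,
        "diagnostics": posterior.diagnostics,
        "n_matched_sets": int(matched["set_id"].nunique()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    results["attrition"] = attrition
    return results


def attrition_report(run_dir) -> pd.DataFrame:
    """Ordered attrition counts for a completed run, from its manifest."""
    path = Path(run_dir) / "manifest.json"
    with open(path) as fh:
        manifest = json.load(fh)
    return pd.DataFrame(manifest["attrition"], columns=["step", "count"])
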