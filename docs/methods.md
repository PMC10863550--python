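# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of `tafswitch`.  It is the
package's account of *why* the code does what it does; the README shows how
to run it.

## Estimand and study design

The question is the renal effect of switching PrEP from TDF to TAF among the
people who actually switched: the average treatment effect among the treated
(ATT), expressed as the difference in expected eGFR (mL/min/1.73 m²) between
the switch and no-switch scenarios at fixed times after the (possibly
counterfactual) switch.  Inference for controls' counterfactual is out of
scope — the propensity model deliberately omits time-varying eGFR, so only
the switchers' counterfactual is identified.

Two observational pathologies drive the design:

* **Confounded switch timing.**  Switching is more likely for older people,
  people with lower measured eGFR at the switch-eligible date, and people
  with cardiometabolic comorbidity.  This is addressed twice: by
  risk-set matching on a time-varying propensity score, and by covariate
  adjustment in the outcome model.
* **Immortal time.**  Nonswitchers have no switch date, so any naive
  follow-up origin gives them guaranteed-alive (guaranteed-enrolled) time.
  Each control therefore inherits an *assigned* index date: their own
  switch-eligible date plus their matched switcher's eligibility-to-switch
  interval.  Both arms then have the same distribution of
  eligibility-to-index gaps by construction.

## Renal outcome: CKD-EPI 2021

All eGFR values are recomputed from serum creatinine with the race-free
CKD-EPI 2021 creatinine equation

```
eGFR = 142 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^(−1.200) · 0.9938^age · (1.012 if female)
κ = 0.7 (F) / 0.9 (M),  α = −0.241 (F) / −0.302 (M)
```

Sex enters as the binary EHR field (the equation defines only two
coefficient sets).  Values are kept at full precision; no rounding layer is
added before modeling.  The equation is strictly decreasing and piecewise
power-law in creatinine, so it inverts algebraically; the simulator uses the
exact inverse to emit creatinine so the pipeline's lab input looks like a
real EHR and the forward recomputation path is genuinely exercised.
The inverse rejects targets whose implied creatinine falls outside
0.05–20 mg/dL.

## Cohort entry and exclusions

* Switch-eligible date = the later of (a) the day cumulative TDF days
  supplied first reaches 183, under sequential consumption with carryover
  (gaps between fills delay coverage but never reset the pill count), and
  (b) the policy date on which TAF became available for PrEP (2019-10-01).
  Both the 183-day threshold and the policy date are config knobs.
* Exclusions, one reason per person, in priority order: TAF initiation
  before cohort entry (which subsumes "<6 months of TDF before TAF");
  baseline CKD / lab-abnormality flag (consumed as a simulator-provided
  flag — diagnosis-code phenotyping is out of scope); no cohort entry
  before disenrollment or study end (binned as `disenrolled`; the reason
  vocabulary has no separate administrative-end bucket).
* Covariates "at" the eligible date (weight, eGFR) are the most recent
  measurement on or before it within a 365-day lookback (config knob);
  remaining gaps get a single random-forest imputation (iterated
  missForest-style fit, 50 trees, 2 rounds, seeded).  Comorbidity status is
  an absorbing step function of onset date.

## TV-PS risk-set matching

The propensity model is an extended Cox model for the switch hazard on the
time scale "days since switch-eligible date", in counting-process layout
with intervals split at comorbidity onsets.  Covariates: age at TDF
initiation, race and ethnicity, male sex, ever smoking, insurance, year of
eligibility, weight and eGFR at the eligible date (time-invariant), and
diabetes / dyslipidemia / hypertension status (time-varying).  The fit is
lifelines' `CoxTimeVaryingFitter` with a small ridge penalizer (0.01,
configurable) that stabilises sparse dummy levels; zero-variance columns are
dropped with a warning, no events or separation raise.

Matching walks switch events in calendar order (same-day ties broken by a
seeded draw).  At each event the risk set contains persons who are eligible
by that date, still enrolled, TDF-only through that date (a *future*
switcher is a valid control before their own switch), and not consumed by an
earlier set.  Up to 4 controls are taken nearest by |difference in Cox
linear predictor| with covariates current at the event date; distance ties
break by a seeded draw.  Design choices where the underlying procedure is
open:

* the model is fitted once on the full eligible cohort and scored at each
  event date (no refitting as calendar time advances) — deterministic and
  consistent with a single-model description of the procedure;
* no caliper by default (none is specified for the procedure); a caliper is
  exposed in config;
* sets with fewer than 4 available controls are kept at reduced ratio
  (matched EHR analyses of this design end below their nominal ratio in
  practice, so partial sets are retained rather than discarded);
* a person consumed as a control who later switches is dropped from the
  switcher stream and remains a nonswitcher ("reclassified") — their own
  switch produces no matched set;
* a control whose assigned index date lands after their disenrollment or
  the study end is dropped; a set losing all controls drops its switcher.

## Outcome model

Long-format post-index eGFR (0 ≤ months ≤ 18; a lab exactly at the index
date is kept as month 0 but does not count as follow-up; persons with no
strictly-post-index eGFR are excluded, with counts logged):

```
egfr_ij = x_ij' β + u_person(i) + v_set(i) + ε_ij
ε ~ N(0, σ²),  u ~ N(0, τ_u²),  v ~ N(0, τ_v²)
```

Fixed effects: switch status; age; male; insurance; race and ethnicity;
smoking; weight and eGFR at the switch-eligible date; duration from TDF
start to the eligible date; hypertension and eGFR at the index date; a
natural cubic spline in months since index (4 df, boundary knots at 0 and
18 months, equally spaced interior knots; df configurable); and all pairwise
interactions among {switch status, eGFR at index, each spline column}.
Both eGFR-at-eligible and eGFR-at-index enter, as listed for the original
model; if they alias, the eligible-date term is dropped with a logged
warning, and any other rank deficiency is an error naming the aliased
columns.  Zero-variance columns (a dummy level absent from a small cohort)
are dropped with a warning.  Continuous covariates and spline columns are
standardized internally using fit-data moments that are reused verbatim for
counterfactual prediction rows.

Priors are weakly informative: N(0, 10²) on standardized-scale coefficients
(N(0, 100²) on the intercept) and half-t(3) on σ, τ_u, τ_v via the
Huang–Wand inverse-gamma mixture, which keeps all conditionals conjugate.
Prior scales are config knobs.

### Sampler

A partially collapsed blocked Gibbs sampler, 2 chains × (500 warmup + 1000
kept) draws by default.  The fixed-effect block is drawn with **both**
random-effect blocks marginalized: persons are nested in matched sets, so
the marginal residual covariance is block-diagonal by set and inverts with a
two-level Woodbury identity whose ingredients are precomputable per-person
and per-set weighted design sums.  Then v | β (with u still marginalized)
and u | β, v are drawn, then the variance parameters.  Collapsing removes
the fixed-effect/random-intercept coupling that makes vanilla Gibbs sweeps
on mixed models mix slowly; fixed-effect split-R̂ is ≈ 1.005 at the default
budget.  Split-R̂ and effective sample size (arviz) are logged for all
blocks; the error gate (default 1.02) is applied to the fixed effects —
variance components mix more slowly without affecting the ATT contrast, and
the gate sits above the R̂ estimator's own noise floor (~0.005 at 2×1000
draws) while still catching genuinely slow mixing.

### ATT, PDI, ROPE

For each posterior draw and timepoint m ∈ {0.5, 3, 6, 9, 12, 15, 18}
months, the model predicts mean eGFR over the *switchers'* baseline
covariate rows under switch = 1 and switch = 0 with random effects at zero
(person and set effects cancel in the population-level contrast), and
differences the scenario means; because the contrast is linear, this reduces
to one contrast vector per timepoint applied to the β draws.  Summaries per
timepoint: posterior median, 2.5/97.5 percentiles, probability of direction
(fraction of draws > 0), and the fraction of draws inside the ±2 eGFR-unit
ROPE (closed interval; bounds configurable).  Timepoints beyond the observed
follow-up are computed but flagged as extrapolation.

## Sensitivity analyses

* **SA1 — adherence censoring.**  eGFR rows dated strictly after a person's
  first deviation (nonswitcher dispensing TAF, switcher re-dispensing TDF,
  after the index date; gaps alone are not deviations) are removed and the
  model refitted.  The SA1 dataset is always a subset of the main one.
* **SA2 — missingness weighting.**  Inclusion = having any post-index eGFR.
  A ridge-stabilised logistic model (weak L2, C = 10⁴) of inclusion on the
  baseline covariates gives stabilized weights (marginal / conditional
  inclusion probability), truncated at the 1st/99th percentiles
  (configurable).  Perfect separation — covariates classifying inclusion
  without error — is an error.  Weights enter the Bayesian model as
  probability-weighted pseudo-likelihood at the **person** level: a
  person's weight scales their entire marginal likelihood contribution
  (equivalently, both their residual precision and their random-intercept
  precision).  Weighting only the residual terms would be silently absorbed
  by the person random intercepts, leaving the ATT essentially unchanged.
* **SA3 — multiple imputation.**  Outcomes are binned to the a priori
  timepoints (nearest timepoint within ±6 weeks; closest observation wins,
  seeded tie-break) into a wide per-person layout, honoring "one regression
  per timepoint".  The wide outcome matrix plus numeric baseline covariates
  are imputed m = 10 times with chained equations (scikit-learn's iterative
  Bayesian-ridge imputer drawing from the posterior predictive; predictive
  mean matching is not available in the installed stack, and Bayesian-ridge
  draws serve the same role for continuous outcomes).  Per imputation and
  timepoint, OLS of eGFR on switch status plus the baseline covariates; the
  switch coefficients pool by Rubin's rules (total variance =
  within + (1 + 1/m)·between, small-m degrees of freedom).  SA3 operates on
  the matched persons with at least one post-index eGFR; a timepoint with no
  observed outcomes is flagged unavailable rather than imputed from nothing.

## Synthetic cohort generator

The generator emulates the data-generating setting the analysis assumes,
with every parameter recorded in a manifest (same seed ⇒ byte-identical
tables; all streams split from one master seed via named `SeedSequence`
spawns).

* **Demographics** match an insured adult PrEP population: age ~ N(38, 11²)
  truncated to ≥18, 98% male, race/insurance frequencies from the same
  setting, 25% ever-smokers, weight ~ N(85, 16²).
* **Latent eGFR** per person: intercept N(97, 14²) minus 0.6 units per year
  of age above 38, drifting −1.5 units/year on TDF (the slow decline seen
  on tenofovir DF), with lab noise of 6 units (≈6% biological+assay
  variability) added at visits.  The true switch effect is a configurable
  piecewise-linear function of months since switch (repeated breakpoints
  encode jumps), applied while the person is on TAF.
* **Visits** follow a person-level Poisson process at 4/year (quarterly
  PrEP monitoring); labs at visits are thinned by a logistic MAR model on
  age and the underlying no-switch trajectory (lower eGFR ⇒ more missing by
  default), leaving late follow-up sparse.  A monitoring lab is planted at
  the switch-eligible date and always observed: PrEP renewal requires labs,
  and the switch hazard must act on a *measured* value (below).
* **Switch process**: discrete 30-day hazard steps from the eligible date.
  The log-hazard loads on age, the *observed* eligibility-date eGFR,
  current comorbidity count, smoking, Medicare/Medicaid membership, and
  non-Hispanic White race — mirroring the broad switcher/nonswitcher
  imbalance seen in insured PrEP cohorts.  Confounding acts only through
  covariates the analysis observes: clinicians act on measured labs, and a
  ground-truth generator for a method whose identifying assumption is "no
  unmeasured confounding" must satisfy that assumption, otherwise no
  estimator with this covariate set could recover the truth.  The base
  hazard (0.05/person-year) is sized so that a 600-person cohort yields
  ~90–120 switch events and matching consumes about half the pool — the
  matched-fraction regime of large insured PrEP cohorts, scaled down.  At
  a realistic population switch incidence (~1%/year) a desk-scale cohort
  would contain ~15 switchers and support no inference.
* **Dispensings**: 30- or 90-day fills, refilled at exhaustion with
  occasional short gaps; TDF until switch, TAF after.
* **Comorbidity onsets** (diabetes, dyslipidemia, hypertension): exponential
  hazards scaled by age, with age-dependent prevalence at enrollment
  (prevalent conditions onset at the enrollment date, keeping all event
  dates inside the enrollment interval).
* **Deviations** (`inject_deviations`): switch-backs to TDF
  (0.06/person-year) and late switching by never-switchers
  (0.03/person-year), applied *consistently in exposure and outcome* — the
  lab trajectory is shifted through the exact eGFR↔creatinine round trip so
  the effect follows the actual exposure (immediate washout on reverting).
  Rates are modest, matching the rarity of observed crossover.

### What the generator does not emulate

ICD-coded phenotypes, urinary biomarkers, HIV seroconversion, on-demand
PrEP dosing, lab batch effects, informative disenrollment, and
measurement-error-driven (latent) switch decisions.  Passing tests
therefore show that the pipeline recovers known effects **when its
identifying assumptions hold**; they say nothing about robustness to
unmeasured confounding, which no analysis of this design can deliver.

## Numerical and degenerate-input conventions

* Same-day switch (switch on the eligible date) contributes a half-day
  counting-process interval so the event is retained.
* Same-day event ties in matching and equal-distance control ties break by
  seeded random draws; all pipeline stages draw from seeds derived from the
  single run seed.
* eGFR targets outside the attainable creatinine range, reversed ROPE
  bounds, empty draw sets, empty datasets, missing weights, and rank
  deficiencies all raise with specific messages; stage failures carry the
  stage name and leave earlier outputs on disk.
* The ATT contrast at month 18 usually extrapolates slightly beyond the
  last observed lab and is flagged as such in the log.

## Problem sizes

Default analyses simulate 600-person cohorts (~90–120 switch events,
~50–70 analyzable switchers) and sample 2 chains × 1000 kept draws — the
scale at which the full pipeline runs in seconds and ten-seed recovery
studies in minutes.  Recovery of a +3 eGFR-unit effect from month 3 is
unbiased to within a few tenths of a unit averaged over seeds; per-seed
posterior medians scatter with an SD near 1 unit, matching the ~±2.5-unit
credible intervals that a matched cohort of roughly a hundred switchers
supports.

## Known limitations

* One-dimensional propensity matching balances strongly confounded
  covariates (pre-matching SMD ≳ 0.3 shrinks to ≲ 0.12) but cannot
  systematically improve covariates whose true imbalance sits below the SMD
  sampling noise floor (~0.11 at ~90 switchers); their post-matching SMD is
  noise on a smaller sample and grows as often as it shrinks.
* The switch main effect is identified between persons; with person random
  intercepts its posterior precision is bounded by the matched switcher
  count, not the lab count.
* SA3's per-timepoint cross-sectional regressions estimate an adjusted
  arm difference, not the longitudinal ATT; under confounding they are
  attenuated relative to the mixed model, which the four-analysis layout
  makes visible rather than hiding.
* The Cox ridge penalizer (0.01) mildly shrinks propensity coefficients;
  set it to 0 to reproduce pure partial likelihood on well-conditioned
  cohorts.
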