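# Methods

`tkisim` couples population pharmacokinetic (PK), pharmacodynamic (PD),
tumor, and time-to-event models into virtual clinical trials of two
tyrosine-kinase inhibitors: sunitinib in gastro-intestinal stromal tumor
(GIST) and axitinib in metastatic renal-cell carcinoma (mRCC). This note
records the models, their assumptions, the parameterization, the numerical
choices, and the known limitations.

## Framework wiring

**Sunitinib / GIST.** Oral sunitinib and its active metabolite SU12662 are
described by linear one-compartment disposition models with first-order
absorption; the metabolite is formed from a fraction `fm` of parent
clearance. The therapeutic-drug-monitoring (TDM) concentration is the
parent + metabolite sum. Downstream:

* **sVEGFR-3** and **sKIT** follow turnover (indirect-response) models,
  `dX/dt = kin (1 − Imax·C/(IC50+C)) − kout X`, driven by total
  concentration.
* **ANC** follows a transit-compartment myelosuppression model
  (proliferating pool → three transit compartments → circulating pool,
  feedback `(base/circ)^γ`), its proliferation inhibited in proportion to
  the relative sVEGFR-3 decrease (sVEGFR-3 acts as the common
  pharmacological-activity signal).
* **Platelets** follow the same chain with an Emax effect of the rolling
  24-h AUC; **diastolic blood pressure** (dBP) is a turnover model with a
  *linear* stimulation by daily AUC (the one non-saturating exposure–effect
  relationship in the framework).
* **Fatigue** and **hand-foot syndrome (HFS)** are daily
  proportional-odds Markov models (grades 0–3): `logit P(G_t ≥ k) = θ_k +
  β·x + κ·G_{t−1}` with the relative sVEGFR-3 decrease as driver `x`.
* **Tumor size** (SLD, mm) follows a growth-inhibition model with
  saturating growth and resistance,
  `dT/dt = kg·T·(1 − T/Tmax) − E(t)·e^{−λt}·T`, where `E(t)` sums kill
  contributions from the relative sVEGFR-3 and sKIT decreases and an Emax
  function of daily AUC. The carrying capacity (1200 mm) prevents the
  unbounded exponential regrowth that would otherwise dominate the
  size-driven dropout hazard; `λ` models resistance appearance.
* **Overall survival** comes from proportional-hazard models with Weibull
  baselines and time-varying model-derived covariates. Two frameworks are
  available: a toxicity-driven model (TAD; covariates ΔdBP(t) = relative
  dBP change, scaled ANC change (ANC−5)/5, and baseline SLD) and an
  sVEGFR-3-driven model (BAD; covariates ΔsVEGFR-3(t) and baseline SLD).
  In both, biomarker movement that indicates pharmacological response
  (dBP rise, ANC drop, sVEGFR-3 drop) lowers the hazard. Non-sVEGFR-3-
  guided protocols default to TAD; sVEGFR-3-guided ones to BAD.
* **Dropout** is exponential-baseline with progression status and current
  SLD as covariates (axitinib adds daily AUC); dropout stops treatment but
  survival follow-up continues.

**Axitinib / mRCC.** One-compartment PK (2.4 h elimination half-life at
typical parameters); sVEGFR-3 turnover as above; dBP turnover with an
*Emax* stimulation by concentration, inter-individual variability on
baseline, drug effect and turnover, and a combined additive + proportional
residual error; tumor driven by sVEGFR-3 alone; OS driven by current SLD
and progression status.

Progression is RECIST-like: the first time SLD exceeds the running nadir
by ≥20% *and* ≥5 mm (both config-overridable), evaluated continuously on
the simulation grid because it drives hazards, not imaging decisions.

## Virtual populations

Weight ~ Normal(73.5, 18.7) kg for GIST (Normal(76.7, 11.6) for mRCC),
truncated to [36, 185] kg; baseline SLD ~ log-normal with arithmetic mean
182.7 mm and SD 134.2 mm (log-scale parameters by moment matching),
truncated to [29, 822] mm. Truncation is by rejection, preserving the
in-range shape; note the weight truncation cuts only the lower tail, so
the truncated mean is ≈74.5 kg. Random effects are independent log-normal
per parameter. Every patient owns an RNG substream keyed on (seed, id),
so populations are reproducible and extending a population never perturbs
existing patients. Baseline biomarkers are each submodel's steady state
under the patient's own etas.

## Trial engine

All patients are integrated simultaneously on a fixed step (default 2 h):
exact matrix-exponential PK with doses as bolus state resets; exact
exponential updates for the turnover models under piecewise-constant
drive; classical RK4 for the (nonlinear) transit chains; an exact
Bernoulli-ODE step for the tumor; trapezoidal accumulation of the OS and
dropout cumulative hazards with inverse-transform event times
(`H(t) ≥ −log u`, linearly interpolated within the step).

The clinical protocol: labs (ANC, platelets, dBP) are observed only on
days 15, 29, 43, 57, 85, 113 and every 12 weeks thereafter; fatigue/HFS
are spontaneously reported daily. Severe toxicity (≥G3 labs, ≥G2
fatigue/HFS, CTCAE v3.0 cut-offs with ties to the more severe grade)
withholds the drug until recovery (≤G1); a first severe episode resumes at
the same dose, a repeated or very severe (G4 labs / G3 categorical) one
resumes one pool level lower, floored at 0. Withheld patients are
re-checked weekly outside the routine calendar (recovery monitoring).
Biomarker-guided adaptation acts at lab days only, after toxicity rules:
a sub-target signal (trough below cutoff; biomarker movement smaller than
the cutoff fraction) steps one pool level up, capped at the pool maximum;
base-case arms allow no escalation. Dose decisions use *observed* grades;
outcome summaries use the true daily state.

Intermittent high-dose schedules use coarse pools — sunitinib 100–700 mg
in 100 mg steps, axitinib 10–80 (QW) / 80–140 mg (Q2W), each plus 0 — so
reductions step within the high-dose range rather than onto the daily
ladder.

Every stochastic draw (survival/dropout uniforms, daily categorical-AE
uniforms, residual errors) is keyed on (population seed, patient id,
purpose), independent of the protocol: arms and cutoffs are compared under
common random numbers, and a threshold that never triggers reproduces the
fixed-dose arm bit-for-bit.

The reported week-102 "survival %" is the simulated true fraction alive
(the simulator knows each death time; dropout does not censor). The
per-AE "max %" is by default the fraction of patients whose maximum grade
reached the severe level; maximum point prevalence is available as a
config switch.

## MAP forecasting

The prospective-evaluation experiment simulates observations
`y = f·(1+ε_p) + ε_a` on daily/weekly/biweekly pre-dose schedules over
0–8 weeks, then estimates each patient's random effects by minimizing the
standard individual objective with interaction,
`Σ_j [(y_j − f_j)²/g_j² + log g_j²] + ηᵀΩ⁻¹η`, `g² = (σ_p f)² + σ_a²`,
batched across patients with L-BFGS-B (central-difference gradients per
eta dimension) and multi-start (η = 0 plus jittered starts; the best mode
per patient is kept; exhausted iteration budgets are flagged). Zero
observations return the prior mode η = 0. Each biomarker chain estimates
a small eta subset (e.g. baseline + potency for sVEGFR-3; clearances and
volume for TDM; baseline, drug effect and turnover for axitinib dBP);
unestimated upstream etas act as residual model misspecification, as they
would in practice. Predictions use a 2–4 h stepping of the same chain
that generated the data, so the noise-free identifiability check is exact
up to optimizer tolerance.

Week-8 (t = 1,344 h) changes are: the trough concentration itself (TDM),
the scaled ANC change (ANC−5)/5 against the 5×10⁹ cells/L population
baseline, and relative changes from individual baseline for dBP and
sVEGFR-3. Accuracy is the ratio of the measured (Y) or forecast
(IPRED_est) change to the true change (IPRED_true); decision
sensitivity/specificity score the implied dose-increase recommendation at
the framework cutoffs against the true-parameter decision.

## Health economics

Per patient over a 5-year horizon: life-years = time to death capped at
the horizon; daily utility = baseline utility × disease-status factor ×
product of the five AE grade factors (multiplicative decrements); QALY =
life-years × mean daily utility over the treatment period (the sum of
daily utilities divided by treatment days — the utility sum deliberately
runs over treatment days, matching the denominator). Costs: drug priced
by minimal-capsule decomposition (dynamic program; ties broken by lowest
price; strengths configurable, 12.5/25/37.5/50 mg default), follow-up
tariffs on the monitoring calendar plus 12-weekly imaging, and a per-event
AE cost charged on each transition to a higher grade. ICERs are computed
on arm medians (strategy vs fixed dosing on the same population under
common random numbers) with bootstrap-over-patients percentile intervals;
non-positive effect differences are reported as dominance classifications
rather than ratios. No discounting by default; a yearly rate is available
for sensitivity analyses. Bundled prices and utilities are placeholder
tariffs — they are pure config, and any published tariff set can be
substituted.

## Parameterization

No parameters are estimated from data in this package. The bundled
`*_reference.yaml` sets take their *structures* from the published source
models (sunitinib/SU12662 popPK; turnover models for sVEGFR-3, sKIT and
dBP; the transit-compartment myelosuppression model; ordered-categorical
AE models; a Claret-type tumor model; parametric OS/dropout models) with
representative magnitudes fixed once at design time; each parameter
carries a provenance string. A `*_fallback.yaml` twin holds round numbers
for structural testing. Two calibration anchors were used, once, when the
reference sets were frozen:

* the Weibull OS baselines were solved so the fixed-dose reference arms
  sit at the clinically reported week-102 OS (≈48% GIST, ≈65% mRCC) under
  the shipped effect parameters and protocol (pilot covariate paths →
  scale solve → one interpolation pass at n = 400);
* AE effect magnitudes were chosen so severe-AE incidences sit in the
  clinically reported ranges (CD sunitinib: neutropenia ~4%,
  thrombocytopenia ~8%, HFS ~9%, fatigue ~1%, hypertension low, rising
  strongly under biweekly high dose).

Units package-wide: time h, concentrations ng/ml, doses mg, cell counts
10⁹/L, SLD mm, dBP mmHg.

## Numerical choices

Engine step 2 h by default (must divide 24 h and the dosing interval);
outcomes are insensitive to halving it (median death-time shift < 2 days).
The standalone PK grid is 1 h for 72 h after any regimen change and 6 h
otherwise; exposure metrics are trapezoidal and shown grid-insensitive at
1 h. Turnover updates are exact for piecewise-constant drive (the drive
is frozen at each step's left edge). MAP convergence tolerance 10⁻⁶ on
the objective, iteration cap with flagging; multi-start default 5 in the
API (examples and batch runs use 1–2 where the landscape is benign).
Event-time interpolation is linear in cumulative hazard within a step.
CTCAE boundary values map to the more severe grade by documented
convention.

## What the generator does and does not emulate

The virtual populations reproduce the stated covariate distributions,
log-normal parameter variability, residual-error-corrupted observations
on the stated monitoring calendar, and protocol-faithful dose logic. They
do **not** include covariate correlations, parameter uncertainty
(fixed effects are point values), adherence variation, concomitant
medication, or inter-occasion variability. Passing tests therefore
demonstrate internal consistency of the machinery and faithfulness to the
stated study design — not predictive validity for real patients.

## Known limitations

* With every efficacy channel routed through sVEGFR-3 and saturating
  exposure–effect relationships, the GIST continuous-vs-intermittent
  comparison comes out approximately OS-neutral (the biweekly 700 mg arm
  delivers a higher dose-equivalent that offsets its washout rebound); the
  axitinib framework, whose short half-life allows full inter-dose
  rebound, shows the clear OS advantage of continuous dosing.
* sVEGFR-3-guided escalation helps the right patients (weak responders)
  but the resulting OS gain is smaller than the gains from TDM- or
  toxicity-guided escalation under this parameterization.
* The MAP chains estimate per-biomarker eta subsets; joint estimation
  across the full framework is not implemented.
* Costs and utilities are placeholders; absolute cost outputs are
  illustrative until real tariffs are configured.
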