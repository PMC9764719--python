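# Methods

## Problem and estimand

The package studies the causal effect of *time-varying* hospital bed
occupancy on short-term in-hospital mortality. Each hospital's daily
**capacity utilization** (CU) is its in-house census as a percentage of its
busiest day of the year; a day is a **high-exposure** day when CU is at or
above the hospital's own 85th-percentile threshold. Each inpatient episode
is followed for at most 14 stay-days; the outcome is daily in-hospital death
within that window.

The estimand is the per-day marginal odds ratio: the multiplicative change
in the daily odds of death per additional *cumulative* day of high-exposure,
under interventions on the exposure path. Ordinary covariate adjustment
cannot identify it because of **treatment-confounder feedback (TCF)**:
today's utilization affects tomorrow's patient turnover, which confounds
tomorrow's utilization, and an unmeasured care-pressure process (staffing
shortfalls, demand surges) drives both turnover and mortality. On the
two-day causal graph shipped with the package, an exhaustive search over all
subsets of measured covariates finds no valid backdoor adjustment set, and
conditioning on day-two turnover opens a collider path
(CU1 → PT2 ← U → M2). The package therefore estimates the effect with a
marginal structural model (MSM) fitted by stabilized
inverse-probability-of-treatment weighting (IPTW).

## Analysis chain

1. **Inclusion filters.** Episodes admitted before day 1 of the study year
   or after day `year_length − 14` are dropped (no full history or follow-up
   window).
2. **Daily series.** Census uses the half-open convention
   `[admission, discharge)`, with same-day stays present on the admission
   day. `CU_d = 100·census_d / max_d census_d` and turnover
   `PT_d = 100·(admissions_d + discharges_d) / max_d census_d`; the daily
   mean Patient Clinical Complexity Level (PCCL, ordinal 0–4) summarises the
   in-house case-mix. Normalising by peak census reads "capacity" as the
   busiest realised occupancy; a switch allows the closed-interval census.
3. **Exposure.** Per hospital, the threshold is the linear-interpolation
   sample quantile (default 85th percentile) of the year's daily CU; ties
   (`CU = threshold`) count as exposed. Because the census is
   integer-valued, the exposed-day share is 15% only up to the tie mass at
   the threshold — small hospitals can sit a few points above.
4. **Person-day expansion.** One row per at-risk stay-day
   `t = 1..min(stay, death, 14)`, carrying the same-day exposure `A_t`, its
   running count `cumA_t` (the death day's exposure counts; a switch lags
   it), the hospital-day confounders `L_t = (PT, mean PCCL)` and baseline
   covariates `V` (sex, 5-year age band as numeric, hospital type,
   comorbidity-weight class, weekend admission).
5. **Stabilized weights.** Pooled logistic models for
   `P(A_t | Ā_{t−1}, V, t)` (numerator) and the same plus `L_t`
   (denominator); exposure history enters as the previous day's exposure and
   the lagged cumulative count; the stay-day index is categorical. The
   stabilized weight is the within-patient cumulative product of
   numerator/denominator probabilities of the observed exposure. Mean
   weights deviating from 1 by more than 0.05 raise a misspecification
   flag; truncation at the weights' own 1st/99th percentiles is available.
6. **Outcome models.** Weighted pooled logistic regression of daily death on
   the exposure term (cumulative count, or the same-day indicator for the
   short-term variant) plus `V`, fitted as a GEE with independence working
   correlation — non-independence working structures can bias weighted
   estimates — and cluster-robust sandwich variances, by hospital by
   default (`patient` available). Reference levels: university hospitals;
   negative comorbidity class. CIs are normal-approximation on the log-odds
   scale. The outcome model omits a stay-day term by default (switchable):
   the cumulative count already grows with t, and the marginal per-day
   contrast is the target.

## Synthetic study year

No patient-level hospital registry of this kind is publicly shareable, so
the package ships a generator whose defaults emulate the study conditions,
with every causal arrow explicit:

* **Admissions** are Poisson per hospital-day; the rate scales with hospital
  size and halves on weekends (≈16% weekend admissions). Five hospitals of
  types 1–5 (expected peak census 320 down to 60) yield ≈21,000 episodes per
  year.
* **Length of stay** is geometric via a daily discharge probability
  `1/6.2`, so days-present average ≈6.2.
* **Care pressure `U`** is a hospital-level AR(1) process (coefficient 0.7,
  innovation SD 0.4). It slows discharges (`×exp(−0.4·U)`), and with
  the `staffing_admission_coef` channel boosts admissions — both visible to
  the analyst only through the day's turnover. It multiplies the daily
  death odds by `exp(γU)` (default γ = 0.5). It is the unmeasured common
  cause of turnover and mortality.
* **Occupancy feedback.** A day above the hospital's running
  85th-percentile census throttles next-day admissions and speeds next-day
  discharges by `exp(∓δ)` (default δ = 0.3): the exposure feeds the next
  day's turnover — the TCF arrow.
* **Mortality.** After the year of flows is generated, the exposure is
  derived from the pre-death episodes with the *same* threshold machinery
  the analysis uses, and each patient's daily death hazard over the first
  14 stay-days is
  `expit(α0 + βA·cumA_t + β'X_i + γ·U_{h,d})` with βA = log(1.02) by
  default and covariate effects on the scale of a large inpatient registry
  (age +0.028 per 5-year band, female −0.27, comorbidity classes up to
  +2.06, weekend +0.09, hospital-type offsets). α0 = −7.5 puts 14-day
  mortality at ≈1.5%. A death closes the episode on the death day (death
  precedes discharge).
* **Covariate mix**: 53.4% female; age, PCCL and comorbidity-class
  frequencies follow a large general-hospital population; the numeric
  comorbidity weight is drawn within its class.

Deaths truncate stays *after* the flows are simulated, so the census the
analyst re-derives differs from the hazard-time census by the ~1.5% of
stays cut short at death; this measurement discrepancy is part of what the
pipeline must tolerate and is negligible at the default event rate.

What the generator does **not** emulate: inter-hospital transfers, ward- or
unit-level structure, seasonal admission waves, severity-dependent length
of stay, within-stay evolution of the comorbidity burden, and any exposure
effect beyond day 14. Passing tests therefore show that the estimator
recovers known truths under this mechanism, not that estimates from any
particular national registry are reproduced — those require the
access-restricted data.

## The randomized-exposure oracle

The true marginal per-day effect is computed by simulation: the same
outcome mechanism (baseline covariates, U-process, hazard) with daily
exposure drawn i.i.d. Bernoulli at the observational person-day prevalence,
severing every arrow into the exposure. An unweighted pooled logistic of
daily death on `cumA_t + V` on this randomized world returns the MSM's
target coefficient with a Monte-Carlo SE. Because the outcome is rare, the
marginal coefficient sits close to the conditional βA in unconfounded
configurations (near-collapsibility), and the hazard-selection effect of the
unmodelled `U` heterogeneity is part of the estimand — the oracle measures
exactly what the MSM can at best estimate.

## Named validation configurations

* **Study year** (default): the full-scale five-hospital year above.
  Weight calibration on it gives a mean stabilized weight of 0.98–0.99
  across seeds (tolerance band 1.00 ± 0.02).
* **Severe-TCF benchmark**: three hospitals, one year, with the
  U→admissions channel at 1.0, discharge channel 0.4, AR 0.75, SD 0.6 and
  γ = 1.8; mortality intercept −6.5 so each replicate carries enough
  events. Here the unweighted GEE is biased by ≈ +0.09 on the log-odds
  scale while the IPTW-MSM is not. Replicate sizes (~7,400 episodes) are
  chosen so the weighted estimator's sampling noise does not swamp the bias
  being demonstrated: with much smaller cohorts the comparison is
  uninformative for any generator. Over 200 replicates the mean absolute
  error against the oracle is 0.094 (unweighted), 0.088 (IPTW) and 0.054
  (IPTW with 1st/99th-truncated weights). The truncated arm is the headline
  comparison: under severe feedback a few replicates produce extreme weight
  products, and clipping the tails is the standard variance-control
  analysis — the same one the main pipeline exposes.
* **Unconfounded**: all feedback/confounder channels off; the hazard is
  exactly logistic, so the naive fit recovers βA and its 95% CI covers the
  truth at the nominal rate (measured 0.950 over 200 replicates; the
  coverage study clusters at the patient level because three hospitals are
  too few clusters for a calibrated hospital-level sandwich).

## Numerical and design choices

* Quantiles everywhere are linear-interpolation sample quantiles (the
  common default); exposure ties are exposed; weight truncation clips at
  sample percentiles of the weights themselves.
* Exposure-model separation or non-convergence raises an estimation error
  naming the stage; replicate studies drop and count such replicates
  (≈1–2%).
* Positivity: denominator probabilities outside `(1e−9, 1−1e−9)` raise a
  warning with the row count rather than silently producing infinite
  weights.
* Degenerate inputs: empty cohorts, single-level exposure or outcome, zero
  clusters and invalid percentile bounds raise typed errors; a percentile
  sweep entry with sparse exposure (fewer than ~5 exposed days per
  hospital) is flagged, not fatal.
* All randomness derives from one master seed through
  `numpy.random.SeedSequence` spawning; identical configuration and seed
  reproduce cohorts byte-identically and estimates exactly.
* d-separation is decided by a reachability (Bayes-ball style) traversal;
  the test suite checks it against an exhaustive path-enumeration oracle on
  every ≤4-node DAG (all queries) and on random 6- and 8-node DAGs, and the
  local Markov property on the shipped graph.

## Known limitations

* The weight models condition on the same-day turnover and complexity plus
  a coarse exposure history; confounding that reaches the exposure only
  through the *accumulated* census (e.g. a pressure process acting purely
  on discharges) is not removable by these weights — in that regime
  weighting neither helps nor hurts. The severe-TCF benchmark represents
  the DAG's intended structure, where the unmeasured process reaches the
  exposure through the measured flows.
* Exposure is shared by all patients in a hospital on the same day, but
  weights are estimated at the patient-day level, as in the original
  analysis; the hospital-level dependence is addressed only through the
  cluster-robust variance.
* Discharge competes with death and is itself affected by occupancy; the
  pipeline (like the analysis it reimplements) does not model it as a
  competing risk.
* With a single simulated year the per-day effect log(1.02) is smaller than
  one year's sampling noise (robust SE ≈ 0.07 at ~110,000 person-days), so
  the worked example's point estimate is statistically indistinguishable
  from the null by design; the replicate studies carry the evidence.
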