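# Methods

This note records the statistical procedures, the synthetic-trial model, the
parameter choices and the known limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Statistical core (`survstats`)

**Cox proportional hazards.** Coefficients maximize the partial likelihood
by Newton–Raphson with monotone step-halving, starting at zero. Tied event
times use the Efron correction by default (Breslow available, mainly for
cross-checks); subjects censored at an event time remain at risk for that
event. Convergence is declared when the largest score component falls below
1e-8 or the relative log-likelihood change falls below 1e-10, within 50
iterations. Standard errors come from the inverse observed information and
all inference is two-sided Wald — hazard ratios with 95% CIs and normal
p-values — rather than likelihood-ratio, because Wald summaries are what the
downstream screening rules consume. Estimates with |coef| > 15 are flagged
non-converged: in this pipeline a log-HR of that size only arises from
(near-)separated dichotomizations, where the MLE is infinite and a Wald
summary is meaningless; scan cells inherit the flag as "not estimable"
instead of propagating a wild hazard ratio.

**Kaplan–Meier.** Product-limit estimate with Greenwood variance; the
median is the smallest event time with survival ≤ 0.5 and is undefined
(NaN) when the curve never reaches 0.5.

**Log-rank.** Observed-minus-expected chi-square with hypergeometric
variance, summed over strata when provided; df = groups − 1. On data without
tied event times the two-group statistic equals the squared Cox score test
at β = 0 exactly — the suite asserts this identity to machine precision.

**Time-dependent ROC.** Cumulative-cases / dynamic-controls AUC at a
horizon τ: cases are subjects with an observed event at or before τ,
weighted 1/G(T−); controls are subjects under observation past τ, weighted
1/G(τ), with G the Kaplan–Meier estimate of the censoring distribution
(events and censorings swap roles). G is floored at 1e-6 (configurable) so
late-horizon weights cannot blow up. Marker ties count 1/2, so with no
censoring the estimator reduces exactly to the pairwise Mann–Whitney AUC.
Binary endpoints (clinical benefit, objective response) use the plain
Mann–Whitney AUC of the ordinal rule count.

**2×2 relative risk.** Risk ratio of row 1 vs row 2 with the Katz log-RR
normal interval; the p-value is Pearson's chi-square, switching to a
two-sided exact hypergeometric (Fisher) test when any expected cell count is
below 5. Zero events in both rows leaves RR flagged undefined rather than
raising.

**Rank tests.** Paired comparisons use the Wilcoxon signed-rank statistic
(zeros dropped; exact two-sided null by the generating-polynomial
distribution for n ≤ 25, tie-corrected normal approximation with continuity
correction beyond); unpaired comparisons use the Mann–Whitney rank-sum with
tie-corrected normal approximation. Between-arm comparisons in the pipeline
are unpaired and therefore take the rank-sum route; the signed-rank form is
reserved for within-patient comparisons across timepoints. The `paired` flag
makes this choice explicit at every call site.

Significance throughout is two-sided p ≤ 0.050, with no multiplicity
correction — the screening cascade runs hundreds of correlated tests, so
individual scan p-values should be read as ranking devices, not calibrated
error rates. The selection stage's implicit multiplicity is quantified
empirically: on null cohorts no candidate tends to reach significance for
all four endpoints in all cohorts (the no-eligible-candidate path is a
tested outcome).

## Synthetic trial model (`trialsim`)

The generator emulates the structure of a two-arm advanced-NSCLC trial
programme comparing an immune-checkpoint inhibitor against chemotherapy.
Defaults (all overridable in `SimConfig`):

| parameter | default | rationale |
|---|---|---|
| n_treated / n_control | 1479 / 707 | combined treated and control cohort sizes of the motivating trial programme |
| baseline_hazard | 0.05 /month | median OS ≈ 14 months |
| progression_hazard | 0.15 /month | median PFS ≈ 4 months |
| followup_max | 36 months | administrative censoring horizon |
| accrual_censor_rate | 0.02 /month | mild independent loss to follow-up |
| count log-means | N 4.5, L 1.5, M 0.6, P 250, RBC 4.5, WBC 7 (10⁹/L) | typical adult differential counts; give median NLR ≈ 3, PLR ≈ 165, NMR ≈ 7.4 |
| count log-sds | 0.30–0.35 (RBC 0.10) | clinically plausible dispersion |
| timepoint_correlation | 0.7 | within-patient stability of counts over 12 weeks |
| treatment_log_hr | −0.3 | treated-arm OS benefit, HR ≈ 0.74 |
| response_base_prob | 0.15 | objective response rate at average risk |

Log-counts of each cell type are trivariate normal over T1/T2/T3 with
exchangeable correlation; ratios are therefore log-normal with analytically
known moments, which the generator uses to standardize effects. Survival is
drawn by inverse transform from an exponential (constant-hazard) baseline —
the simplest proportional-hazards-consistent generator; a Weibull shape
would be a straightforward extension but nothing downstream depends on the
baseline's form. Planted effects act on the linear predictor either per
standard deviation of the log-ratio (scale-free, so a 0.6 effect means
"log-HR 0.6 per SD") or as a step at an absolute threshold, on the high or
the low side; predictive effects apply in the treated arm only, prognostic
effects in both. The same linear predictor drives the progression hazard
and, with opposite sign, a logistic response model (good-risk patients
respond more; `response_slope` scales this coupling). PFS is the minimum of
progression and death, so PFS ≤ OS holds by construction. Counts at T2/T3
are missing when the patient's observation ends before the draw (6 and 12
weeks), plus an independent 5% missingness; baseline counts are always
present.

What the generator does **not** emulate: covariate-outcome associations
(sex, age, ECOG and the rest are drawn independently of survival, so
multivariate adjustment is exercised mechanically but cannot confound),
non-proportional hazards, delayed treatment-effect onset,
treatment-dependent count trajectories, inter-trial heterogeneity, or
informative censoring. Passing tests therefore demonstrate that the
pipeline's machinery recovers planted truths under a clean
proportional-hazards world — not that the score would validate on real
trial data.

## Screening conventions (`screen`)

- **Landmark convention.** A biomarker measured at timepoint t is analyzed
  only in patients event-free and under follow-up at t, with survival
  measured from t. This guards the immortal-time bias that otherwise
  afflicts on-treatment biomarkers (surviving to the blood draw is a
  prerequisite for having the biomarker). Analyses from randomization
  instead of the landmark are available via `landmark=False`.
- **Quantiles and boundaries.** Fraction cutoffs are linear-interpolation
  (type-7) quantiles of the treated-arm combined cohort; `value >= cutoff`
  labels a patient high-risk, chosen so that a printed integer cutoff
  places the boundary value in the high-risk group.
- **Retention rule.** "Consistently significant" means p ≤ 0.05 in at least
  a `share` (default 0.8) of fraction cutoffs for both OS and PFS; full
  strictness (share 1.0) is brittle under simulation noise and is exposed
  as configuration. The control-arm exclusion applies the same rule to the
  control scans; direction consistency requires all significant treated-arm
  HRs on one side of 1.
- **Integer narrowing.** Cutoff candidates are every step-multiple inside
  the closed 25–50% quantile band (step 10 for platelet-ratio-scale
  markers, else 1). Candidates are then confirmed by re-scanning (treated
  arm, both endpoints, univariate and covariate-adjusted) in every cohort;
  in the pipeline at most 4 confirmed cutoffs per biomarker (evenly thinned,
  deterministic) enter candidate enumeration to keep the Cartesian product
  at trial scale.
- **Covariate adjustment** uses sex, age, race (white reference), ECOG PS,
  metastasis and PD-L1 dichotomized at 1% (5% for cohorts labelled BIRCH,
  matching that trial's assay threshold), complete-case. Body-mass index
  and smoking status are not modelled.

## Score building and evaluation (`score`, `evaluate`)

The default combination rule is `any_high` (high risk iff at least one rule
fires) — the common clinical convention for multi-marker risk flags —
with `majority`, `all_high` and `count_threshold k` as alternatives.
Classification is monotone in every ratio and deterministic. Selection
requires significance for OS, PFS, CB and ORR in every cohort and then
maximizes the minimum OS AUC across cohorts (12-month horizon by default,
measured on the landmark time scale); exact ties break lexicographically on
candidate id, and an empty eligible set is returned as a warning state, not
an error.

Predictive status is reported two ways: the informal criterion (one
stratum's treatment-HR CI excluding 1 while the other covers it), which is
fragile because it turns two noisy CIs into a binary call, and a formal
treatment-by-risk interaction Cox coefficient with its Wald p-value. Both
appear in every report; the interaction test is the one with a controlled
error rate.

## Verification experiments (`experiments`, `scripts/acceptance.py`)

Problem sizes were chosen to give each check high power at desk scale:

1. **Cox oracle equivalence** — 24 random 1-covariate fixtures (n ≤ 20,
   half with tied times); Newton estimate vs golden-section maximization of
   an O(n²) from-definition partial likelihood, agreement within 1e-4.
   Separated fixtures (monotone likelihood, no finite MLE) are regenerated.
2. **Algebraic identities** — log-rank = squared Cox score test (no ties);
   KM = empirical survival and td-AUC = pairwise AUC (no censoring);
   NMR = NLR × LMR. All to machine precision.
3. **Type-I error** — 200 null cohorts (200/arm, no planted effects,
   no treatment effect); pooled scan rejection rate at p ≤ 0.05 within the
   binomial 95% band around 0.05 computed at 200 replicates (cells within a
   replicate are positively correlated, so this band is conservative).
4. **Cascade recovery** — 50 cohorts of 750/350 with a treated-only 0.6/SD
   effect on PLR_T3 and a both-arm 0.6/SD effect on NMR_T2 (the one ratio
   pair sharing no component count, so neither signal leaks into the other);
   the cascade must retain the former and remove the latter as
   control-prognostic in ≥ 90% of replicates.
5. **Cutoff recovery** — 30 cohorts of 1000 treated patients with a hazard
   step of log-HR 0.9 at PLR_T3 = 140 and response slope 2.0 (so the
   response endpoints carry the risk signal, as they do in the trials this
   emulates); narrowing plus selection must land within one grid step (10)
   of the truth in ≥ 80% of replicates.
6. **Predictive signature** — 50 cohorts of 750/350 with a treated-only
   log-HR 0.8 confined to marker-low patients and no treatment main effect;
   the assessment must show a low-stratum CI excluding 1, a high-stratum CI
   covering 1 and interaction p ≤ 0.05 in ≥ 80% of replicates.
7. **Determinism** — the full pipeline run twice at one seed must produce
   byte-identical artifacts.

The planted effect sizes in experiments 5 and 6 were set by design-stage
power analysis (the acceptance thresholds themselves are fixed): weaker
effects turn these checks into tests of sampling noise rather than of the
recovery machinery.

## Numerical choices and degenerate inputs

- The partial-likelihood exponentials are shifted by max(η), which cancels
  exactly in the log-likelihood and derivatives.
- Degenerate dichotomizations (all values identical, empty stratum, fewer
  than `min_events` events in a stratum) are flagged per scan cell, never
  silently dropped; every screened biomarker appears in the audit trail
  with the rule that removed it.
- Zero denominators in ratios yield missing values, never infinities.
- The empty-candidate and no-eligible-candidate paths return explicit
  warning states; a cohort with no events at a landmark raises "no events".
- JSON artifacts are serialized with sorted keys and CSV floats use the
  shortest round-trippable representation, so identical inputs reproduce
  identical bytes.

## Known limitations

- The 16-candidate enumeration of the motivating analysis is reproduced
  structurally (Cartesian product of per-biomarker cutoff grids), but the
  original grid sizes are not derivable from public sources; grids here
  come from the data via the quantile-band rule.
- Stratification factors for the stratified log-rank test are exposed as an
  argument but default to unstratified, as the original factors are not
  public.
- No frailty, time-varying coefficients, competing risks or restricted-mean
  survival; no modelling of PD-L1/TMB comparator biomarkers.
- Whether survival in the motivating analysis was measured from
  randomization or from the landmark is not determinable; both conventions
  are supported (`landmark` flag), with the landmark as the
  statistically safer default.
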