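# Methods

This note documents the statistical model behind the package, the
conventions and defaults that matter for reproducing its numbers, and what
the synthetic-data experiments do and do not establish.

## The score and its risk groups

The iSEND score is an integer sum of three components: male sex (1 point),
ECOG performance status >= 2 (1 point), and the composite haematology
biomarker — baseline neutrophil-to-lymphocyte ratio NLR1 >= 5 *and*
on-treatment change dNLR = NLR2 − NLR1 >= 0 (2 points). Both composite
inequalities are inclusive: NLR1 exactly 5 with dNLR exactly 0 scores the
2 points. Risk groups are Good (0), Intermediate (1), Poor (>= 2).

The published grouping table prints the Poor condition with an inverted
inequality ("<= 2"), which contradicts the score range and the other two
group definitions; the only consistent reading, and the one implemented,
is Poor ⇔ score >= 2. ECOG enters solely through the >= 2 dichotomy, so
ECOG 3 and 4 are valid inputs and score identically to ECOG 2.

## Survival estimation conventions

Times are months throughout; event indicators use 1 = event, 0 =
right-censored. Estimation is delegated to lifelines behind the module
surface; the package fixes the conventions:

- **Kaplan–Meier.** Ties at one time are processed events-before-
  censorings. Greenwood's formula gives the variance of S(t).
- **Confidence bands.** Log-log (complementary log, "exponential
  Greenwood") transform by default — the common clinical-reporting
  choice — with a plain linear Greenwood band available via
  `ci_method="linear"`.
- **Median survival.** Smallest event time with S(t) <= 0.5; `NR` (not
  reached) when the curve never gets there. The CI is read off where the
  pointwise band crosses 0.5 (the Brookmeyer–Crowley construction on the
  chosen transform); a band that never crosses reports `NR` for that bound.
- **Median follow-up.** Reverse Kaplan–Meier: the event indicator is
  complemented so censoring becomes the event of interest, and the median
  of that curve is reported.
- **Log-rank.** Unweighted, over pooled event times, chi-square with
  (groups − 1) df. P-values below 1e-4 are displayed as "< 0.0001" in
  reports while the raw value is retained.
- **Cox PH.** Efron tie correction (the better default when the original
  software is unknown; with the tie rates seen here the Efron–Breslow
  difference is well below reporting precision). Newton ascent from zero
  coefficients. Non-convergence and coefficient divergence beyond |β| > 20
  (a monotone-likelihood symptom) are flagged in the fit object, never
  silent.

## Time-dependent predictive values

The predictive-value estimand is defined within-group: for a marker
oriented toward the event, PPV(t) = P(event <= t | marker positive) is
estimated as 1 − S(t) from the Kaplan–Meier curve of the marker-positive
subgroup; for a marker oriented toward survival, NPV(t) = S(t) of the
marker group. This definition handles censoring correctly and reduces to
the naive within-group event proportion when no one is censored before t.
Confidence intervals come from the log-log band, complemented for PPV.
An estimate at a horizon where nobody is still at risk is reported as
not-estimable with a reason, not as a number.

Two markers on the same cohort (possibly overlapping groups — an iSEND
group and a PD-L1 stratum can share patients) are compared by a **paired
nonparametric bootstrap**: resample patients with replacement B times
(default 2,000), recompute both predictive values per replicate, and test
the observed difference against the bootstrap standard error with a
two-sided normal (Wald) test. Replicates in which either marker group is
empty or not at risk at the horizon are redrawn, capped at 10·B attempts.
Pairing makes the test valid under group overlap; a z-test treating the
two groups' Greenwood variances as independent is available
(`method="independent_z"`) for sensitivity analysis. The comparison
records B and the seed, and is bit-reproducible given both. Simulation
calibration (in the test suite): type-I error 0.057 at nominal 0.05 over
1,000 null repetitions with B = 300, and power 1.0 for an exponential
median contrast of 4.5 vs. 14 months at group sizes 120 and 47.

Default comparison horizons are {6, 12, 18, 24} months; any positive
increasing set is accepted via `AnalysisConfig.horizons` (published
analyses of this design have used both {3, 6, 9, 12} and {6, 12, 18, 24}).

## Cohort-comparison table statistics

Categorical variables are tested with **uncorrected** Pearson chi-square
(expected counts from the product of margins); "Unknown" levels are shown
in the table but excluded from the test. Both conventions were verified by
recomputation to be the ones that reproduce the published p-value column
from the printed counts — including Yates correction, or pooling Unknown
as a level, gives visibly different values (e.g. ~0.34 instead of 0.45 for
smoking history). Continuous variables use the Wilcoxon rank-sum test:
exact null distribution for small tie-free samples, otherwise the
tie-corrected normal approximation with continuity correction (scipy's
`method="auto"` policy). No multiplicity adjustment is applied anywhere,
matching standard practice for descriptive cohort tables.

## Synthetic-cohort generator

The generator emulates the statistical structure of a post-platinum
PD-1/L1 monotherapy cohort:

- **Covariates** are sampled independently from configurable marginals
  (defaults: 56% male, 18.7% ECOG >= 2, 26.9% squamous, 17.3% never-smokers
  among known, 10.5% EGFR/ALK-altered, 61.5% PD-L1 unavailable).
- **Haematology.** NLR1 is log-normal with median 4.5 and log-scale sigma
  0.55; dNLR is normal with median 0.1 and SD 2.5. A mean-reversion
  correlation of **ρ = −0.29** between the log-NLR1 driver and dNLR was
  calibrated once by Monte Carlo (2×10⁶ draws) so the composite prevalence
  P(NLR1 >= 5, dNLR >= 0) hits the 17.3% target; with independence this
  joint probability cannot fall below ~0.22 while keeping the dNLR median
  at 0.1, and negative correlation is also the physiologically expected
  regression-to-the-mean pattern. NLR2 = NLR1 + dNLR is clipped below at
  0.05; clipping affects only the far-left dNLR tail, leaving the median
  and the composite prevalence untouched.
- **Risk group.** Computed from the sampled covariates through the real
  scoring module — never assigned as a latent label — so the generator
  exercises the exact dependency path the pipeline estimates.
- **Event times.** Exponential by default (medians are the only
  distributional information available for this design), with group OS
  medians 23 / 13.4 / 4.5 months and PFS medians 6.5 / 4.0 / 1.9. PFS is
  min(progression, death) with the progression hazard solved so the PFS
  median is exact (λ_prog = ln2/m_PFS − ln2/m_OS); pfs_time <= os_time
  holds by construction. A Weibull family (`weibull_shape`) is available
  to stress non-proportional hazards.
- **Censoring.** Staggered accrual: entry uniform over 16 months with an
  administrative cutoff at 26 months, giving potential follow-up
  ~U(10, 26) and a reverse-KM median follow-up of ≈ 18 months.
- **Chemotherapy control.** Identical covariate model but a single PFS
  median (9.8 months) and OS median for every risk group — the score
  carries no information about chemotherapy outcome by construction. The
  chemo OS median is not constrained by the published design; 12 months
  (typical for second-line chemotherapy in this population) is the
  default.
- **PD-L1.** Independent of the risk group by default (no joint
  distribution is published); among available patients the category split
  defaults to 0.28 / 0.44 / 0.28 for 0% / 1–49% / >= 50%, anchored at the
  published 47/169 share for the 0% stratum. An association knob shifts
  Poor patients toward 0% and Good patients toward >= 50% for sensitivity
  experiments.

Two deterministic fixtures complement the sampler: a 439-patient cohort
matching the published categorical count table cell-for-cell (columns
filled independently, so only the margins — what the chi-square tests
see — are meaningful), and a 727-record pre-exclusion cohort realising the
36 / 44 / 31 / 177 exclusion-cascade counts.

**What passing these simulations shows — and does not.** Recovery of
generator parameters demonstrates that the estimators are implemented
correctly under the generator's assumptions (exponential hazards,
independent censoring, covariate-driven groups). Real cohorts add
structure the generator omits: non-proportional hazards, informative
censoring, site heterogeneity, correlated covariates (smoking × sex ×
histology), and a PD-L1–outcome association. Published patient-level
quantities (per-cohort hazard ratios, printed PPVs and their p-values, the
145/175/119 group split) therefore cannot be, and are not, reproduced
numerically; the suites check estimator correctness and directional
structure instead.

## Problem sizes and numerical choices

Simulation experiments use n = 5,000 for median/HR recovery (±10% / ±0.15
tolerances, comfortably above sampling noise at that size), n = 10,000 for
marginal convergence (binomial tolerance ±2 points), 100 repetitions for
the chemotherapy null rate, and 1,000 repetitions with B = 300 for the
bootstrap type-I calibration. Median-recovery experiments extend the
administrative cutoff to 60 months so the Good-group median (23 months)
lies safely inside the observable window; under the study-like 18-month
follow-up that median is frequently not reached — the same phenomenon the
original design reports as "NR" — which is a property of the censoring,
not of the estimator. Cox iteration starts at zero with lifelines'
step-halving Newton scheme; the toy-data cross-check bounds the
coefficient error at 1e-4 against a brute-force partial-likelihood
maximiser.

## Known limitations

- The predictive-value comparison p-value is a bootstrap-Wald construct;
  the published analysis does not state its method, so printed p-values
  are not comparable beyond direction and rough magnitude.
- PFS is treated as a single composite endpoint (no competing-risks
  decomposition), matching the design being emulated.
- The generator's dispersion parameters for NLR1/dNLR are calibration
  choices constrained only by medians, ranges and the composite
  prevalence; real haematology is heavier-tailed.
- No proportional-hazards diagnostics, stratified Cox, time-varying
  covariates or time-dependent C-index are provided.
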