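# Methods

## Estimand and model

The target is the marginal dose–response between a continuous exposure X
and the mortality rate in a stratum-aggregated person-year cohort: the
relative risk RR_i of death had everyone's exposure been set into
person-year decile i, versus the lowest decile. Binning replaces the
continuous-treatment IPW estimator (which needs a correct conditional
density for X and is fragile under heteroscedasticity and long tails) with
a K-level categorical one.

Two stages:

1. **Design.** Exposure is cut at person-year-weighted quantiles
   1/K,…,(K−1)/K. A boosted-tree classifier estimates
   p(i | C) = P(bin = i | confounders), trained on strata weighted by their
   person-years n_ij. The stabilized weight sw_ij = (1/K)/p̂(observed bin)
   reweights the cohort into a pseudo-population in which bin assignment is
   independent of measured confounders; the 1/K numerator (exact by the
   equal-mass construction) keeps weights centred near 1.
2. **Analysis.** Quasi-Poisson regression of stratum deaths on the factored
   bin with offset log(n_ij) and prior (variance) weights sw. For the
   saturated factor model this weighted MLE equals the pseudo-population
   rate ratio Σ sw·d / Σ sw·n per bin, so the point estimates have a
   closed-form interpretation that the tests exploit as an oracle. The
   dispersion φ = Pearson χ²/df (floored at 1) scales the Wald CIs; an
   option (`weight_mode="sw_times_py"`) instead applies sw·n_ij as weights,
   which leaves the saturated point estimates unchanged and mainly rescales
   the dispersion.

Assumptions inherited from IPW: no unmeasured confounding, correct
propensity specification, and positivity — every stratum must have
non-negligible probability of every bin. Positivity is the binding
constraint for a 10-level treatment; see "Simulation design" below.

## Propensity estimation choices

"Probability of the observed category given confounders" is implemented as
one multinomial (softmax) LightGBM classifier by default; a one-vs-rest
variant (K binary logistic boosters, each class probability its own expit,
renormalized) is available since either formulation matches that
description. The classifier is **cross-fitted** (default 5 folds, seeded
permutation): each stratum's p̂ comes from boosters that never saw it.
In-sample boosted propensities are overconfident at realistic data sizes —
the observed-class probability is biased upward, deflating the weights
(person-year-weighted mean sw ≈ 0.6–0.8 instead of 1) and leaving
covariate imbalance in place. Cross-fitting restores honest calibration;
out-of-sample prediction for *new* data averages the fold models.

Default hyperparameters: 130 trees, depth 3 (8 leaves), learning rate 0.05,
80% bagging, minimum 60 rows per leaf, 63 histogram bins, n_jobs = 1 and
deterministic mode. The tree count is the calibration/balance compromise:
more boosting keeps removing measured imbalance but inflates
E[1/p̂] (Jensen: estimation noise in p̂ enters the weight mean), pushing the
mean stabilized weight above 1. At the defaults the reference simulation
gives mean sw ≈ 1.01 with post-weighting max |SMD| ≈ 0.08. All knobs are
in `GBMConfig`.

Weight hygiene: probabilities are floored at 1e-6 (warned) to preclude
infinite weights; no truncation by default — binning itself bounds the
weights in well-behaved designs — with optional symmetric percentile
truncation (flagged and logged) for heavy-tailed applications.

## Binning conventions

"Equal-sized groups" is read as equal **person-year mass** (the population
is person-years; the reference is the lowest 10% of the study population).
Equal stratum counts are available (`equal_mass=False`) as a sensitivity
option. The weighted quantile is the right-continuous inverse CDF over the
data: Q(p) = the smallest observed value whose cumulative person-year
fraction strictly exceeds p. Intervals are [lower, upper), last bin closed;
a value equal to a cut point is the first member of the upper bin. This
combination splits mass as evenly as the discrete data allow (e.g. four
equal-mass points at K = 2 split {1,2}|{3,4}) and is deterministic under
ties; duplicate cut points (K unachievable) raise an error rather than
silently merging bins. Bin means are person-year-weighted and must increase
strictly across bins.

Aggregation uses the full demographic key (sex, race, 5-year age group,
Medicaid, area, year); any column that varies within a key is an error
naming the key and column, since exposures and area-year covariates must be
constant within a stratum by construction.

## Synthetic cohort generator

`generate_cohort` emulates the features of an administrative mortality
cohort that matter to this estimator, with known ground truth:

- ~40,000 area-year strata (10,000 ZIP-like areas × 4 years) carrying
  200,000 person-years apportioned by a gamma size law (largest-remainder
  integerization conserves the total exactly).
- Six continuous area-year confounders: warm/cold-season temperatures,
  humidity, % poverty (gamma, long right tail), median income (lognormal),
  % ever-smokers.
- Three exposures — annual PM2.5 (target), warm-season O3, annual NO2 —
  each a linear loading on standardized confounders plus noise drawn
  through a Gaussian copula (cross-noise correlations 0.15–0.2) with
  per-exposure margins (normal / gamma / lognormal, so co-exposures are
  long-tailed). PM2.5 noise is heteroscedastic: scale × max(0.2,
  1 + 0.2·z_tempwarm).
- Deaths: stratum-level Poisson with mean
  n_ij · α0 · exp(true_log_rr[bin]) · m_j, where bin is the
  person-year-weighted decile of the realized target exposure and m_j an
  exp-normalized multiplier from the confounder log-rate terms and an age
  gradient (0.35 per 5-year group). The normalization keeps the *marginal*
  RR of bin i at exp(true_log_rr[i]) — confounder effects multiply out —
  so the generating RR vector is the recovery target for the marginal IPW
  estimand, while the crude per-bin ratios are biased by construction.
  α0 = 0.045 deaths/person-year (an elderly-cohort scale); rates are kept
  well below the documented α0 ≤ 0.2 bound, and Poisson draws exceeding a
  stratum's person-years (a handful per million) are clipped with a
  warning.
- One seeded random stream per named substream (confounders, exposures,
  demographics, allocation, deaths, fragments), so adding a confounder does
  not perturb the death draws. Identical configs are bit-identical.
- `rows_per_stratum > 1` splits each stratum into several person-year
  records (deaths distributed by multivariate hypergeometric), exercising
  the aggregation step; aggregation recovers the strata exactly.

Default true RRs rise log-linearly from 1.10 (bin 2) to 1.20 (bin 10).
The step up from the reference is deliberate: at ~900 deaths per bin the
Monte-Carlo standard error of a 50-replicate mean log-RR is ≈ 0.007, so a
near-zero bin-2 effect could not be distinguished from noise, whereas
log 1.10 ≈ 0.095 is testable against a 20%-of-truth bias budget.

### Positivity arithmetic (why confounding is moderate)

For a 10-level treatment the weighted population of bin i has effective
sample size n_bin / (0.1 · E[1/p_i]); E[1/p_i] diverges as soon as some
strata have near-zero probability of bin i. Under a Gaussian sketch
(X = m + c·Z with R² the propensity R-squared), R² ≈ 0.05 keeps the
smallest per-bin ESS factor near 0.85, while R² ≥ 0.2 collapses it below
0.4 — at which point even *true*-propensity weighting fails to balance or
recover the extreme bins at this cohort size (verified with analytic
oracle weights during design). The default exposure loadings therefore give
R² ≈ 0.05: strong enough that the crude estimator is visibly biased (max
pre-weighting |SMD| ≈ 0.6, top-bin crude bias ≈ 40–70% of the true log RR),
weak enough that the estimand is identifiable. Similarly, ~40,000 strata
keep the per-bin ESS near 2,000, below which the max-over-(confounder×bin)
|SMD| would exceed the 0.1 convention from Monte-Carlo noise alone.

What the generator does **not** emulate: spatial autocorrelation and
repeated area effects across years (area-years are independent), exposure
measurement error, informative censoring, person-level survival times, and
calendar trends. Passing recovery tests therefore show the estimator is
correct under its own assumptions at realistic signal/noise — not that
those assumptions hold in any particular real cohort.

## Diagnostics

Balance: person-year-weighted standardized mean difference of each
confounder (categoricals expanded to level indicators) in each bin versus
the pooled population, before (w = n_ij) and after (w = sw·n_ij) weighting,
with the pre-weighting pooled SD as the fixed denominator; |SMD| < 0.1 is
the conventional pass. Weight reports include distribution quantiles, the
person-year-weighted mean (≈ 1 for a calibrated model), and the Kish
effective sample size (Σw)²/Σw².

Monotonicity of a fitted curve is assessed by the Spearman rank correlation
of log RR with bin index, not strict bin-to-bin increase: with true
adjacent-bin steps of ≈ 0.011 log units and per-bin standard errors of
≈ 0.05 at this cohort size, a strictly monotone estimate is a coin-flip
event even for a perfect estimator, while a strong positive rank trend
(ρ > 0.5) is the meaningful qualitative recovery of the rising curve (and
is what the 10- vs 14-bin robustness comparison checks).

## Numerical choices

- Quantiles/ties: exact cumulative-mass scan on unique values; no
  interpolation (cut points are data values, keeping bins reproducible on
  serialized boundaries).
- GLM: statsmodels Poisson IRLS; non-convergence or a zero-death bin raises
  with a weight summary / a suggestion to reduce K. CIs use
  z = Φ⁻¹(0.975).
- Dispersion floored at 1: underdispersion is not allowed to shrink SEs.
- Model-based CIs ignore weight-estimation uncertainty; empirically they
  cover ≈ 0.90 in the reference study. The bootstrap-over-strata
  alternative was considered and left out of the default path for cost; the
  CI coverage check in the test suite documents the achieved behaviour.
- Seeds: every stochastic component (generator substreams, fold
  assignment, LightGBM bagging) derives from explicit integer seeds;
  replicate seeds are an affine hash of the base seed kept below 2³¹.

## Known limitations

- The marginal RR interpretation needs the co-exposures not to mediate the
  target's effect; the generator gives co-exposures no direct mortality
  effect, matching that reading of mutual adjustment.
- α0 for impact estimates is an explicit input; the helper that derives it
  from the reference decile (reference-bin deaths per person-year per
  year) is one plausible reading of "baseline annual mortality rate".
  Multi-pollutant totals are additive, ignoring interactions.
- For simulated tables without person identifiers, cohort summaries
  apportion category shares by person-years; with real enrollment counts
  use `CohortSummary.from_counts`.
- At 2×10⁵ person-years individual fitted curves wiggle (per-bin SE ≈
  0.05); single-cohort output should be read with its CIs, and the
  replicate study is the authoritative statement of estimator performance.
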