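# dosebin

Emulating causal dose–response curves between continuous environmental
exposures and mortality counts, via decile binning and stabilized inverse
probability weighting.

## The problem

Large administrative mortality cohorts (the motivating case: tens of
millions of elderly beneficiaries followed as an open cohort, with annual
PM2.5, warm-season O3 and annual NO2 assigned to each person-year by
residential area) support *associational* dose–response curves, but policy
questions — how many early deaths would a tighter air-quality standard
prevent? — need *causal* ones. Inverse probability weighting (IPW) builds
the counterfactual contrast, but for a continuous exposure the conventional
estimator must specify the exposure's conditional density, handle
heteroscedasticity, and survive the extreme weights that long-tailed
pollution distributions produce.

The decile-binning approach sidesteps all three: split the exposure into
K = 10 groups of equal person-year mass, treat the lowest decile as
reference, and estimate one marginal relative risk (RR) per group. For
stratum *j* (all person-years sharing sex, race, 5-year age group, Medicaid
eligibility, area and calendar year, with deaths and person-years *n_ij*
cumulated) observed in exposure group *i*, the stabilized weight is

```
sw_ij = P(X in i) / p_hat(i | C_j),      P(X in i) = 1/K = 0.1
```

where `p_hat` is a gradient-boosted classifier's probability of the
observed group given the confounders C (the concurrent co-exposures,
calendar year, demographics, and area-level covariates), trained with each
stratum weighted by *n_ij* and cross-fitted so every stratum is scored by a
model that never saw it. On the weighted pseudo-population, deaths are
regressed on the factored exposure group by quasi-Poisson with a
log(person-years) offset:

```
log E[deaths_j] = log(n_ij) + beta_bin(j),      RR_i = exp(beta_i)
```

with Wald 95% CIs scaled by the estimated dispersion. A fitted curve
translates into public-health impact through

```
deaths avoided = N * alpha0 * ((RR_high - 1)/RR_high - (RR_low - 1)/RR_low)
```

with N the annual person-years and alpha0 the baseline annual mortality
rate.

Because the motivating cohort is restricted-access, the package ships a
synthetic cohort generator (`dosebin.simulate`) with the same structure —
stratum-level person-year tables, three mutually correlated exposures
confounded by area-year covariates, heteroscedastic long-tailed noise, and
Poisson deaths whose log-rate is a known step function of the exposure
decile — so estimator correctness is testable by parameter recovery.

## Worked example

```python
import dosebin as db
from dosebin.config import GBMConfig, PipelineConfig

cfg = db.default_config(seed=42)          # 200,000 person-years, known truth
cohort = db.generate_cohort(cfg)
target, co_exposures, confounders = db.pipeline_inputs(cfg)
result = db.run_pipeline(cohort, target, co_exposures, confounders,
                         PipelineConfig(n_bins=10, gbm=GBMConfig(seed=42)))
print(result.curve.table[["bin", "mean_exposure", "rr", "ci_low", "ci_high"]])
```

On this seed the pipeline reports (see `analysis/04_dose_response_curves.py`
for the full driver):

```
max |SMD|: before 0.588 -> after 0.079 (threshold 0.1)
stabilized weights: py-weighted mean 1.0136
quasi-Poisson dispersion: 1.043
bin 10: RR ipw 1.293 [1.182, 1.415]   crude 1.358   true 1.200
mean |log RR error| vs truth: ipw 0.0365, crude 0.0752
monotone trend (Spearman rho of log RR vs bin): 0.842 (p=0.0022)
```

Weighting halves the error of the confounded crude curve, the confounders
are balanced below the conventional |SMD| < 0.1 threshold, and the rising
dose–response is recovered. The `analysis/` scripts (01–06) run the full
narrative — simulate, aggregate/bin, weight/balance, fit, replicate-study,
impact — writing tables under `results/`. A `dosebin` CLI
(`simulate` / `run` / `impact`) wraps the same pipeline for shell use.

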