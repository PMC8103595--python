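"""Synthetic open-cohort generator with known confounding and dose-response.

Emulates the structure of a person-year mortality follow-up table: strata of
demographically identical beneficiaries within an area-year, area-year-level
continuous confounders, three mutually correlated continuous exposures with
heteroscedastic (optionally long-tailed) noise, and Poisson death counts
whose log-rate is a known step function of the target exposure's
person-year-weighted quantile bin.  Because the generating relative risks
are known, estimator correctness is testable by parameter recovery.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfounderSpec, ExposureSpec, SimConfig
from .doseresponse import DoseResponseCurve
from .errors import ConfigurationError
from .prep import BinDefinition, weighted_quantile

SEX_LEVELS = ["female", "male"]
RACE_LEVELS = ["white", "black", "other"]
AGE_LEVELS = ["65-69", "70-74", "75-79", "80-84", "85+"]
MEDICAID_LEVELS = [0, 1]

# fixed substream tags so e.g. adding a confounder never perturbs death draws
_STREAMS = {
    "confounders": 101,
    "exposures": 211,
    "demographics": 307,
    "allocation": 401,
    "deaths": 503,
    "fragments": 601,
}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


def _draw_confounder(spec: ConfounderSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    p = spec.params
    if spec.family == "normal":
        return rng.normal(p.get("mean", 0.0), p.get("sd", 1.0), size=n)
    if spec.family == "lognormal":
        return rng.lognormal(p.get("mu", 0.0), p.get("sigma", 1.0), size=n)
    if spec.family == "gamma":
        return rng.gamma(p.get("shape", 1.0), p.get("scale", 1.0), size=n)
    if spec.family == "uniform":
        return rng.uniform(p.get("low", 0.0), p.get("high", 1.0), size=n)
    raise ConfigurationError(f"unknown confounder family {spec.family!r}")


def _standardized_noise(z: np.ndarray, family: str) -> np.ndarray:
    """Transform standard-normal draws to a zero-mean unit-variance margin.

    The Gaussian-copula construction preserves the cross-exposure rank
    correlation while giving each exposure its own (possibly long-tailed)
    noise law.
    """
    if family == "normal":
        return z
    if family == "lognormal":
        s = 0.6  # fixed shape: right-skewed with a long upper tail
        m1 = np.exp(s * s / 2.0)
        sd = np.sqrt((np.exp(s * s) - 1.0) * np.exp(s * s))
        return (np.exp(s * z) - m1) / sd
    if family == "gamma":
        shape = 2.0
        g = stats.gamma.ppf(stats.norm.cdf(z), a=shape)
        return (g - shape) / np.sqrt(shape)
    raise ConfigurationError(f"unknown noise family {family!r}")


def _apportion(weights: np.ndarray, total: int, rng: np.random.Generator) -> np.ndarray:
    """Integer allocation of ``total`` person-years by largest remainder."""
    share = weights / weights.sum() * total
    base = np.floor(share).astype(int)
    short = total - base.sum()
    if short > 0:
        rem = share - base
        # deterministic tie-break: remainder, then random jitter from the stream
        order = np.lexsort((rng.random(len(rem)), -rem))
        base[order[:short]] += 1
    return base


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate a person-year follow-up table under a known mortality law.

    Deaths for stratum j are Poisson with mean
    ``n_j * baseline_rate * exp(true_log_rr[bin_j]) * m_j`` where ``bin_j``
    is the person-year-weighted K-quantile bin of the target exposure over
    the realized cohort, and ``m_j`` is the exp-normalized confounder/age
    multiplier (see :class:`~dosebin.config.SimConfig`).  The total of the
    ``person_years`` column equals ``config.n_person_years`` exactly, and
    the output is bit-identical for identical configs.
    """
    config.validate()
    n_ay = config.n_areas * config.n_years
    area = np.repeat(np.arange(1, config.n_areas + 1), config.n_years)
    year = np.tile(2000 + np.arange(config.n_years), config.n_areas)

    # --- area-year confounders -------------------------------------------
    rng_c = _rng(config, "confounders")
    conf = {c.name: _draw_confounder(c, rng_c, n_ay) for c in config.confounders}
    conf_z = {}
    for name, v in conf.items():
        sd = v.std()
        conf_z[name] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    # --- exposures: linear confounder loadings + correlated noise --------
    rng_x = _rng(config, "exposures")
    R = config.correlation_matrix()
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(R)))
    z = rng_x.standard_normal((n_ay, len(config.exposures))) @ L.T
    exposures = {}
    for k, spec in enumerate(config.exposures):
        noise = _standardized_noise(z[:, k], spec.noise_family)
        scale = np.full(n_ay, spec.noise_scale)
        if spec.hetero_confounder is not None:
            mult = 1.0 + spec.hetero_slope * conf_z[spec.hetero_confounder]
            scale = scale * np.maximum(spec.hetero_floor, mult)
        x = np.full(n_ay, spec.intercept, dtype=float)
        for cname, coef in spec.coefficients.items():
            x += coef * conf_z[cname]
        exposures[spec.name] = x + scale * noise

    # --- demographic cells within each area-year -------------------------
    rng_d = _rng(config, "demographics")
    combos = [
        (s, r, a, m)
        for s in SEX_LEVELS
        for r in RACE_LEVELS
        for a in AGE_LEVELS
        for m in MEDICAID_LEVELS
    ]
    n_cells = min(config.cells_per_area_year, len(combos))
    picks = np.argsort(rng_d.random((n_ay, len(combos))), axis=1)[:, :n_cells]
    ay_idx = np.repeat(np.arange(n_ay), n_cells)
    combo_idx = picks.ravel()
    sex = np.array([combos[i][0] for i in combo_idx])
    race = np.array([combos[i][1] for i in combo_idx])
    age_group = np.array([combos[i][2] for i in combo_idx])
    medicaid = np.array([combos[i][3] for i in combo_idx])
    age_idx = np.searchsorted(np.array(AGE_LEVELS), age_group)  # AGE_LEVELS is sorted

    # --- person-year allocation ------------------------------------------
    rng_a = _rng(config, "allocation")
    sizes = _apportion(rng_a.gamma(2.0, 1.0, size=len(ay_idx)), config.n_person_years, rng_a)
    keep = sizes > 0
    ay_idx, sizes = ay_idx[keep], sizes[keep]
    sex, race, age_group, medicaid = sex[keep], race[keep], age_group[keep], medicaid[keep]
    age_idx = age_idx[keep]

    # --- mortality law ----------------------------------------------------
    target = exposures[config.target][ay_idx]
    py = sizes.astype(float)
    cuts = weighted_quantile(target, py, np.arange(1, config.n_bins) / config.n_bins)
    if len(np.unique(cuts)) != config.n_bins - 1:
        raise ConfigurationError(
            "degenerate exposure distribution: cannot form the requested bins"
        )
    bins = BinDefinition(config.target, config.n_bins, cuts).assign(target)

    log_m = config.age_gradient * (age_idx - 2.0)
    for cname, gamma in config.mortality_coefficients.items():
        log_m = log_m + gamma * conf_z[cname][ay_idx]
    m = np.exp(log_m)
    m = m / np.average(m, weights=py)  # reference-bin marginal rate stays baseline_rate
    rate = config.baseline_rate * np.exp(np.asarray(config.true_log_rr)[bins - 1]) * m
    if config.baseline_rate > 0.2:
        warnings.warn(
            "baseline_rate > 0.2: Poisson death counts may exceed person-years "
            "and will be clipped",
            stacklevel=2,
        )
    rng_y = _rng(config, "deaths")
    deaths = rng_y.poisson(py * rate)
    over = deaths > sizes
    if over.any():
        warnings.warn(
            f"clipped {int(over.sum())} stratum death counts to person-years",
            stacklevel=2,
        )
        deaths = np.minimum(deaths, sizes)

    table = pd.DataFrame(
        {
            "sex": sex,
            "race": race,
            "age_group": age_group,
            "medicaid": medicaid,
            "area_id": area[ay_idx],
            "year": year[ay_idx],
        }
    )
    for c in config.confounders:
        table[c.name] = conf[c.name][ay_idx]
    for e in config.exposures:
        table[e.name] = exposures[e.name][ay_idx]
    table["deaths"] = deaths
    table["person_years"] = sizes

    if config.rows_per_stratum > 1:
        table = _fragment(table, config)
    return table


def _fragment(table: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Split each stratum row into several person-year records.

    Person-years are split near-equally; deaths are distributed by
    multivariate hypergeometric draws so every fragment satisfies
    deaths <= person_years.  Aggregating the result recovers the original
    strata exactly.
    """
    rng = _rng(config, "fragments")
    r = config.rows_per_stratum
    rows = []
    py = table["person_years"].to_numpy()
    deaths = table["deaths"].to_numpy()
    for i in range(len(table)):
        parts = np.full(r, py[i] // r, dtype=int)
        parts[: py[i] % r] += 1
        parts = parts[parts > 0]
        d_parts = rng.multivariate_hypergeometric(parts, int(deaths[i]))
        rows.append((parts, d_parts))
    idx = np.repeat(np.arange(len(table)), [len(p) for p, _ in rows])
    out = table.iloc[idx].reset_index(drop=True)
    out["person_years"] = np.concatenate([p for p, _ in rows])
    out["deaths"] = np.concatenate([d for _, d in rows])
    return out


def true_dose_response(config: SimConfig) -> DoseResponseCurve:
    """Ground-truth curve implied by the config: RR_i = exp(true_log_rr[i]).

    Intervals are degenerate (zero width); bin mean exposures are left NaN
    since they depend on the realized cohort.
    """
    config.validate()
    rr = np.exp(np.asarray(config.true_log_rr, dtype=float))
    k = config.n_bins
    table = pd.DataFrame(
        {
            "bin": np.arange(1, k + 1),
            "mean_exposure": np.full(k, np.nan),
            "rr": rr,
            "ci_low": rr,
            "ci_high": rr,
            "log_rr": np.log(rr),
            "se": np.zeros(k),
            "is_reference": np.arange(1, k + 1) == 1,
        }
    )
    return DoseResponseCurve(exposure=config.target, n_bins=k, table=table, dispersion=float("nan"))


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The package's reference simulation: a Medicare-like tri-pollutant cohort.

    40,000 area-years (10,000 ZIP-like areas over 4 calendar years), one
    demographic stratum each, carrying 200,000 person-years in total; six
    area-year confounders (poverty gamma-tailed, income lognormal); annual
    PM2.5 as the target exposure with warm-season O3 and annual NO2 as
    correlated co-exposures; heteroscedastic PM2.5 noise scaled by
    warm-season temperature; baseline mortality 0.045 per person-year with
    an age gradient and confounder effects that bias the crude estimator
    upward; true RRs rising log-linearly from 1.10 (bin 2) to 1.20 (bin 10).

    The confounder-exposure loadings are deliberately moderate (propensity
    R^2 around 0.05): every stratum retains non-negligible probability of
    every decile bin, the positivity condition a ten-level inverse
    probability weighting estimand needs.  Stronger confounding makes the
    marginal effect of the extreme deciles unidentifiable at this cohort
    size for *any* weighting estimator, not just this one.
    """
    log_rr = [0.0] + [float(v) for v in np.linspace(np.log(1.10), np.log(1.20), 9)]
    cfg = SimConfig(
        n_person_years=200_000,
        n_areas=10_000,
        n_years=4,
        cells_per_area_year=1,
        confounders=[
            ConfounderSpec("temp_warm", "normal", {"mean": 22.0, "sd": 3.0}),
            ConfounderSpec("temp_cold", "normal", {"mean": 5.0, "sd": 4.0}),
            ConfounderSpec("humidity", "normal", {"mean": 70.0, "sd": 8.0}),
            ConfounderSpec("pct_poverty", "gamma", {"shape": 4.0, "scale": 3.0}),
            ConfounderSpec("median_income", "lognormal", {"mu": 4.0, "sigma": 0.3}),
            ConfounderSpec("pct_smokers", "normal", {"mean": 20.0, "sd": 4.0}),
        ],
        exposures=[
            ExposureSpec(
                "pm25",
                intercept=9.85,
                coefficients={
                    "pct_smokers": 0.45,
                    "temp_warm": 0.3,
                    "pct_poverty": 0.2,
                },
                noise_family="normal",
                noise_scale=2.2,
                hetero_confounder="temp_warm",
                hetero_slope=0.2,
            ),
            ExposureSpec(
                "o3",
                intercept=39.34,
                coefficients={"temp_warm": 0.6, "humidity": -0.4},
                noise_family="gamma",
                noise_scale=2.5,
            ),
            ExposureSpec(
                "no2",
                intercept=17.30,
                coefficients={"pct_poverty": 0.35, "median_income": 0.3, "temp_cold": -0.25},
                noise_family="lognormal",
                noise_scale=4.0,
            ),
        ],
        cross_exposure_correlation=[[1.0, 0.15, 0.2], [0.15, 1.0, 0.1], [0.2, 0.1, 1.0]],
        target_exposure="pm25",
        true_log_rr=tuple(log_rr),
        baseline_rate=0.045,
        mortality_coefficients={
            "pct_smokers": 0.08,
            "pct_poverty": 0.05,
            "temp_warm": 0.04,
        },
        age_gradient=0.35,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


CANONICAL_COLUMNS_NOTE = (
    "Canonical CSV column order: sex, race, age_group, medicaid, area_id, "
    "year, <confounders...>, <exposures...>, deaths, person_years."
)


def write_cohort_csv(table: pd.DataFrame, path: str) -> None:
    """Write a cohort in the canonical column order (see CANONICAL_COLUMNS_NOTE)."""
    table.to_csv(path, index=False)


def read_cohort_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
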