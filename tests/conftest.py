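import numpy as np
import pandas as pd
import pytest

import dosebin as db
from dosebin.config import GBMConfig


def small_config(seed: int = 0, **overrides) -> db.SimConfig:
    """Scaled-down reference cohort for fast unit tests (~4,000 strata)."""
    defaults = dict(n_person_years=20_000, n_areas=2_000, n_years=2)
    defaults.update(overrides)
    return db.default_config(seed=seed, **defaults)


def fast_gbm(seed: int = 0, **overrides) -> GBMConfig:
    defaults = dict(n_estimators=40, n_folds=2, seed=seed)
    defaults.update(overrides)
    return GBMConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return db.generate_cohort(small_config(seed=11))


@pytest.fixture(scope="session")
def small_strata_binned(small_cohort):
    strata = db.aggregate_person_years(small_cohort)
    return db.assign_exposure_bins(strata, "pm25", n_bins=10)


@pytest.fixture()
def toy_records() -> pd.DataFrame:
    """Six person-year rows over four unique stratum keys."""
    return pd.DataFrame(
        {
            "sex": ["female", "female", "male", "male", "female", "male"],
            "race": ["white"] * 6,
            "age_group": ["65-69"] * 6,
            "medicaid": [0, 0, 0, 0, 1, 0],
            "area_id": [1, 1, 1, 2, 1, 2],
            "year": [2000, 2000, 2000, 2000, 2000, 2000],
            "pm25": [8.0, 8.0, 8.0, 9.5, 8.0, 9.5],
            "deaths": [1, 2, 0, 3, 1, 2],
            "person_years": [3, 4, 5, 6, 2, 7],
        }
    )


def rate_fixture(deaths, person_years, bins, sw=None) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Minimal binned stratum table (and weight table) for outcome-model tests."""
    strata = pd.DataFrame(
        {
            "deaths": np.asarray(deaths, dtype=float),
            "person_years": np.asarray(person_years, dtype=float),
            "x_bin": np.asarray(bins, dtype=int),
        }
    )
    weights = None
    if sw is not None:
        weights = pd.DataFrame({"bin": strata["x_bin"], "p_hat": 0.1, "sw": sw, "truncated": False})
    return strata, weights
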