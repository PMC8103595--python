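"""Public-health impact arithmetic and cohort summary statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError


def deaths_avoided(
    n_person_years: float, alpha0: float, rr_high: float, rr_low: float
) -> float:
    """Expected annual early deaths avoided by moving exposure bins.

    N * alpha0 * ((RR_high - 1)/RR_high - (RR_low - 1)/RR_low), where N is
    the annual averaged number of person-years, alpha0 the baseline annual
    mortality rate (deaths per person-year in the reference bin), and
    RR_high / RR_low the relative risks of the higher and lower bins.  Zero
    when the RRs are equal; negative values (excess deaths from moving to a
    *higher*-risk bin) are permitted with a warning.
    """
    if n_person_years <= 0:
        raise ConfigurationError("n_person_years must be positive")
    if not (0.0 < alpha0 < 1.0):
        raise ConfigurationError("alpha0 must lie in (0, 1)")
    if rr_high <= 0 or rr_low <= 0:
        raise ConfigurationError("relative risks must be positive")
    value = n_person_years * alpha0 * ((rr_high - 1.0) / rr_high - (rr_low - 1.0) / rr_low)
    if value < 0:
        warnings.warn(
            "deaths_avoided is negative: moving to the 'low' bin increases risk "
            "(interpreted as excess deaths)",
            stacklevel=2,
        )
    return float(value)


def baseline_rate_from_reference(
    strata_binned: pd.DataFrame, bin_col: str, n_years: int = 1
) -> float:
    """One plausible alpha0: reference-bin deaths per person-year per year."""
    sel = strata_binned[bin_col] == 1
    py = float(strata_binned.loc[sel, "person_years"].sum())
    if py <= 0:
        raise ConfigurationError("reference bin has no person-years")
    return float(strata_binned.loc[sel, "deaths"].sum()) / py / max(n_years, 1)


def _pct(count: float, population: float) -> float:
    return round(100.0 * count / population, 1)


@dataclass
class CohortSummary:
    """Cohort demographic summary in the style of an enrollment table.

    Percentages are 100 * count / population rounded to one decimal;
    average follow-up is total person-years / population, one decimal.
    """

    population: int
    total_person_years: float
    deaths: int
    category_counts: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def average_follow_up(self) -> float:
        if self.population <= 0:
            raise ConfigurationError("population must be positive")
        return round(self.total_person_years / self.population, 1)

    @property
    def death_pct(self) -> float:
        return _pct(self.deaths, self.population)

    def category_pct(self, category: str, level: str) -> float:
        return _pct(self.category_counts[category][level], self.population)

    def to_dict(self) -> dict:
        d = {
            "population": int(self.population),
            "total_person_years": float(self.total_person_years),
            "average_follow_up": self.average_follow_up,
            "deaths": int(self.deaths),
            "death_pct": self.death_pct,
            "categories": {},
        }
        for cat, levels in self.category_counts.items():
            d["categories"][cat] = {
                level: {"count": float(c), "pct": _pct(c, self.population)}
                for level, c in levels.items()
            }
        return d

    def to_markdown(self) -> str:
        lines = [
            "| Characteristic | No. | % |",
            "| --- | ---: | ---: |",
            f"| Population | {self.population:,} | 100 |",
            f"| Total person-years | {self.total_person_years:,.0f} | |",
            f"| Average years of follow-up | {self.average_follow_up} | |",
            f"| Death | {self.deaths:,} | {self.death_pct} |",
        ]
        for cat, levels in self.category_counts.items():
            for level, c in levels.items():
                lines.append(f"| {cat}: {level} | {c:,.0f} | {_pct(c, self.population)} |")
        return "\n".join(lines)

    @classmethod
    def from_counts(
        cls,
        population: int,
        total_person_years: float,
        deaths: int,
        category_counts: dict[str, dict[str, float]] | None = None,
    ) -> "CohortSummary":
        """Build a summary from printed counts (worked-example arithmetic)."""
        if population <= 0:
            raise ConfigurationError("population must be positive")
        return cls(
            population=population,
            total_person_years=total_person_years,
            deaths=deaths,
            category_counts=category_counts or {},
        )


def summarize_cohort(
    records: pd.DataFrame, population: int, categories: list[str] | None = None
) -> CohortSummary:
    """Summarize a person-year table given the person count.

    Simulated tables carry no person identifiers, so ``population`` comes
    from the design (e.g. the simulation config); category "counts" are
    person-year masses apportioned to the population (person-year shares),
    which coincide with person counts when follow-up does not differ by
    group.
    """
    if population <= 0:
        raise ConfigurationError("population must be positive")
    total_py = float(records["person_years"].sum())
    deaths = int(records["deaths"].sum())
    cat_counts: dict[str, dict[str, float]] = {}
    for cat in categories or []:
        shares = records.groupby(cat, observed=True)["person_years"].sum() / total_py
        cat_counts[cat] = {str(k): float(v * population) for k, v in shares.items()}
    return CohortSummary(
        population=population,
        total_person_years=total_py,
        deaths=deaths,
        category_counts=cat_counts,
    )


def curve_impact(
    curve_table: pd.DataFrame,
    n_person_years: float,
    alpha0: float,
    high_bin: int,
    low_bin: int,
) -> float:
    """deaths_avoided using the RRs of two bins from a fitted curve table."""
    rr = curve_table.set_index("bin")["rr"]
    return deaths_avoided(n_person_years, alpha0, float(rr.loc[high_bin]), float(rr.loc[low_bin]))


def multi_pollutant_impact(impacts: list[float]) -> float:
    """Additive total over pollutants; interactions are deliberately not modeled."""
    return float(np.sum(impacts))
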