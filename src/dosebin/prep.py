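"""Stratum aggregation and equal-mass exposure binning.

Person-year follow-up records are collapsed to estimation strata (unique
combinations of the demographic, area and year key fields, with deaths and
person-years cumulated), and each continuous exposure is split into K groups
of equal person-year mass at weighted quantiles.  Bin 1 (lowest exposure) is
the reference group throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AggregationError, BinningError

DEFAULT_KEY_FIELDS = ["sex", "race", "age_group", "medicaid", "area_id", "year"]


def weighted_quantile(
    values: np.ndarray, weights: np.ndarray, probs: np.ndarray | list[float]
) -> np.ndarray:
    """Weighted quantiles as the right-continuous inverse CDF over the data.

    Q(p) = smallest data value x whose cumulative weight fraction F(x)
    strictly exceeds p (Q(p) = max(x) for p >= 1).  With this convention a
    value equal to a returned cut point is the first member of the *upper*
    group, so assigning every x < Q(p) to the lower group splits the mass as
    evenly as the discrete data permit.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if values.shape != weights.shape:
        raise ValueError("values and weights must have the same shape")
    if not np.all(np.isfinite(values)):
        raise BinningError("non-finite exposure values")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    # collapse ties so F is evaluated per unique value
    uniq, start = np.unique(v, return_index=True)
    cum = np.cumsum(w)
    totals_at = cum[np.append(start[1:] - 1, len(v) - 1)]
    frac = totals_at / cum[-1]
    idx = np.searchsorted(frac, probs, side="right")
    idx = np.minimum(idx, len(uniq) - 1)
    return uniq[idx]


def aggregate_person_years(
    records: pd.DataFrame, key_fields: list[str] | None = None
) -> pd.DataFrame:
    """Collapse person-year records to one row per unique stratum key.

    Deaths and person-years are summed; every other column must be constant
    within a key (exposures and area-year covariates are, by construction)
    and is carried through unchanged.

    Raises
    ------
    AggregationError
        If a non-key, non-additive column varies within a stratum key; the
        message names the column and an offending key.
    """
    key_fields = list(key_fields or DEFAULT_KEY_FIELDS)
    missing = [k for k in key_fields if k not in records.columns]
    if missing:
        raise AggregationError(f"key fields missing from records: {missing}")
    for col in ("deaths", "person_years"):
        if col not in records.columns:
            raise AggregationError(f"records lack required column {col!r}")
    if records[key_fields].isna().any().any():
        raise AggregationError("missing values in key fields")

    carried = [
        c for c in records.columns if c not in key_fields and c not in ("deaths", "person_years")
    ]
    grouped = records.groupby(key_fields, sort=True, observed=True)
    for col in carried:
        nun = grouped[col].nunique(dropna=False)
        if (nun > 1).any():
            bad_key = nun[nun > 1].index[0]
            raise AggregationError(
                f"column {col!r} is not constant within stratum key {dict(zip(key_fields, np.atleast_1d(bad_key)))}"
            )
    agg = {c: "first" for c in carried}
    agg["deaths"] = "sum"
    agg["person_years"] = "sum"
    strata = grouped.agg(agg).reset_index()
    strata = strata[key_fields + carried + ["deaths", "person_years"]]
    strata.insert(0, "stratum_id", np.arange(len(strata)))
    return strata


@dataclass
class BinDefinition:
    """Equal-mass bin scheme for one exposure.

    ``boundaries`` holds the K-1 ascending cut points (exposure units); a
    stratum with exposure >= boundaries[i-1] and < boundaries[i] is in bin
    i+1 (1-based), i.e. intervals are [lower, upper) with the last bin
    right-closed.  ``bin_person_years`` and ``bin_mean_exposure`` are filled
    from the data the scheme was built on.  The marginal probability of any
    bin is 1/K by construction — the numerator of the stabilized weights.
    """

    exposure: str
    n_bins: int
    boundaries: np.ndarray
    bin_person_years: np.ndarray = field(default=None)  # type: ignore[assignment]
    bin_mean_exposure: np.ndarray = field(default=None)  # type: ignore[assignment]
    reference_bin: int = 1

    @property
    def marginal_probability(self) -> float:
        return 1.0 / self.n_bins

    def assign(self, x: np.ndarray) -> np.ndarray:
        """Map exposure values to 1-based bin labels (cut point -> upper bin)."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise BinningError(f"non-finite values in exposure {self.exposure!r}")
        return np.searchsorted(self.boundaries, x, side="right") + 1

    def max_mass_deviation(self) -> float:
        """Largest |bin mass - total/K| as a fraction of total person-years."""
        total = self.bin_person_years.sum()
        return float(np.abs(self.bin_person_years / total - 1.0 / self.n_bins).max())

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "n_bins": int(self.n_bins),
            "boundaries": [float(b) for b in self.boundaries],
            "bin_person_years": None
            if self.bin_person_years is None
            else [float(m) for m in self.bin_person_years],
            "bin_mean_exposure": None
            if self.bin_mean_exposure is None
            else [float(m) for m in self.bin_mean_exposure],
            "reference_bin": int(self.reference_bin),
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "BinDefinition":
        return cls(
            exposure=d["exposure"],
            n_bins=int(d["n_bins"]),
            boundaries=np.asarray(d["boundaries"], dtype=float),
            bin_person_years=None
            if d.get("bin_person_years") is None
            else np.asarray(d["bin_person_years"], dtype=float),
            bin_mean_exposure=None
            if d.get("bin_mean_exposure") is None
            else np.asarray(d["bin_mean_exposure"], dtype=float),
            reference_bin=int(d.get("reference_bin", 1)),
        )

    @classmethod
    def from_json(cls, path: str) -> "BinDefinition":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def assign_exposure_bins(
    strata: pd.DataFrame,
    exposure: str,
    n_bins: int = 10,
    equal_mass: bool = True,
    bin_col: str | None = None,
) -> tuple[pd.DataFrame, BinDefinition]:
    """Bin an exposure into ``n_bins`` equal-person-year groups.

    Cut points are person-year-weighted quantiles at levels 1/K .. (K-1)/K
    (set ``equal_mass=False`` for equal *stratum-count* groups, a documented
    sensitivity option).  Returns a copy of ``strata`` with a 1-based bin
    label column (default ``f"{exposure}_bin"``) and the completed
    :class:`BinDefinition`.
    """
    if n_bins < 2:
        raise BinningError("n_bins must be >= 2")
    if exposure not in strata.columns:
        raise BinningError(f"exposure column {exposure!r} not found")
    x = strata[exposure].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise BinningError(f"non-finite values in exposure {exposure!r}")
    if len(np.unique(x)) < n_bins:
        raise BinningError(
            f"exposure {exposure!r} has fewer distinct values than n_bins={n_bins}"
        )
    w = (
        strata["person_years"].to_numpy(dtype=float)
        if equal_mass
        else np.ones(len(strata))
    )
    probs = np.arange(1, n_bins) / n_bins
    cuts = weighted_quantile(x, w, probs)
    if len(np.unique(cuts)) != n_bins - 1:
        raise BinningError(
            f"degenerate bins for {exposure!r}: duplicated cut points at K={n_bins}; "
            "reduce the number of bins"
        )
    definition = BinDefinition(exposure=exposure, n_bins=n_bins, boundaries=cuts)
    labels = definition.assign(x)
    out = strata.copy()
    col = bin_col or f"{exposure}_bin"
    out[col] = labels
    definition = bin_summaries(out, exposure, bin_col=col, definition=definition)
    return out, definition


def bin_summaries(
    strata_binned: pd.DataFrame,
    exposure: str,
    bin_col: str | None = None,
    definition: BinDefinition | None = None,
) -> BinDefinition:
    """Fill per-bin person-year masses and weighted mean exposures.

    bin_mean_exposure[i] is the person-year-weighted mean exposure among
    strata in bin i+1; means must be strictly increasing across bins (they
    are, for any non-degenerate binning of an ordered exposure).
    """
    col = bin_col or f"{exposure}_bin"
    if col not in strata_binned.columns:
        raise BinningError(f"bin column {col!r} not found; assign bins first")
    labels = strata_binned[col].to_numpy()
    x = strata_binned[exposure].to_numpy(dtype=float)
    py = strata_binned["person_years"].to_numpy(dtype=float)
    n_bins = definition.n_bins if definition is not None else int(labels.max())
    masses = np.zeros(n_bins)
    means = np.zeros(n_bins)
    for b in range(1, n_bins + 1):
        sel = labels == b
        if not sel.any():
            raise BinningError(f"bin {b} of exposure {exposure!r} is empty")
        masses[b - 1] = py[sel].sum()
        means[b - 1] = np.average(x[sel], weights=py[sel])
    if definition is None:
        definition = BinDefinition(
            exposure=exposure,
            n_bins=n_bins,
            boundaries=np.array(
                [x[labels == b].min() for b in range(2, n_bins + 1)], dtype=float
            ),
        )
    if not np.all(np.diff(means) > 0):
        raise BinningError(f"bin mean exposures for {exposure!r} are not strictly increasing")
    definition.bin_person_years = masses
    definition.bin_mean_exposure = means
    return definition
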