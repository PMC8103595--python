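"""Gradient-boosted propensity scores, stabilized weights, balance checks.

The design stage of the pipeline: a boosted-tree classifier estimates each
stratum's probability of its observed exposure bin given the confounders
(including the concurrent co-exposures), training weighted by person-years.
The stabilized inverse-probability weight is the marginal bin probability
(1/K) over that conditional probability; in the reweighted pseudo-population
the exposure bin is independent of the measured confounders, which the
standardized-mean-difference diagnostics verify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier

from .config import GBMConfig
from .errors import ConfigurationError, EstimationError


def _lgbm(hyper: GBMConfig, objective: str, seed_offset: int = 0) -> LGBMClassifier:
    return LGBMClassifier(
        objective=objective,
        n_estimators=hyper.n_estimators,
        max_depth=hyper.max_depth,
        num_leaves=2**hyper.max_depth,
        learning_rate=hyper.learning_rate,
        subsample=hyper.subsample,
        subsample_freq=1 if hyper.subsample < 1.0 else 0,
        min_child_samples=hyper.min_child_samples,
        max_bin=hyper.max_bin,
        random_state=hyper.seed + seed_offset,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )


def _design(frame: pd.DataFrame, confounders: list[str]) -> pd.DataFrame:
    X = frame[confounders].copy()
    for col in X.columns:
        if X[col].dtype == object or isinstance(X[col].dtype, pd.CategoricalDtype):
            X[col] = X[col].astype("category")
    return X


@dataclass
class PropensityModel:
    """Fitted K-class propensity model for one binned exposure.

    With cross-fitting (``hyper.n_folds > 1``) the model holds one booster
    set per fold plus the out-of-fold probabilities for the training strata;
    :func:`stabilized_weights` uses those honest predictions for the data
    the model was fitted on, while :meth:`predict_proba` averages the fold
    models for any other data.
    """

    exposure: str
    bin_col: str
    confounders: list[str]
    n_bins: int
    hyper: GBMConfig
    fold_models: list[list[LGBMClassifier]] = field(default_factory=list, repr=False)
    categories: dict[str, list] = field(default_factory=dict, repr=False)
    oof_proba: np.ndarray | None = field(default=None, repr=False)
    train_bins: np.ndarray | None = field(default=None, repr=False)

    @property
    def marginal_probability(self) -> float:
        return 1.0 / self.n_bins

    def _proba_one(self, models: list[LGBMClassifier], X: pd.DataFrame) -> np.ndarray:
        if self.hyper.method == "multinomial":
            return models[0].predict_proba(X)
        cols = [b.predict_proba(X)[:, 1] for b in models]
        proba = np.column_stack(cols)
        return proba / proba.sum(axis=1, keepdims=True)

    def predict_proba(self, strata: pd.DataFrame) -> np.ndarray:
        """(n, K) predicted bin probabilities (fold average), columns bin 1..K."""
        X = _design(strata, self.confounders)
        for col, cats in self.categories.items():
            X[col] = pd.Categorical(X[col], categories=cats)
        proba = np.mean([self._proba_one(ms, X) for ms in self.fold_models], axis=0)
        return np.clip(proba, 1e-12, 1.0)

    def training_proba(self, strata_binned: pd.DataFrame) -> np.ndarray:
        """Out-of-fold probabilities if ``strata_binned`` is the training frame."""
        if self.oof_proba is not None and len(strata_binned) == len(self.oof_proba):
            bins = strata_binned[self.bin_col].to_numpy().astype(int)
            if np.array_equal(bins, self.train_bins):
                return self.oof_proba
        return self.predict_proba(strata_binned)


def fit_propensity(
    strata_binned: pd.DataFrame,
    exposure: str,
    confounders: list[str],
    hyper: GBMConfig | None = None,
    bin_col: str | None = None,
) -> PropensityModel:
    """Fit the boosted classifier for P(bin | confounders), weighted by n_ij.

    ``confounders`` must exclude the binned exposure itself; the concurrent
    co-exposures belong in it.  Every bin class must appear in the training
    data.  With ``hyper.n_folds > 1`` (the default) the strata are split
    into folds by a seeded permutation and each fold is predicted by
    boosters trained on the others.  Deterministic given the hyperparameter
    seed.
    """
    hyper = hyper or GBMConfig()
    hyper.validate()
    if exposure in confounders:
        raise ConfigurationError(
            f"confounder list must not contain the binned exposure {exposure!r}"
        )
    col = bin_col or f"{exposure}_bin"
    if col in confounders:
        raise ConfigurationError(f"confounder list must not contain the bin column {col!r}")
    missing = [c for c in confounders if c not in strata_binned.columns]
    if missing:
        raise ConfigurationError(f"confounders not found in strata: {missing}")
    y = strata_binned[col].to_numpy().astype(int)
    n_bins = int(y.max())
    present = set(np.unique(y))
    expected = set(range(1, n_bins + 1))
    if present != expected:
        raise EstimationError(
            f"bin classes {sorted(expected - present)} absent from training data"
        )
    w = strata_binned["person_years"].to_numpy(dtype=float)
    X = _design(strata_binned, confounders)
    categories = {
        c: list(X[c].cat.categories)
        for c in X.columns
        if isinstance(X[c].dtype, pd.CategoricalDtype)
    }

    def _fit_set(rows: np.ndarray) -> list[LGBMClassifier]:
        models = []
        if hyper.method == "multinomial":
            clf = _lgbm(hyper, "multiclass" if n_bins > 2 else "binary")
            clf.fit(X.iloc[rows], y[rows], sample_weight=w[rows])
            models.append(clf)
        else:  # one binary logistic booster per class, renormalized at predict time
            for k in range(1, n_bins + 1):
                clf = _lgbm(hyper, "binary", seed_offset=k)
                clf.fit(X.iloc[rows], (y[rows] == k).astype(int), sample_weight=w[rows])
                models.append(clf)
        return models

    model = PropensityModel(
        exposure=exposure,
        bin_col=col,
        confounders=list(confounders),
        n_bins=n_bins,
        hyper=hyper,
        categories=categories,
        train_bins=y.copy(),
    )
    n = len(strata_binned)
    if hyper.n_folds <= 1 or n < 2 * hyper.n_folds:
        model.fold_models = [_fit_set(np.arange(n))]
        model.oof_proba = None  # in-sample predictions are the only option
        return model
    rng = np.random.default_rng(hyper.seed)
    fold = rng.permutation(n) % hyper.n_folds
    oof = np.zeros((n, n_bins))
    for f in range(hyper.n_folds):
        tr = np.where(fold != f)[0]
        te = np.where(fold == f)[0]
        if len(set(y[tr])) < n_bins:
            raise EstimationError(
                f"fold {f} lost a bin class during cross-fitting; "
                "reduce n_folds or n_bins"
            )
        models = _fit_set(tr)
        model.fold_models.append(models)
        proba = model._proba_one(models, X.iloc[te])
        oof[te] = proba
    model.oof_proba = np.clip(oof, 1e-12, 1.0)
    return model


def stabilized_weights(
    model: PropensityModel,
    strata_binned: pd.DataFrame,
    probability_floor: float = 1e-6,
    truncate_percentiles: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Stabilized weights sw = (1/K) / p_hat(observed bin) per stratum.

    The numerator is the marginal probability of any bin (1/K by the
    equal-mass construction); it stabilizes the weight distribution around
    one.  Predicted probabilities below ``probability_floor`` are floored
    (with a warning) to avoid numerically infinite weights.  Optional
    symmetric percentile truncation clips extreme weights; no truncation is
    applied by default.
    """
    proba = model.training_proba(strata_binned)
    y = strata_binned[model.bin_col].to_numpy().astype(int)
    p_hat = proba[np.arange(len(y)), y - 1]
    floored = p_hat < probability_floor
    if floored.any():
        warnings.warn(
            f"floored {int(floored.sum())} propensity values at {probability_floor:g}",
            stacklevel=2,
        )
        p_hat = np.maximum(p_hat, probability_floor)
    sw = model.marginal_probability / p_hat
    truncated = np.zeros(len(sw), dtype=bool)
    if truncate_percentiles is not None:
        lo_p, hi_p = truncate_percentiles
        lo, hi = np.percentile(sw, [lo_p, hi_p])
        truncated = (sw < lo) | (sw > hi)
        if truncated.any():
            warnings.warn(
                f"truncated {int(truncated.sum())} weights to "
                f"[{lo:.4g}, {hi:.4g}] ({lo_p:g}/{hi_p:g} percentiles)",
                stacklevel=2,
            )
        sw = np.clip(sw, lo, hi)
    out = pd.DataFrame(
        {
            "bin": y,
            "p_hat": p_hat,
            "sw": sw,
            "truncated": truncated,
        }
    )
    if "stratum_id" in strata_binned.columns:
        out.insert(0, "stratum_id", strata_binned["stratum_id"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# balance diagnostics


def weighted_smd(x: np.ndarray, in_bin: np.ndarray, w: np.ndarray, sd: float) -> float:
    """Standardized mean difference of a bin versus the pooled population.

    ``sd`` is the pooled (pre-weighting) standard deviation, held fixed so
    before/after comparisons share a denominator.
    """
    if sd == 0:
        return 0.0
    mean_bin = np.average(x[in_bin], weights=w[in_bin])
    mean_all = np.average(x, weights=w)
    return float((mean_bin - mean_all) / sd)


def effective_sample_size(w: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    return float(w.sum() ** 2 / np.square(w).sum())


@dataclass
class BalanceReport:
    """Per-confounder, per-bin SMDs before/after weighting plus weight summaries."""

    table: pd.DataFrame
    weight_summary: dict[str, float]

    def max_abs_smd(self, when: str = "after") -> float:
        return float(self.table[f"smd_{when}"].abs().max())

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def _numeric_columns(strata: pd.DataFrame, confounders: list[str]) -> dict[str, np.ndarray]:
    """Expand categorical confounders into level indicators for SMD purposes."""
    cols: dict[str, np.ndarray] = {}
    for c in confounders:
        s = strata[c]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            cols[c] = s.to_numpy(dtype=float)
        elif pd.api.types.is_numeric_dtype(s):
            cols[c] = s.to_numpy(dtype=float)
        else:
            for level in sorted(s.astype(str).unique()):
                cols[f"{c}={level}"] = (s.astype(str) == level).to_numpy(dtype=float)
    return cols


def balance_diagnostics(
    strata_binned: pd.DataFrame,
    weights: pd.DataFrame,
    confounders: list[str],
    bin_col: str,
) -> BalanceReport:
    """Person-year-weighted SMDs of each bin vs the pooled population.

    "Before" uses w = n_ij; "after" uses w = sw * n_ij.  The denominator is
    the pre-weighting pooled SD (a constant column yields SMD 0, flagged).
    Weight summaries report the sw distribution, its person-year-weighted
    mean, and the Kish effective sample size of sw * n_ij.
    """
    if len(weights) != len(strata_binned):
        raise EstimationError("weight table is not aligned with the strata")
    sw = weights["sw"].to_numpy(dtype=float)
    py = strata_binned["person_years"].to_numpy(dtype=float)
    bins = strata_binned[bin_col].to_numpy().astype(int)
    w_before = py
    w_after = sw * py
    rows = []
    for name, x in _numeric_columns(strata_binned, confounders).items():
        mean_all = np.average(x, weights=w_before)
        sd = float(np.sqrt(np.average((x - mean_all) ** 2, weights=w_before)))
        for b in np.unique(bins):
            sel = bins == b
            rows.append(
                {
                    "confounder": name,
                    "bin": int(b),
                    "smd_before": weighted_smd(x, sel, w_before, sd),
                    "smd_after": weighted_smd(x, sel, w_after, sd),
                    "zero_variance": sd == 0,
                }
            )
    q = np.percentile(sw, [0, 1, 25, 50, 75, 99, 100])
    summary = {
        "sw_min": float(q[0]),
        "sw_p01": float(q[1]),
        "sw_p25": float(q[2]),
        "sw_median": float(q[3]),
        "sw_p75": float(q[4]),
        "sw_p99": float(q[5]),
        "sw_max": float(q[6]),
        "sw_py_weighted_mean": float(np.average(sw, weights=py)),
        "ess": effective_sample_size(w_after),
        "total_person_years": float(py.sum()),
    }
    return BalanceReport(table=pd.DataFrame(rows), weight_summary=summary)
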