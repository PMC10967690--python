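"""Soil fertility index (SFI): 0-1 indicator scoring, PCA-derived weights,
weighted summation and SFI-vs-enzyme regressions.

The index is the additive soil-quality form SFI = sum_i W_i * S_i where S_i
is a bounded [0, 1] score of raw indicator i and the non-negative weights
W_i (summing to one) come from a principal-component decomposition of the
score matrix: each indicator's weight is its communality over the retained
components divided by the total communality.

Scoring shapes follow soil-quality-index practice:

- ``linear_more`` / ``linear_less``: min-max ramp up (resp. down) between
  lower and upper thresholds L and U;
- ``optimum_plateau``: rises L -> O1, flat 1 on the optimum band [O1, O2],
  falls O2 -> U (used for pH, default band 4.5-5.5 for acid-loving tea);
- ``sigmoid_more`` / ``sigmoid_less``: S = 1/(1 + (x/x0)^(-+b)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import InvariantError, MeasurementTable

SCORING_KINDS = ("linear_more", "linear_less", "optimum_plateau",
                 "sigmoid_more", "sigmoid_less")


@dataclass(frozen=True)
class ScoringFunction:
    """A bounded [0, 1] transform of a raw indicator."""

    kind: str
    lower: float | None = None          # L
    upper: float | None = None          # U
    optimum: tuple[float, float] | None = None  # [O1, O2]
    midpoint: float | None = None       # x0
    steepness: float = 2.5              # b

    def __post_init__(self) -> None:
        if self.kind not in SCORING_KINDS:
            raise InvariantError(f"unknown scoring kind {self.kind!r}")
        if self.kind.startswith(("linear", "optimum")):
            if self.lower is not None and self.upper is not None \
                    and self.lower >= self.upper:
                raise InvariantError("scoring thresholds need L < U")
        if self.kind == "optimum_plateau" and self.optimum is not None:
            o1, o2 = self.optimum
            if o1 > o2:
                raise InvariantError("optimum band needs O1 <= O2")
        if self.steepness <= 0:
            raise InvariantError("sigmoid steepness b must be positive")

    def with_range(self, lower: float, upper: float) -> "ScoringFunction":
        """Fill unset thresholds from an observed data range."""
        lo = self.lower if self.lower is not None else lower
        up = self.upper if self.upper is not None else upper
        if lo >= up:
            raise InvariantError(f"degenerate range [{lo}, {up}]")
        mid = self.midpoint if self.midpoint is not None else (lo + up) / 2.0
        opt = self.optimum
        if self.kind == "optimum_plateau" and opt is None:
            third = (up - lo) / 3.0
            opt = (lo + third, up - third)
        return ScoringFunction(self.kind, lo, up, opt, mid, self.steepness)

    def __call__(self, values) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        if self.kind in ("linear_more", "linear_less", "optimum_plateau") \
                and (self.lower is None or self.upper is None):
            raise InvariantError("thresholds L, U unset; call with_range first")
        if self.kind == "linear_more":
            s = np.clip((x - self.lower) / (self.upper - self.lower), 0.0, 1.0)
        elif self.kind == "linear_less":
            s = 1.0 - np.clip((x - self.lower) / (self.upper - self.lower),
                              0.0, 1.0)
        elif self.kind == "optimum_plateau":
            o1, o2 = self.optimum
            s = np.ones_like(x)
            rising = x < o1
            falling = x > o2
            if o1 > self.lower:
                s = np.where(rising, (x - self.lower) / (o1 - self.lower), s)
            else:
                s = np.where(rising, 0.0, s)
            if self.upper > o2:
                s = np.where(falling, (self.upper - x) / (self.upper - o2), s)
            else:
                s = np.where(falling, 0.0, s)
            s = np.clip(s, 0.0, 1.0)
        else:
            x0 = self.midpoint
            if x0 is None or x0 <= 0:
                raise InvariantError("sigmoid midpoint x0 must be positive")
            with np.errstate(divide="ignore", over="ignore"):
                ratio = np.where(x > 0, x / x0, 0.0)
                sign = -1.0 if self.kind == "sigmoid_more" else 1.0
                s = np.where(ratio > 0,
                             1.0 / (1.0 + ratio ** (sign * self.steepness)),
                             1.0 if sign > 0 else 0.0)
        out = np.where(np.isnan(x), np.nan, s)
        return out


#: default assignment used when a variable has no configured scoring kind:
#: nutrients, carbon pools and enzyme activities are "more is better";
#: pH gets an optimum plateau on the tea-appropriate acidity band.
DEFAULT_SCORING: dict[str, ScoringFunction] = {
    "pH": ScoringFunction("optimum_plateau", optimum=(4.5, 5.5)),
}
FALLBACK_KIND = "linear_more"


@dataclass
class WeightVector:
    """PCA-derived indicator weights plus the derivation record."""

    weights: pd.Series
    eigenvalues: np.ndarray
    retained: np.ndarray              # indices of retained components
    loadings: pd.DataFrame            # indicators x components
    communalities: pd.Series
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if (w < -1e-12).any():
            raise InvariantError("negative weight")
        if abs(w.sum() - 1.0) > 1e-9:
            raise InvariantError("weights must sum to 1")


def derive_weights_pca(scores: pd.DataFrame, eigenvalue_min: float = 1.0,
                       method: str = "communality") -> WeightVector:
    """Derive indicator weights from a standardized PCA of an indicator matrix.

    Components with eigenvalue >= ``eigenvalue_min`` (Kaiser rule) are
    retained; at least one component is always kept. ``method``:

    - ``"communality"`` (default): weight_i proportional to indicator i's
      communality (sum of squared loadings) over retained components;
    - ``"variance_loading"``: weight_i proportional to
      sum_k varexpl_k * |loading_ik| over retained components.
    """
    scores = pd.DataFrame(scores).dropna()
    if scores.shape[1] < 1:
        raise InvariantError("no indicators")
    if scores.shape[0] < 3 and scores.shape[1] > 1:
        raise InvariantError("need at least 3 samples to derive weights")
    sds = scores.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise InvariantError(f"constant indicator column(s): {constant}")
    names = list(scores.columns)
    if len(names) == 1:
        return WeightVector(pd.Series([1.0], index=names),
                            np.array([1.0]), np.array([0]),
                            pd.DataFrame([[1.0]], index=names, columns=["PC1"]),
                            pd.Series([1.0], index=names), np.array([1.0]))
    corr = np.corrcoef(scores.to_numpy(dtype=float), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
    retained = np.where(eigval >= eigenvalue_min)[0]
    if retained.size == 0:
        retained = np.array([0])
    loadings = eigvec * np.sqrt(eigval)     # indicators x components
    varexpl = eigval / eigval.sum()
    if method == "communality":
        raw = (loadings[:, retained] ** 2).sum(axis=1)
    elif method == "variance_loading":
        raw = (np.abs(loadings[:, retained]) * varexpl[retained]).sum(axis=1)
    else:
        raise ValueError(f"unknown weighting method {method!r}")
    weights = raw / raw.sum()
    cols = [f"PC{k + 1}" for k in range(len(names))]
    return WeightVector(
        pd.Series(weights, index=names),
        eigval, retained,
        pd.DataFrame(loadings, index=names, columns=cols),
        pd.Series((loadings[:, retained] ** 2).sum(axis=1), index=names),
        varexpl)


@dataclass
class FertilityIndexResult:
    """Per-sample SFI with group summaries and percent change vs reference."""

    sfi: pd.Series                      # indexed by sample_id
    scores: pd.DataFrame                # samples x indicators, in [0, 1]
    weights: WeightVector
    summary: pd.DataFrame | None = None        # (treatment, period) mean/sd/n
    percent_change: pd.DataFrame | None = None  # vs reference treatment
    letters: dict | None = None


class SoilFertilityIndex(BaseEstimator, TransformerMixin):
    """PCA-weighted additive soil fertility index, sklearn-style.

    ``fit`` fixes the scoring thresholds (observed min-max per indicator by
    default) and derives the weights from a standardized PCA of the raw
    indicator matrix; ``transform`` maps raw measurements to the per-sample
    index in [0, 1].

    Parameters
    ----------
    scoring:
        Mapping variable -> ``ScoringFunction`` or kind name, overriding the
        defaults (more-is-better for every indicator, optimum-plateau pH).
    indicators:
        Variable subset to use; default all numeric variables.
    eigenvalue_min:
        Kaiser retention threshold for PCA components.
    weight_method:
        "communality" (default) or "variance_loading".
    """

    def __init__(self, scoring: Mapping[str, ScoringFunction | str] | None = None,
                 indicators: Sequence[str] | None = None,
                 eigenvalue_min: float = 1.0,
                 weight_method: str = "communality"):
        self.scoring = scoring
        self.indicators = indicators
        self.eigenvalue_min = eigenvalue_min
        self.weight_method = weight_method

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _as_matrix(X) -> pd.DataFrame:
        if isinstance(X, MeasurementTable):
            return X.matrix()
        X = pd.DataFrame(X)
        if not X.shape[1]:
            raise InvariantError("empty indicator matrix")
        return X

    def _resolve_scoring(self, name: str) -> ScoringFunction:
        table = dict(DEFAULT_SCORING)
        for key, val in (self.scoring or {}).items():
            table[key] = ScoringFunction(val) if isinstance(val, str) else val
        return table.get(name, ScoringFunction(FALLBACK_KIND))

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None) -> "SoilFertilityIndex":
        mat = self._as_matrix(X)
        cols = list(self.indicators) if self.indicators else list(mat.columns)
        mat = mat[cols]
        self.scoring_: dict[str, ScoringFunction] = {}
        for name in cols:
            vals = mat[name].dropna()
            if vals.empty:
                raise InvariantError(f"indicator {name!r} is all-missing")
            fn = self._resolve_scoring(name)
            lo, up = float(vals.min()), float(vals.max())
            if lo == up:
                raise InvariantError(f"constant indicator column: {name!r}")
            self.scoring_[name] = fn.with_range(lo, up)
        # weights come from a standardized PCA of the *untransformed*
        # indicators; scoring only bounds the indicator contributions.
        # (Plateau-scored variables can be constant on the score scale
        # while still carrying variance worth weighting.)
        self.weights_ = derive_weights_pca(
            mat, self.eigenvalue_min, self.weight_method)
        self.indicator_names_ = cols
        self.n_features_in_ = len(cols)
        return self

    def score_indicators(self, X) -> pd.DataFrame:
        check_is_fitted(self, "scoring_")
        mat = self._as_matrix(X)[self.indicator_names_]
        return self.score(mat)

    def score(self, mat: pd.DataFrame) -> pd.DataFrame:
        fns = getattr(self, "scoring_", None)
        if fns is None:
            raise InvariantError("call fit first")
        out = {}
        for name in mat.columns:
            out[name] = fns[name](mat[name].to_numpy(dtype=float))
        return pd.DataFrame(out, index=mat.index)

    def transform(self, X) -> pd.Series:
        check_is_fitted(self, "weights_")
        scores = self.score_indicators(X)
        return compute_sfi_values(scores, self.weights_)

    def fit_transform(self, X, y=None, **kwargs) -> pd.Series:
        return self.fit(X).transform(X)


def score_indicator(values, fn: ScoringFunction) -> np.ndarray:
    """Apply one scoring function to a raw indicator vector."""
    return fn(values)


def compute_sfi_values(scores: pd.DataFrame, weights: WeightVector) -> pd.Series:
    """Per-sample SFI = sum_i W_i * S_i."""
    names = list(weights.weights.index)
    if sorted(names) != sorted(scores.columns):
        raise InvariantError("weights and scores cover different indicators")
    s = scores[names].to_numpy(dtype=float)
    if np.nanmin(s) < -1e-12 or np.nanmax(s) > 1 + 1e-12:
        raise InvariantError("scores outside [0, 1]")
    sfi = s @ weights.weights.to_numpy()
    return pd.Series(sfi, index=scores.index, name="SFI")


def compute_sfi(table: MeasurementTable,
                estimator: SoilFertilityIndex | None = None,
                reference: str = "CK") -> FertilityIndexResult:
    """Fit the index on a measurement table and summarize it per group.

    Percent change is computed on group means, per period, against the
    reference treatment: 100*(mean_T - mean_ref)/mean_ref.
    """
    est = estimator or SoilFertilityIndex()
    sfi = est.fit_transform(table)
    scores = est.score_indicators(table)
    df = table.data[["sample_id", "treatment", "period"]].copy()
    df["SFI"] = sfi.to_numpy()
    grouped = df.groupby(["treatment", "period"])["SFI"]
    summary = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    means = summary["mean"].unstack("period")
    if reference not in means.index:
        raise InvariantError(f"reference treatment {reference!r} absent")
    ref = means.loc[reference]
    pct = 100.0 * (means - ref) / ref
    return FertilityIndexResult(sfi=sfi, scores=scores, weights=est.weights_,
                                summary=summary, percent_change=pct)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def regress_sfi_on(x, y) -> RegressionResult:
    """OLS of y on x with a two-sided t-test on the slope.

    Used for index-vs-enzyme-activity regressions; pairs with a missing
    value are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InvariantError("need at least 3 complete pairs")
    if np.ptp(x) == 0:
        raise InvariantError("zero variance in predictor")
    if np.ptp(y) == 0:
        # perfectly flat response: slope 0, no linear association
        warnings.warn("response has zero variance", stacklevel=2)
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, int(x.size))
    fit = stats.linregress(x, y)
    return RegressionResult(float(fit.slope), float(fit.intercept),
                            float(fit.rvalue) ** 2, float(fit.pvalue),
                            int(x.size))
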