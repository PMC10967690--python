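"""Community ecology: relative abundance, alpha diversity, Bray-Curtis,
NMDS ordination, ANOSIM, VIF screening, RDA and variation partitioning.

NMDS minimizes Kruskal stress-1,

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

by alternating isotonic (monotone) regression of configuration distances on
dissimilarity ranks with Guttman-transform updates; a step is accepted only
if it lowers stress, so the recorded stress trajectory is non-increasing by
construction. ANOSIM ranks all n(n-1)/2 dissimilarities and tests
R = (rbar_between - rbar_within)/(M/4) against a permutation (or exhaustive)
null of group relabelings. RDA is the PCA of the fitted values from a
multivariate regression of the (optionally Hellinger-transformed) community
matrix on standardized environmental variables.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity.alpha import chao1 as _skbio_chao1
from sklearn.base import BaseEstimator

from .io import InvariantError, MeasurementTable, OtuTable


# ---------------------------------------------------------------------------
# relative abundance + alpha diversity
# ---------------------------------------------------------------------------

def relative_abundance(otu: OtuTable, rank: str = "phylum",
                       min_frac: float = 0.01) -> pd.DataFrame:
    """Aggregate counts at a taxonomic rank and total-sum scale per sample.

    Ranks whose overall mean relative abundance falls below ``min_frac``
    are lumped into an ``"others"`` bucket; every row sums to 1.
    """
    rel = otu.relative()
    by_rank: dict[str, list[str]] = {}
    for o in otu.otu_ids:
        by_rank.setdefault(otu.rank_of(o, rank), []).append(o)
    agg = pd.DataFrame({name: rel[cols].sum(axis=1)
                        for name, cols in by_rank.items()})
    keep = agg.mean(axis=0) >= min_frac
    out = agg.loc[:, keep.to_numpy()].copy()
    lumped = agg.loc[:, ~keep.to_numpy()]
    if lumped.shape[1]:
        out["others"] = lumped.sum(axis=1)
    return out


def alpha_diversity(otu: OtuTable, metric: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity: richness, Shannon (natural log) or Chao1."""
    counts = otu.counts
    if metric == "richness":
        vals = (counts > 0).sum(axis=1).astype(float)
    elif metric == "shannon":
        def h(row: np.ndarray) -> float:
            p = row[row > 0] / row.sum()
            return float(-(p * np.log(p)).sum())
        vals = pd.Series([h(r) for r in counts.to_numpy(dtype=float)],
                         index=counts.index)
    elif metric == "chao1":
        # classic estimator S_obs + f1^2/(2*f2)
        vals = pd.Series([float(_skbio_chao1(r, bias_corrected=False))
                          for r in counts.to_numpy()], index=counts.index)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return vals.rename(metric)


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(otu: OtuTable | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix BC(a,b) = sum|a-b| / sum(a+b)."""
    if isinstance(otu, OtuTable):
        mat = otu.counts
    else:
        mat = pd.DataFrame(otu)
    arr = mat.to_numpy(dtype=float)
    if (arr < 0).any():
        raise InvariantError("negative abundances")
    zero = arr.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = list(mat.index[zero])
        raise InvariantError(f"Bray-Curtis undefined between all-zero "
                             f"samples: {bad}")
    condensed = pdist(arr, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in mat.index])


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def _kruskal_stress(d_config: np.ndarray, d_hat: np.ndarray) -> float:
    denom = float((d_config ** 2).sum())
    if denom == 0:
        return 0.0
    return math.sqrt(float(((d_config - d_hat) ** 2).sum()) / denom)


class NMDS(BaseEstimator):
    """Non-metric multidimensional scaling by majorization, sklearn-style.

    Best configuration over ``n_restarts`` random starts plus one metric
    start (classical scaling); per-iteration stress is logged and strictly
    non-increasing (non-improving Guttman steps terminate the run).

    Attributes (after ``fit``): ``embedding_`` (n x k), ``stress_``,
    ``stress_history_`` of the winning start, ``converged_``, ``ids_``.
    """

    def __init__(self, n_components: int = 2, n_restarts: int = 20,
                 max_iter: int = 500, tol: float = 1e-6,
                 random_state: int | None = 0):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, dissimilarity: DistanceMatrix | np.ndarray, y=None) -> "NMDS":
        if isinstance(dissimilarity, DistanceMatrix):
            D = dissimilarity.data.astype(float)
            self.ids_ = list(dissimilarity.ids)
        else:
            D = np.asarray(dissimilarity, dtype=float)
            self.ids_ = [str(i) for i in range(D.shape[0])]
        n = D.shape[0]
        if n < self.n_components + 2:
            raise InvariantError("need at least k+2 samples")
        rng = np.random.default_rng(self.random_state)
        iu = np.triu_indices(n, 1)
        order = np.argsort(D[iu], kind="stable")

        starts = [self._metric_start(D)]
        starts += [rng.normal(size=(n, self.n_components))
                   for _ in range(self.n_restarts)]
        best = None
        for X0 in starts:
            X, history, converged = self._smacof(D, X0, iu, order)
            if best is None or history[-1] < best[1][-1]:
                best = (X, history, converged)
        X, history, converged = best
        self.embedding_ = X - X.mean(axis=0)
        self.stress_ = float(history[-1])
        self.stress_history_ = [float(s) for s in history]
        self.converged_ = bool(converged)
        if not converged:
            warnings.warn("NMDS did not converge in any start; best-effort "
                          "configuration returned", stacklevel=2)
        return self

    def fit_transform(self, dissimilarity, y=None) -> np.ndarray:
        return self.fit(dissimilarity).embedding_

    def _metric_start(self, D: np.ndarray) -> np.ndarray:
        # classical (Torgerson) scaling as the metric start
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D ** 2) @ J
        eigval, eigvec = np.linalg.eigh(B)
        idx = np.argsort(eigval)[::-1][: self.n_components]
        lam = np.clip(eigval[idx], 0.0, None)
        return eigvec[:, idx] * np.sqrt(lam)

    def _smacof(self, D, X, iu, order):
        n = D.shape[0]
        d = pdist(X)
        d_hat = self._monotone_fit(d, order)
        stress = _kruskal_stress(d, d_hat)
        history = [stress]
        converged = False
        for _ in range(self.max_iter):
            X_new = self._guttman(X, d, d_hat, n)
            d_new = pdist(X_new)
            d_hat_new = self._monotone_fit(d_new, order)
            stress_new = _kruskal_stress(d_new, d_hat_new)
            if stress_new >= stress - 1e-15:       # non-improving: stop
                converged = stress - stress_new < self.tol
                break
            X, d, d_hat, stress = X_new, d_new, d_hat_new, stress_new
            history.append(stress)
            if history[-2] - history[-1] < self.tol:
                converged = True
                break
        return X, history, converged

    @staticmethod
    def _monotone_fit(d: np.ndarray, order: np.ndarray) -> np.ndarray:
        # isotonic regression of configuration distances on dissimilarity rank
        fitted = isotonic_regression(d[order]).x
        d_hat = np.empty_like(d)
        d_hat[order] = fitted
        return d_hat

    @staticmethod
    def _guttman(X, d, d_hat, n):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, d_hat / d, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        return (B @ X) / n


def nmds(dissimilarity, n_components: int = 2, n_restarts: int = 20,
         seed: int | None = 0, **kwargs) -> NMDS:
    """Functional wrapper over :class:`NMDS`."""
    return NMDS(n_components=n_components, n_restarts=n_restarts,
                random_state=seed, **kwargs).fit(dissimilarity)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int | None
    exact: bool = False


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim(dissimilarity: DistanceMatrix | np.ndarray, groups,
           n_permutations: int = 999, seed: int | None = 0,
           exact: bool = False) -> AnosimResult:
    """ANOSIM: ranked between- vs within-group dissimilarities.

    ``p = (1 + #{perm R >= observed R}) / (1 + n_permutations)`` (upper
    tail). With ``exact=True`` all distinct group relabelings are
    enumerated instead (feasible for small n).
    """
    if isinstance(dissimilarity, DistanceMatrix):
        D = dissimilarity.data
    else:
        D = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(groups)
    if len(labels) != D.shape[0]:
        raise InvariantError("labels do not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise InvariantError("need at least 2 groups")
    if (counts < 2).any():
        raise InvariantError("every group needs at least 2 members")
    iu = np.triu_indices(D.shape[0], 1)
    ranks = sps.rankdata(D[iu])
    same = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranks, same)

    if exact:
        perms = set(itertools.permutations(labels))
        count = sum(
            _anosim_r(ranks, np.asarray(p)[iu[0]] == np.asarray(p)[iu[1]])
            >= r_obs - 1e-12
            for p in perms)
        return AnosimResult(r_obs, count / len(perms), len(perms), None, True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        same_p = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, same_p) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return AnosimResult(r_obs, p, n_permutations, seed, False)


# ---------------------------------------------------------------------------
# VIF screening
# ---------------------------------------------------------------------------

@dataclass
class VifReport:
    rounds: list[pd.Series]
    retained: list[str]
    dropped: list[str]
    cutoff: float


def _vif_values(X: pd.DataFrame) -> pd.Series:
    """VIF_i = 1/(1 - R_i^2) from regressing column i on the others."""
    arr = X.to_numpy(dtype=float)
    n, p = arr.shape
    out = {}
    for i, name in enumerate(X.columns):
        y = arr[:, i]
        others = np.delete(arr, i, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            raise InvariantError(f"constant variable {name!r}")
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_screen(env: MeasurementTable | pd.DataFrame,
               cutoff: float = 10.0) -> VifReport:
    """Iteratively drop the largest-VIF variable until all VIF <= cutoff.

    Perfectly collinear variables (infinite VIF) fall first, with a warning;
    ties break alphabetically on the variable name.
    """
    X = env.matrix() if isinstance(env, MeasurementTable) else pd.DataFrame(env)
    X = X.dropna()
    if X.shape[1] < 2:
        raise InvariantError("need at least 2 variables")
    rounds: list[pd.Series] = []
    dropped: list[str] = []
    while X.shape[1] >= 2:
        vifs = _vif_values(X)
        rounds.append(vifs)
        over = vifs[vifs > cutoff]
        if over.empty:
            break
        if np.isinf(over).any():
            warnings.warn("perfectly collinear variable dropped",
                          stacklevel=2)
        worst = over.sort_index().idxmax()  # stable alphabetical tie-break
        dropped.append(str(worst))
        X = X.drop(columns=[worst])
    return VifReport(rounds, list(X.columns), dropped, cutoff)


# ---------------------------------------------------------------------------
# RDA + variation partitioning
# ---------------------------------------------------------------------------

def hellinger(abundance: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of row-relative abundances."""
    arr = abundance.to_numpy(dtype=float)
    totals = arr.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise InvariantError("zero-total sample in Hellinger transform")
    return pd.DataFrame(np.sqrt(arr / totals), index=abundance.index,
                        columns=abundance.columns)


@dataclass
class RdaResult:
    axes: pd.DataFrame                  # sample scores, constrained axes
    axis_fractions: np.ndarray          # of total variance, non-increasing
    constrained_fraction: float
    total_variance: float
    constrained_variance: float
    unconstrained_variance: float
    biplot_scores: pd.DataFrame         # env variables x axes
    variable_p: pd.Series | None = None
    seed: int | None = None


class RDA(BaseEstimator):
    """Redundancy analysis, sklearn-style.

    ``fit(Y, X)`` centers the community matrix Y (after an optional
    Hellinger transform), regresses it on standardized environment X, and
    extracts constrained axes as the PCA of the fitted values. Per-variable
    significance comes from seeded marginal permutation tests (permuting
    the variable's rows and recomputing its constrained R-squared).
    """

    def __init__(self, hellinger_transform: bool = True,
                 n_permutations: int = 999, random_state: int | None = 0):
        self.hellinger_transform = hellinger_transform
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, Y, X, y=None) -> "RDA":
        Y = pd.DataFrame(Y)
        X = X.matrix() if isinstance(X, MeasurementTable) else pd.DataFrame(X)
        if list(Y.index) != list(X.index):
            shared = [s for s in Y.index if s in set(X.index)]
            if len(shared) < 3:
                raise InvariantError("fewer than 3 aligned samples")
            Y, X = Y.loc[shared], X.loc[shared]
        n = Y.shape[0]
        if X.shape[1] > n - 1:
            raise InvariantError("more environmental variables than n-1")
        if self.hellinger_transform:
            Y = hellinger(Y)
        Yc = Y - Y.mean(axis=0)
        sds = X.std(ddof=1)
        if (sds == 0).any():
            raise InvariantError(
                f"constant env variable(s): {list(sds[sds == 0].index)}")
        Xs = (X - X.mean(axis=0)) / sds

        Yfit = self._fitted(Yc.to_numpy(), Xs.to_numpy())
        total = float((Yc.to_numpy() ** 2).sum())
        constrained = float((Yfit ** 2).sum())
        u, s, vt = np.linalg.svd(Yfit, full_matrices=False)
        rank = min(np.linalg.matrix_rank(Xs.to_numpy()), Y.shape[1])
        s = s[:rank]
        scores = u[:, :rank] * s
        axes = pd.DataFrame(scores, index=Y.index,
                            columns=[f"RDA{k+1}" for k in range(rank)])
        fractions = (s ** 2) / total if total > 0 else np.zeros_like(s)
        biplot = pd.DataFrame(
            np.corrcoef(np.column_stack([Xs.to_numpy(), scores]),
                        rowvar=False)[: Xs.shape[1], Xs.shape[1]:],
            index=Xs.columns, columns=axes.columns)

        self.result_ = RdaResult(
            axes=axes, axis_fractions=fractions,
            constrained_fraction=constrained / total if total else 0.0,
            total_variance=total, constrained_variance=constrained,
            unconstrained_variance=total - constrained,
            biplot_scores=biplot, seed=self.random_state)
        if self.n_permutations:
            self.result_.variable_p = self._variable_significance(Yc, Xs)
        return self

    @staticmethod
    def _fitted(Yc: np.ndarray, Xs: np.ndarray) -> np.ndarray:
        design = np.column_stack([np.ones(Yc.shape[0]), Xs])
        beta, *_ = np.linalg.lstsq(design, Yc, rcond=None)
        return design @ beta

    def _variable_significance(self, Yc: pd.DataFrame,
                               Xs: pd.DataFrame) -> pd.Series:
        rng = np.random.default_rng(self.random_state)
        Ya = Yc.to_numpy()
        total = float((Ya ** 2).sum())
        out = {}
        for name in Xs.columns:
            x = Xs[name].to_numpy()
            obs = float((self._fitted(Ya, x[:, None]) ** 2).sum()) / total
            count = 0
            for _ in range(self.n_permutations):
                xp = rng.permutation(x)
                r2 = float((self._fitted(Ya, xp[:, None]) ** 2).sum()) / total
                if r2 >= obs - 1e-12:
                    count += 1
            out[name] = (1 + count) / (1 + self.n_permutations)
        return pd.Series(out, name="p_value")


def rda(species, env, hellinger_transform: bool = True,
        n_permutations: int = 999, seed: int | None = 0) -> RdaResult:
    """Functional wrapper over :class:`RDA`."""
    est = RDA(hellinger_transform=hellinger_transform,
              n_permutations=n_permutations, random_state=seed).fit(species, env)
    return est.result_


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise InvariantError("too few samples for adjusted R-squared")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class VariationPartition:
    fractions: dict[str, float]         # unique/shared adjusted fractions
    total_adjusted: float
    negative_flagged: list[str] = field(default_factory=list)


def variation_partition(species, env_groups: Mapping[str, pd.DataFrame],
                        hellinger_transform: bool = True) -> VariationPartition:
    """Adjusted-R-squared partitioning over 2-3 named environment sets.

    All subset RDAs are fitted; unique and shared fractions follow by
    inclusion-exclusion on adjusted R-squared. Negative fractions are
    reported as computed and flagged, never clipped.
    """
    names = list(env_groups.keys())
    if not 2 <= len(names) <= 3:
        raise InvariantError("need 2 or 3 environment sets")
    Y = pd.DataFrame(species)

    def adj_r2(subset: tuple[str, ...]) -> float:
        if not subset:
            return 0.0
        X = pd.concat([pd.DataFrame(env_groups[g]) for g in subset], axis=1)
        res = rda(Y, X, hellinger_transform=hellinger_transform,
                  n_permutations=0)
        return _adjusted_r2(res.constrained_fraction, Y.shape[0], X.shape[1])

    r2 = {subset: adj_r2(subset)
          for k in range(1, len(names) + 1)
          for subset in itertools.combinations(names, k)}
    full = r2[tuple(names)]
    fractions: dict[str, float] = {}
    if len(names) == 2:
        a, b = names
        fractions[f"{a}_unique"] = full - r2[(b,)]
        fractions[f"{b}_unique"] = full - r2[(a,)]
        fractions["shared"] = r2[(a,)] + r2[(b,)] - full
    else:
        a, b, c = names
        fractions[f"{a}_unique"] = full - r2[(b, c)]
        fractions[f"{b}_unique"] = full - r2[(a, c)]
        fractions[f"{c}_unique"] = full - r2[(a, b)]
        fractions[f"{a}_{b}_shared"] = (r2[(a, c)] + r2[(b, c)] - r2[(c,)]
                                        - full)
        fractions[f"{a}_{c}_shared"] = (r2[(a, b)] + r2[(b, c)] - r2[(b,)]
                                        - full)
        fractions[f"{b}_{c}_shared"] = (r2[(a, b)] + r2[(a, c)] - r2[(a,)]
                                        - full)
        # inclusion-exclusion: shared-by-all = sum singles - sum pairs + full
        fractions["all_shared"] = (r2[(a,)] + r2[(b,)] + r2[(c,)]
                                   - r2[(a, b)] - r2[(a, c)] - r2[(b, c)]
                                   + full)
    flagged = [k for k, v in fractions.items() if v < 0]
    return VariationPartition(fractions, full, flagged)
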