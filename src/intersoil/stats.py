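"""Group statistics: one-way ANOVA, Duncan's multiple range test with
letter display, percent-change tables and cross-table correlation matrices.

Duncan's multiple range test compares the p means spanned by each candidate
range against a critical range R_p = q(1 - alpha_p, p, df) * sqrt(MSE/n_h)
where alpha_p = 1 - (1 - alpha)^(p - 1) is Duncan's protection level, q is
the studentized-range quantile and n_h the harmonic mean group size. No
lookup tables are used; quantiles come from the studentized range
distribution directly. For k = 2 the test reduces to Fisher's LSD.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import InvariantError, MeasurementTable


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    mse: float
    group_means: pd.Series
    group_ns: pd.Series


def anova_oneway(values, groups) -> AnovaResult:
    """Classical one-way decomposition with an F test.

    Degenerate inputs (any group with fewer than 2 observations, or zero
    within-group variance) raise rather than returning infinities.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "g": np.asarray(groups)}).dropna()
    sizes = df.groupby("g")["y"].size()
    if len(sizes) < 2:
        raise InvariantError("need at least 2 groups")
    small = sizes[sizes < 2].index.tolist()
    if small:
        raise InvariantError(f"groups with n < 2: {small}")
    means = df.groupby("g")["y"].mean()
    grand = df["y"].mean()
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(((df["y"] - means.loc[df["g"]].to_numpy()) ** 2).sum())
    df1, df2 = len(sizes) - 1, len(df) - len(sizes)
    mse = ss_within / df2
    if mse == 0:
        raise InvariantError("zero within-group variance: F undefined")
    f = (ss_between / df1) / mse
    p = float(sps.f.sf(f, df1, df2))
    return AnovaResult(f, df1, df2, p, mse, means, sizes)


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

@dataclass
class DuncanResult:
    means: pd.Series                    # sorted descending
    letters: dict[str, str]             # group -> letter string
    alpha: float
    mse: float
    df_error: int
    critical_ranges: dict[int, float]   # span p -> R_p
    significant: pd.DataFrame = field(default=None)  # pairwise bool


def _duncan_critical_range(p_span: int, df_error: int, alpha: float,
                           n_harmonic: float, mse: float) -> float:
    protection = 1.0 - (1.0 - alpha) ** (p_span - 1)
    q = sps.studentized_range.ppf(1.0 - protection, p_span, df_error)
    return float(q * math.sqrt(mse / n_harmonic))


def duncan_mrt(values, groups, alpha: float = 0.05) -> DuncanResult:
    """Duncan's multiple range test with compact-letter display.

    Means are sorted descending; a pair is declared different when its gap
    exceeds the critical range for the span of means it straddles *and* no
    enclosing non-significant range covers both (the standard underlining
    rule). Letters are assigned greedily from the largest mean.
    """
    anova = anova_oneway(values, groups)
    means = anova.group_means.sort_values(ascending=False)
    k = len(means)
    n_h = k / float((1.0 / anova.group_ns).sum())
    ranges = {p: _duncan_critical_range(p, anova.df_within, alpha, n_h,
                                        anova.mse)
              for p in range(2, k + 1)}

    names = list(means.index)
    # non-significant runs: maximal [i, j] with spread below the span range
    nonsig_runs: list[tuple[int, int]] = []
    for i in range(k):
        j_max = i
        for j in range(i + 1, k):
            span = j - i + 1
            if means.iloc[i] - means.iloc[j] < ranges[span]:
                j_max = j
        # a mean alone is its own run only if covered by no wider run
        nonsig_runs.append((i, j_max))
    # keep maximal runs only
    maximal = [r for r in nonsig_runs
               if not any(o[0] <= r[0] and r[1] <= o[1] and o != r
                          for o in nonsig_runs)]
    maximal.sort()
    letters: dict[str, str] = {name: "" for name in names}
    for idx, (i, j) in enumerate(maximal):
        letter = _letter(idx)
        for pos in range(i, j + 1):
            letters[names[pos]] += letter

    sig = pd.DataFrame(False, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        sig.loc[a, b] = sig.loc[b, a] = not set(letters[a]) & set(letters[b])
    return DuncanResult(means, letters, alpha, anova.mse, anova.df_within,
                        ranges, sig)


def _letter(idx: int) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = ""
    idx += 1
    while idx:
        idx, rem = divmod(idx - 1, 26)
        out = letters[rem] + out
    return out


def letter_table(table: MeasurementTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable, per-period Duncan letters across treatments.

    Returns a frame indexed by variable with one (period, treatment) column
    per cell, mirroring a published-summary layout.
    """
    records = {}
    for var in table.variables:
        for period in table.periods:
            sub = table.data[table.data["period"] == period]
            res = duncan_mrt(sub[var], sub["treatment"], alpha)
            for trt, let in res.letters.items():
                records.setdefault(var, {})[(period, trt)] = let
    out = pd.DataFrame(records).T
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["period", "treatment"])
    return out.sort_index(axis=1)


# ---------------------------------------------------------------------------
# percent change
# ---------------------------------------------------------------------------

def percent_change(table: MeasurementTable, reference: str = "CK",
                   variables=None) -> pd.DataFrame:
    """100*(mean_T - mean_ref)/mean_ref on group means, per period.

    Returns a frame indexed by variable with (treatment, period) columns;
    the reference treatment's column is identically 0. Zero reference means
    yield explicit missing values with a warning.
    """
    variables = list(variables) if variables is not None else table.variables
    means = table.group_means(variables)
    if reference not in means.index.get_level_values("treatment"):
        raise InvariantError(f"reference treatment {reference!r} absent")
    ref = means.xs(reference, level="treatment")
    out = {}
    n_zero = 0
    for (trt, period), row in means.iterrows():
        ref_row = ref.loc[period]
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * (row - ref_row) / ref_row
        zero_mask = ref_row == 0
        n_zero += int(zero_mask.sum()) if trt != reference else 0
        pct[zero_mask] = np.nan
        out[(trt, period)] = pct
    if n_zero:
        warnings.warn(f"{n_zero} zero reference means -> missing percent "
                      "changes", stacklevel=2)
    frame = pd.DataFrame(out)
    frame.columns.names = ["treatment", "period"]
    return frame.sort_index(axis=1)


# ---------------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    method: str
    q: pd.DataFrame | None = None       # BH-adjusted, optional


def spearman_exact_p(x, y) -> float:
    """Two-sided exact permutation p for Spearman's rho at small n.

    Enumerates all n! orderings of one variable's ranks (n <= 9), counting
    permutations whose |rho| matches or exceeds the observed |rho|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 9:
        raise ValueError("exact enumeration limited to n <= 9")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho_obs = _rank_corr(rx, ry)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = _rank_corr(rx, ry[list(perm)])
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx ** 2).sum() * (ry ** 2).sum()))
    if denom == 0:
        return 0.0
    return float((rx * ry).sum() / denom)


def _pair_corr(x: np.ndarray, y: np.ndarray, method: str,
               exact_max_n: int) -> tuple[float, float, int]:
    keep = np.isfinite(x) & np.isfinite(y)
    n = int(keep.sum())
    if n < 3:
        return np.nan, np.nan, n
    xs, ys = x[keep], y[keep]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return np.nan, np.nan, n
    if method == "pearson":
        r, p = sps.pearsonr(xs, ys)
    elif method == "spearman":
        r, p = sps.spearmanr(xs, ys)
        if n <= exact_max_n:
            p = spearman_exact_p(xs, ys)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p), n


def correlate(table_a: MeasurementTable, table_b: MeasurementTable | None = None,
              method: str = "pearson", bh_adjust: bool = False,
              exact_max_n: int = 9) -> CorrelationReport:
    """Pairwise correlation matrix between (or within) measurement tables.

    Samples are matched on sample_id; missing values are deleted pairwise
    and the effective n is reported per cell. Spearman p-values are exact
    (full enumeration) for n <= ``exact_max_n`` and use the t approximation
    above; Pearson always uses the t approximation. Cells with fewer than
    3 complete pairs are missing, with one summary warning.
    """
    a = table_a.matrix()
    if table_b is None:
        b = a
    else:
        shared = [s for s in table_a.sample_ids if s in set(table_b.sample_ids)]
        if len(shared) < 3:
            raise InvariantError("fewer than 3 shared samples")
        a = a.loc[shared]
        b = table_b.matrix().loc[shared]
    r = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    p = r.copy()
    n = pd.DataFrame(index=a.columns, columns=b.columns, dtype=int)
    n_short = 0
    for va in a.columns:
        for vb in b.columns:
            if table_b is None and va == vb:
                rr, pp, nn = 1.0, 0.0, int(a[va].notna().sum())
            else:
                rr, pp, nn = _pair_corr(a[va].to_numpy(dtype=float),
                                        b[vb].to_numpy(dtype=float),
                                        method, exact_max_n)
                n_short += int(nn < 3)
            r.loc[va, vb], p.loc[va, vb], n.loc[va, vb] = rr, pp, nn
    if n_short:
        warnings.warn(f"{n_short} variable pairs had <3 complete samples",
                      stacklevel=2)
    q = None
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests
        flat = p.to_numpy().ravel()
        mask = np.isfinite(flat)
        adj = np.full_like(flat, np.nan)
        if mask.any():
            adj[mask] = multipletests(flat[mask], method="fdr_bh")[1]
        q = pd.DataFrame(adj.reshape(p.shape), index=p.index, columns=p.columns)
    return CorrelationReport(r, p, n, method, q)
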