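"""Synthetic soil-measurement and OTU-count generators with known ground truth.

Two generators mirror the study design they stand in for: a 3-treatment
(CK control, T1, T2) x 4-period x 3-replicate Gaussian soil design with
additive treatment effects, and compositional OTU counts from a latent
Gaussian copula (correlated taxon blocks) pushed through multinomial
sampling at a fixed sequencing depth.

The module also carries the published group summaries of the study's soil
(Table 1) and tea-leaf quality (Table 2) tables, expanded into three
pseudo-replicates per cell that reproduce each printed mean and SD exactly,
so ANOVA/Duncan/percent-change machinery can run on published content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import InvariantError, MeasurementTable, OtuTable

TREATMENTS = ("CK", "T1", "T2")
PERIODS = (1, 2, 3, 4)


# ---------------------------------------------------------------------------
# specs + ground truth
# ---------------------------------------------------------------------------

@dataclass
class SoilSimSpec:
    """Design for the Gaussian soil generator.

    ``variables`` maps variable name -> (baseline mean, SD); ``effects`` maps
    (treatment, period) -> {variable: additive shift}. Values of
    concentration-like variables are truncated at zero (events are counted).
    """

    variables: Mapping[str, tuple[float, float]]
    effects: Mapping[tuple[str, int], Mapping[str, float]] = field(
        default_factory=dict)
    treatments: Sequence[str] = TREATMENTS
    periods: Sequence[int] = PERIODS
    n_replicates: int = 3

    def __post_init__(self) -> None:
        for name, (mu, sd) in self.variables.items():
            if sd <= 0:
                raise InvariantError(f"non-positive SD for {name!r}")
            if not (np.isfinite(mu) and np.isfinite(sd)):
                raise InvariantError(f"non-finite baseline for {name!r}")
        for eff in self.effects.values():
            for name, delta in eff.items():
                if not np.isfinite(delta):
                    raise InvariantError(f"non-finite effect on {name!r}")


@dataclass
class OtuSimSpec:
    """Design for the latent-Gaussian-copula OTU generator.

    Per-OTU latent log-abundances are multivariate normal with correlation
    ``rho`` inside each declared block; declared log-fold-change effects are
    added for non-reference groups; counts are multinomial at ``depth``.
    """

    n_samples_per_group: Mapping[str, int]
    n_otus: int = 50
    mu: float = 0.0          # log-normal base-abundance location
    sigma: float = 1.0       # log-normal base-abundance scale
    blocks: Sequence[Sequence[int]] = ()
    rho: float = 0.0
    group_effects: Mapping[str, Mapping[int, float]] = field(
        default_factory=dict)  # group -> {otu index: log-fold change}
    depth: int = 10_000

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise InvariantError("depth must be positive")
        if not (0.0 <= self.rho < 1.0):
            raise InvariantError("rho must lie in [0, 1)")
        if self.sigma <= 0:
            raise InvariantError("sigma must be positive")
        seen: set[int] = set()
        for block in self.blocks:
            bs = set(block)
            if bs & seen:
                raise InvariantError("overlapping correlation blocks")
            seen |= bs
        if seen and (min(seen) < 0 or max(seen) >= self.n_otus):
            raise InvariantError("block index outside [0, n_otus)")
        if sum(len(b) for b in self.blocks) > self.n_otus:
            raise InvariantError("block sizes exceed n_otus")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    group_means: pd.DataFrame | None = None
    effect_otus: dict[str, dict[str, float]] = field(default_factory=dict)
    block_membership: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_soil(spec: SoilSimSpec, seed: int = 0,
                  ) -> tuple[MeasurementTable, GroundTruth]:
    """Draw a full factorial soil table: baseline + effect + N(0, SD) noise."""
    rng = np.random.default_rng(seed)
    rows = []
    n_trunc = 0
    for trt in spec.treatments:
        for period in spec.periods:
            eff = spec.effects.get((trt, int(period)), {})
            for rep in range(1, spec.n_replicates + 1):
                row = {"sample_id": f"{trt}.P{period}.R{rep}",
                       "treatment": trt, "period": int(period),
                       "replicate": rep}
                for name, (mu, sd) in spec.variables.items():
                    val = rng.normal(mu + eff.get(name, 0.0), sd)
                    if name != "pH" and val < 0:
                        val, n_trunc = 0.0, n_trunc + 1
                    row[name] = val
                rows.append(row)
    if n_trunc:
        warnings.warn(f"{n_trunc} values truncated at 0", stacklevel=2)
    table = MeasurementTable(pd.DataFrame(rows))
    means = {
        (trt, p): {
            name: mu + spec.effects.get((trt, p), {}).get(name, 0.0)
            for name, (mu, _) in spec.variables.items()}
        for trt in spec.treatments for p in spec.periods}
    truth = GroundTruth(group_means=pd.DataFrame(means).T)
    return table, truth


def _block_correlation(n_otus: int, blocks: Sequence[Sequence[int]],
                       rho: float) -> np.ndarray:
    corr = np.eye(n_otus)
    for block in blocks:
        idx = np.asarray(list(block))
        corr[np.ix_(idx, idx)] = rho
        corr[idx, idx] = 1.0
    return corr


def simulate_otu(spec: OtuSimSpec, seed: int = 0,
                 ) -> tuple[OtuTable, GroundTruth]:
    """Draw compositional OTU counts with planted blocks and group effects.

    Latent layer: z ~ MVN(0, block-correlation), per-OTU log-abundance
    mu + sigma*z (+ group log-fold change on designated OTUs); relative
    abundances are the softmax of log-abundances; counts are multinomial
    at the declared depth, so per-sample totals equal ``depth`` exactly.
    Blocks map to distinct synthetic phyla in the taxonomy.
    """
    # separate latent and count streams so the latent layer is invariant
    # to sequencing depth (compositions match in expectation across depths)
    rng_latent, rng_count = np.random.default_rng(seed).spawn(2)
    corr = _block_correlation(spec.n_otus, spec.blocks, spec.rho)
    chol = np.linalg.cholesky(corr)
    otu_ids = [f"OTU{i:04d}" for i in range(spec.n_otus)]

    block_of = {}
    for b, block in enumerate(spec.blocks):
        for i in block:
            block_of[otu_ids[i]] = b
    taxonomy = {}
    for i, otu in enumerate(otu_ids):
        phylum = (f"Blockphylum{block_of[otu]}" if otu in block_of
                  else f"Bgphylum{i % 5}")
        taxonomy[otu] = f"k__Bacteria;p__{phylum};g__Genus{i:04d}"

    rows, index, groups = [], [], []
    for group, n in spec.n_samples_per_group.items():
        lfc = np.zeros(spec.n_otus)
        for i, delta in spec.group_effects.get(group, {}).items():
            lfc[int(i)] = delta
        for k in range(n):
            z = chol @ rng_latent.standard_normal(spec.n_otus)
            log_abund = spec.mu + spec.sigma * z + lfc
            p = np.exp(log_abund - log_abund.max())
            p /= p.sum()
            rows.append(rng_count.multinomial(spec.depth, p))
            index.append(f"{group}.S{k + 1}")
            groups.append(group)
    counts = pd.DataFrame(np.asarray(rows), index=index, columns=otu_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero OTUs are expected here
        otu = OtuTable(counts, taxonomy)
    otu.sample_groups = pd.Series(groups, index=index)  # type: ignore[attr-defined]
    truth = GroundTruth(
        effect_otus={g: {otu_ids[int(i)]: d for i, d in eff.items()}
                     for g, eff in spec.group_effects.items()},
        block_membership=block_of)
    return otu, truth


# ---------------------------------------------------------------------------
# published-table fixtures
# ---------------------------------------------------------------------------

def _cells(*vals):
    """12 (mean, sd, letters) cells in CK,T1,T2 x period 1..4 order."""
    out = {}
    for j, trt_period in enumerate(
            [(t, p) for p in PERIODS for t in TREATMENTS]):
        out[trt_period] = vals[j]
    return out


#: Published soil physicochemical summaries: variable -> (treatment, period)
#: -> (mean, sd, significance letters). Units: TN/TC g/kg; AN/AMN/NN/AP/AK
#: mg/kg; SOM as declared in the source table; pH and C:N unitless.
TABLE1_SOIL = {
    "pH": _cells((5.08, .02, "a"), (5.13, .01, "a"), (4.96, .04, "b"),
                 (4.69, .01, "a"), (4.62, .03, "a"), (4.37, .13, "b"),
                 (4.78, .02, "a"), (4.90, .07, "a"), (4.79, .03, "a"),
                 (4.67, .07, "b"), (4.88, .03, "a"), (4.83, .03, "a")),
    "TN": _cells((0.49, .008, "c"), (0.68, .001, "b"), (0.85, .026, "a"),
                 (1.21, .004, "c"), (1.26, .013, "b"), (1.34, .017, "a"),
                 (1.17, .011, "b"), (1.25, .015, "a"), (1.23, .037, "ab"),
                 (1.11, .012, "c"), (1.34, .03, "b"), (1.44, .014, "a")),
    "AN": _cells((18.17, .28, "b"), (15.91, .29, "c"), (22.76, .31, "a"),
                 (37.60, .67, "b"), (55.98, .23, "a"), (37.26, .07, "b"),
                 (15.42, .15, "b"), (30.88, .07, "a"), (30.61, .31, "a"),
                 (14.90, .19, "c"), (25.95, .15, "b"), (30.03, .16, "a")),
    "AMN": _cells((13.15, .13, "b"), (12.69, .20, "b"), (16.75, .20, "a"),
                  (20.61, .21, "b"), (25.76, .23, "a"), (12.62, .09, "c"),
                  (7.55, .09, "c"), (15.37, .03, "a"), (13.24, .13, "b"),
                  (8.70, .20, "b"), (9.08, .54, "ab"), (9.87, .09, "a")),
    "NN": _cells((5.57, .16, "a"), (3.22, .12, "b"), (6.01, .21, "a"),
                 (16.99, .49, "c"), (30.22, .13, "a"), (24.65, .15, "b"),
                 (7.87, .24, "c"), (15.51, .09, "b"), (17.38, .24, "a"),
                 (6.20, .08, "c"), (16.87, .27, "b"), (20.15, .16, "a")),
    "TC": _cells((4.72, .13, "c"), (5.19, .01, "b"), (6.69, .07, "a"),
                 (10.17, .25, "b"), (10.72, .01, "b"), (12.38, .08, "a"),
                 (11.22, .02, "c"), (12.83, .13, "a"), (11.74, .05, "b"),
                 (11.54, .08, "c"), (13.45, .07, "b"), (13.86, .03, "a")),
    "SOM": _cells((8.22, .23, "c"), (9.04, .02, "b"), (11.66, .13, "a"),
                  (17.72, .44, "c"), (18.68, .02, "b"), (21.57, .14, "a"),
                  (19.54, .03, "c"), (22.35, .23, "a"), (20.46, .09, "b"),
                  (20.10, .14, "c"), (23.43, .12, "b"), (24.14, .05, "a")),
    "AP": _cells((0.41, .09, "c"), (2.43, .24, "a"), (1.69, .19, "b"),
                 (5.61, .27, "a"), (4.27, .27, "b"), (4.61, .19, "b"),
                 (9.07, .94, "b"), (13.70, 1.40, "a"), (6.33, .11, "c"),
                 (10.56, 1.02, "c"), (26.59, .55, "a"), (19.01, 1.10, "b")),
    "AK": _cells((96.49, .84, "c"), (136.12, 2.78, "b"), (166.65, .85, "a"),
                 (143.85, .47, "b"), (158.54, 2.89, "a"), (123.16, .35, "c"),
                 (160.97, 3.96, "c"), (241.04, .89, "a"), (224.20, .90, "b"),
                 (139.69, 1.59, "c"), (222.50, 3.14, "b"), (242.78, .61, "a")),
    "CN": _cells((9.72, .23, "a"), (7.65, .02, "b"), (7.92, .24, "b"),
                 (9.89, .18, "a"), (8.48, .08, "c"), (9.25, .06, "b"),
                 (9.56, .08, "b"), (10.27, .11, "a"), (9.57, .27, "b"),
                 (10.44, .10, "a"), (10.01, .20, "b"), (9.64, .11, "b")),
}

#: Published tea-leaf quality summaries, same layout; all values % dry mass.
TABLE2_TEA = {
    "tea_polyphenols": _cells(
        (20.78, .64, "a"), (19.47, .79, "b"), (20.59, .41, "ab"),
        (20.39, .41, "a"), (20.56, .58, "a"), (19.49, .67, "a"),
        (21.19, .74, "b"), (19.52, .53, "c"), (22.63, .36, "a"),
        (18.74, .45, "a"), (17.53, .07, "b"), (17.88, .12, "b")),
    "catechins": _cells(
        (13.90, .55, "a"), (13.13, .76, "a"), (14.20, .26, "a"),
        (13.55, .41, "a"), (13.84, .32, "a"), (13.33, .39, "a"),
        (11.29, 1.21, "a"), (12.52, .13, "a"), (11.60, .50, "a"),
        (13.90, .20, "a"), (13.03, .77, "a"), (13.42, .18, "a")),
    "EC": _cells(
        (0.34, .069, "a"), (0.37, .024, "a"), (0.21, .01, "b"),
        (0.39, .027, "a"), (0.31, .039, "b"), (0.40, .019, "a"),
        (1.26, .07, "a"), (1.23, .03, "a"), (1.20, .03, "a"),
        (0.48, .01, "a"), (0.36, .04, "b"), (0.38, .01, "b")),
    "EGC": _cells(
        (0.84, .048, "b"), (0.93, .01, "a"), (0.92, .012, "a"),
        (0.85, .009, "b"), (0.88, .006, "a"), (0.86, .01, "b"),
        (1.07, .08, "a"), (1.17, .009, "a"), (1.10, .03, "a"),
        (0.89, .003, "a"), (0.84, .02, "c"), (0.87, .006, "b")),
    "ECG": _cells(
        (1.23, .06, "b"), (1.56, .04, "a"), (1.51, .05, "a"),
        (1.22, .10, "b"), (1.35, .03, "a"), (1.32, .01, "ab"),
        (1.31, .13, "b"), (1.59, .05, "a"), (1.36, .17, "ab"),
        (1.26, .01, "b"), (1.46, .02, "a"), (1.41, .044, "a")),
    "EGCG": _cells(
        (9.62, .14, "ab"), (8.13, 1.34, "b"), (9.89, .24, "a"),
        (9.57, .13, "ab"), (10.01, .23, "a"), (9.42, .35, "b"),
        (6.59, 1.06, "b"), (7.50, .10, "a"), (6.79, .33, "a"),
        (9.19, .09, "a"), (8.81, .47, "a"), (9.01, .13, "a")),
    "amino_acids": _cells(
        (3.95, .05, "b"), (4.01, .17, "ab"), (4.22, .04, "a"),
        (3.10, .10, "b"), (3.38, .08, "a"), (3.11, .04, "b"),
        (2.22, .03, "b"), (2.43, .07, "a"), (2.30, .07, "b"),
        (2.24, .02, "c"), (2.88, .05, "a"), (2.68, .09, "b")),
    "caffeine": _cells(
        (2.93, .26, "a"), (3.48, .01, "a"), (3.31, .23, "a"),
        (2.87, .34, "a"), (3.07, .13, "a"), (3.32, .15, "a"),
        (3.91, .11, "a"), (3.76, .06, "ab"), (3.60, .08, "b"),
        (3.59, .16, "a"), (3.36, .05, "a"), (3.59, .05, "a")),
    "soluble_sugar": _cells(
        (3.43, .24, "b"), (3.45, .57, "b"), (5.30, .02, "a"),
        (5.40, .32, "b"), (7.23, .53, "a"), (5.68, .13, "b"),
        (4.82, .13, "b"), (5.22, .18, "a"), (5.18, .11, "a"),
        (5.21, .39, "b"), (6.22, .45, "a"), (5.80, .17, "ab")),
}

SOIL_UNITS = {"pH": "", "TN": "g/kg", "AN": "mg/kg", "AMN": "mg/kg",
              "NN": "mg/kg", "TC": "g/kg", "SOM": "as-declared",
              "AP": "mg/kg", "AK": "mg/kg", "CN": ""}
TEA_UNITS = {v: "% dry mass" for v in TABLE2_TEA}


def _expand(summary: Mapping[str, Mapping[tuple[str, int], tuple]],
            units: Mapping[str, str]) -> MeasurementTable:
    # {m-s, m, m+s}: sample mean m and sample SD s (ddof=1) exactly.
    rows: dict[tuple[str, int, int], dict] = {}
    for var, cells in summary.items():
        for (trt, period), (mean, sd, _letters) in cells.items():
            for rep, offset in enumerate((-1.0, 0.0, 1.0), start=1):
                key = (trt, period, rep)
                row = rows.setdefault(key, {
                    "sample_id": f"{trt}.P{period}.R{rep}",
                    "treatment": trt, "period": period, "replicate": rep})
                row[var] = mean + offset * sd
    return MeasurementTable(pd.DataFrame(list(rows.values())), units)


def published_tables() -> tuple[MeasurementTable, MeasurementTable]:
    """Published soil and tea-quality summaries as replicate-level fixtures.

    Each (treatment, period) cell of the printed tables expands into the
    three pseudo-replicates {m-s, m, m+s}, whose sample mean and sample SD
    equal the printed mean and SD exactly; letters are not part of the data
    (see :data:`TABLE1_SOIL` / :data:`TABLE2_TEA` for the printed letters).
    """
    return _expand(TABLE1_SOIL, SOIL_UNITS), _expand(TABLE2_TEA, TEA_UNITS)
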