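# Methods

## Scope and data model

The package analyzes a three-treatment (CK monoculture control, T1, T2
intercropping), multi-period, replicated field design. Measurement tables
are tidy per-sample frames keyed by `(treatment, period, replicate)` with a
unique `sample_id`; OTU tables are samples × OTUs integer count matrices
with a rank-prefixed taxonomy lineage per OTU. All joins are on
`sample_id`, never row order. Missing measurement values propagate as
missing into group means and are deleted pairwise in correlations, with
the effective n reported; declared units are carried as metadata and never
converted (the source soil table labels organic matter "mg/kg" although
its magnitudes are typical of g/kg — the label is kept as declared).

## Soil fertility index

Indicator scores are bounded transforms `S_i(x) ∈ [0, 1]`:

- `linear_more` / `linear_less`: `(x − L)/(U − L)` clipped to [0, 1], and
  its complement. By default L and U are the observed min/max of the
  indicator over the fitted dataset (min–max scoring), so scores use the
  data's own range rather than external agronomic thresholds.
- `optimum_plateau`: rises linearly L→O1, equals 1 on [O1, O2], falls
  O2→U. Used for pH with default band [4.5, 5.5] — the acidity range tea
  prefers; values outside the fitted range clip to 0.
- `sigmoid_more` / `sigmoid_less`: `1/(1 + (x/x0)^(∓b))` with midpoint
  `x0` (default mid-range) and steepness `b > 0` (default 2.5).

The default assignment treats every nutrient, carbon pool and enzyme
activity as more-is-better and pH as optimum-plateau; every assignment is
overrideable per variable in the YAML config, because the original
per-indicator assignment table is not published — the package reproduces
the *method*, not unpublished constants. For the same reason the index's
exact percent increases on the published tables are treated as
direction-only claims (intercropping above control), never as numeric
targets.

Weights come from a standardized PCA of the **raw** indicator matrix (the
scores only bound contributions; a plateau-scored variable can be constant
on the score scale while still varying informatively on the raw scale).
Components with eigenvalue ≥ 1 are retained (Kaiser rule; at least one is
always kept), and indicator i receives weight proportional to its
communality — the sum of its squared loadings over retained components. An
alternative `variance_loading` weighting (variance explained × |loading|)
is available behind a flag. Weights are non-negative and sum to 1, so
`SFI = Σ W_i S_i ∈ [0, 1]` and is monotone in any more-is-better
indicator. Percent change is computed on group means per period against
the reference treatment, matching how the published percentages relate to
the published group means.

Caveat: when all population eigenvalues are ≈ 1 (independent indicators),
Kaiser retention is a coin flip per component and the communality weights
fluctuate around 1/n rather than converging to it; with full retention
they equal 1/n exactly. This is inherent to eigenvalue-threshold retention
at the boundary, not a numerical defect.

## Group statistics

One-way ANOVA uses the classical decomposition; groups with n < 2 or zero
within-group variance are rejected rather than returning infinities.
Duncan's multiple range test compares the gap of each pair of ranked means
against the critical range `R_p = q(1 − α_p, p, df) √(MSE/n_h)`, where `p`
is the span of means straddled, `α_p = 1 − (1 − α)^(p−1)` is Duncan's
protection level, `q` is the studentized-range quantile (computed from
scipy's distribution, no lookup tables) and `n_h` the harmonic mean group
size. Letters follow the standard underlining rule (maximal
non-significant runs of the descending means); for k = 2 the procedure
reduces to Fisher's LSD. On the published-table fixtures, letter patterns
are only asserted for clearly separated cells: printed SDs at 2–3 decimal
places make near-ties unstable at the printed precision.

Correlation matrices (Pearson or Spearman) use pairwise deletion with a
minimum of 3 complete pairs per cell. Spearman p-values are exact —
full enumeration of orderings — up to n = 9 and use the t approximation
above; Benjamini–Hochberg adjustment is available behind a flag and off by
default (the source analysis applies none).

## Published-table fixtures

The published group summaries (soil physicochemistry; tea-leaf quality)
are embedded as mean ± SD per (treatment, period) cell and expanded into
three pseudo-replicates `{m − s, m, m + s}`, whose sample mean and sample
SD (ddof = 1) equal the printed values exactly. This lets ANOVA, Duncan
letters and percent-change tables run on published content without the
unpublished raw replicates. Two printed percent claims (available nitrogen
+21.63 % and available phosphorus +310.61/+492.42 % in period 1) do not
match arithmetic on the printed means (recomputed 25.26 / 312.20 /
492.68 %) and are therefore excluded from numeric reproduction; all other
printed percentages reproduce within 0.1 percentage point.

## Synthetic data

`simulate_soil` draws each cell as baseline + additive (treatment, period)
effect + N(0, SD) noise, truncating concentration-like variables at zero
(events counted). Defaults mirror the field design: 3 treatments ×
4 periods × 3 replicates, baselines at the magnitudes of the published
soil table.

`simulate_otu` uses a latent Gaussian copula: per-OTU latent log-abundances
are multivariate normal with correlation ρ inside declared OTU blocks,
group log-fold-change effects are added on designated OTUs, relative
abundances are the softmax of the latent log-abundances, and counts are
multinomial at a fixed sequencing depth (so totals equal the depth
exactly — Dirichlet-multinomial-like overdispersion arises from the latent
layer). The latent and count streams come from two spawned RNG streams, so
compositions are depth-invariant in expectation. Blocks map to distinct
synthetic phyla. What this emulates: compositionality, overdispersion,
planted differential abundance and planted co-occurrence structure. What
it does not: zero-inflation beyond multinomial sampling, phylogenetic
signal, variable sequencing depth, chimeras/sequencing error. Tests
passing on this generator therefore validate the *inference machinery*,
not performance on any particular real community.

## Ordination and multivariate tests

Bray–Curtis dissimilarity `Σ|a − b| / Σ(a + b)` comes from scipy and is
returned as a scikit-bio `DistanceMatrix`. NMDS minimizes Kruskal
stress-1, `√(Σ(d − d̂)² / Σd²)`, alternating isotonic regression of
configuration distances on dissimilarity ranks with Guttman-transform
updates, best of 20 random starts plus one classical-scaling (metric)
start; convergence when the stress drop falls below 1e-6 or 500
iterations. Because the stress-1 normalizer changes between iterations,
plain SMACOF does not guarantee monotone stress-1; a candidate step is
therefore accepted only if it lowers stress-1, making the recorded
trajectory non-increasing by construction (a non-improving step terminates
that start).

ANOSIM ranks all `M = n(n−1)/2` dissimilarities and computes
`R = (r̄_between − r̄_within)/(M/2)`, the Clarke normalization under which
two maximally separated groups give exactly R = 1. The permutation p-value
is upper-tail, `(1 + #{R_perm ≥ R_obs})/(1 + n_perm)` with 999 seeded
permutations by default; `exact=True` enumerates all distinct relabelings
(used at small n, e.g. the 20 relabelings of a 3+3 design). The R
statistic is cross-checked against scikit-bio's implementation in the test
suite.

VIF screening iteratively computes `VIF_i = 1/(1 − R_i²)` from regressing
each variable on the others, drops the largest above the cutoff
(default 10; perfectly collinear variables fall first with a warning;
alphabetical tie-break) and repeats until all pass.

RDA centers the community matrix (Hellinger transform on by default — the
standard choice for abundance data; disable via flag), regresses it on
standardized environmental variables, and takes the SVD of the fitted
values; axis variance fractions are non-increasing and constrained +
unconstrained variance equals total variance to 1e-9. Per-variable
significance uses seeded marginal permutation tests: the variable's rows
are permuted and its constrained R² recomputed (999 permutations); with no
covariate structure this equals the residual-permutation null. Variation
partitioning fits all subset RDAs over 2–3 named variable sets and applies
inclusion–exclusion on Ezekiel-adjusted R²; negative fractions are
reported as computed and flagged, never clipped. Note that adjusted R²
penalizes redundant predictors, so "unique" fractions of duplicated sets
are only approximately zero.

## Co-occurrence networks

Edges join OTU pairs with `|Spearman R| > 0.6` and `p < 0.001` (the
figure-caption thresholds; raw p-values by default, BH behind a flag),
computed on per-sample relative abundances after a prevalence filter
(present in ≥ 20 % of samples by default — all-pairs correlation on
unfiltered OTU tables is dominated by zero-inflation artifacts). Edge sign
is retained. Topology reports nodes, links, average degree, density, mean
local clustering (0 for degree < 2), average path length on the largest
component, and modularity with community count from deterministic greedy
modularity maximization.

Module *recovery* (and module assignment generally) runs community
detection on the positive-association subgraph: modularity's null model
reads an edge as affinity, while a strong negative correlation is evidence
two taxa do not co-occur — and under compositional closure distinct
abundance blocks are necessarily anti-correlated, so treating negative
edges as ties merges genuinely distinct modules. Null-model comparison
draws Erdős–Rényi G(n, m) ensembles matched on nodes and edges and reports
`z = (obs − mean_null)/sd_null` for clustering and path length plus the
small-world index `σ = (C/C_rand)/(L/L_rand)`. σ is reported as a
descriptive diagnostic only: it is known to exceed 1 even for ring
lattices (high clustering dominates), so no pass/fail claim is attached to
it, and "scale-free" behavior is likewise only exported as a degree
distribution, never tested on small graphs.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; the pipeline manifest
records the seed, a config digest and per-file checksums, and re-running
with the same config yields identical checksums. The validation studies
use: 100 seeds for index recovery (2-treatment, 2-period, 3-replicate
design), 500 simulations × 199 permutations for ANOSIM calibration, 2000
replicates for ANOVA calibration, 1000 for OLS calibration, 100 seeds for
planted-block recovery (3 blocks × 10 OTUs, ρ = 0.9, 40 samples, depth
5000), all non-isomorphic graphs on ≤ 6 nodes for the topology oracle
sweep, and 50 random fixtures for NMDS stress monotonicity — sizes chosen
so the whole suite runs in a couple of minutes on one core while keeping
Monte-Carlo error well inside the asserted bands.

## Known limitations

- Correlation-threshold networks on relative abundances inherit the usual
  compositional caveats; SparCC/SpiecEasi-style compositionally aware
  estimators are out of scope by design.
- Periods are analyzed independently (no repeated-measures or mixed
  models), matching the source analysis.
- The published ANOSIM R values and RDA variance fractions require the
  deposited raw sequencing data and are out of reproduction scope; the
  package validates those procedures on synthetic ground truth instead.
- BIOM support covers the JSON (1.0) flavor read-only; HDF5 BIOM is not
  parsed.
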