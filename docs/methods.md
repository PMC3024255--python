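# Methods

This note documents the statistical machinery behind `netpreserve`: the
statistics, the permutation null, the composite summaries, the synthetic
study generator, and the numerical and design choices that were genuinely
open.

## Networks and network concepts

A weighted network is a symmetric adjacency matrix `A` with `a_ij ∈ [0, 1]`
and `a_ii = 1`. Co-expression networks are built from a samples × nodes
matrix `X` by correlating node profiles and soft-thresholding:

* unsigned: `a_ij = |cor(x_i, x_j)|^β`, default `β = 6`;
* signed: `a_ij = ((1 + cor(x_i, x_j))/2)^β`, default `β = 12`.

The defaults are the community's usual soft-thresholding choices for the
respective network types; both are exposed (`--power`). Correlation methods:
Pearson (default), Spearman (Pearson on ranks), and biweight midcorrelation
(median/MAD-weighted with a 9-MAD outlier cutoff, falling back to Pearson
for a zero-MAD profile, with a warning).

Per-node concepts on a (sub-)network, with the diagonal excluded throughout:
connectivity `k_i = Σ_j a_ij`; maximum adjacency ratio
`MAR_i = Σ_j a_ij² / Σ_j a_ij` (constant 1 in unweighted networks, hence
informative only for weighted ones); weighted clustering coefficient
`cc_i = Σ_{j≠i} Σ_{l≠i,j} a_ij a_jl a_li / ((Σ a_ij)² − Σ a_ij²)`; density =
mean off-diagonal adjacency. Isolated nodes get NaN for MAR and cc; NaN is
the package-wide undefined marker and is skipped (and counted) by averages.

## The module eigennode

For module `q`, node profiles are standardized (mean 0, sd 1, divisor
m−1; missing entries mean-imputed per node first) and the eigennode `E` is
the leading left singular vector. Its sign is oriented so the mean
correlation with member profiles is ≥ 0 (a tie keeps the decomposition's
native sign); without a convention the sign-aware statistics would not be
reproducible across BLAS implementations. Module membership
`kME_i = cor(x_i, E)` is defined for every node in the network. The
proportion of variance explained satisfies `PVE = mean(kME²)` over members
exactly (for Pearson kME on complete data); the package computes
`propVarExplained` through this identity so its missing-value behavior
matches kME's, and the test suite keeps the spectral computation as an
independent oracle.

## Preservation statistics

With reference network/data fixed and module labels taken from the
reference side only:

**Density** (does the module stay tight?): `meanAdj`, `meanClusterCoef`,
`meanMAR` on the module's test sub-network; `meanSignAwareCorDat` — the mean
over module pairs of `sign(cor_ref) · cor_test`, so a pair whose correlation
flips sign counts against preservation; `propVarExplained` of the test
eigennode; `meanSignAwareKME` — mean of `sign(kME_ref) · kME_test` over
members.

**Connectivity** (are the same nodes hubs?): Pearson correlations, across
the module, of the vectorized upper-triangular sub-adjacencies (`cor.adj`),
sub-correlations (`cor.cor`), intramodular connectivities (`cor.kIM`),
clustering coefficients (`cor.cc`), MARs (`cor.MAR`), and module memberships
over members (`cor.kME`) or over all network nodes (`cor.kMEall`).

**Separability**: pairwise `1 − meanInterAdj(q1,q2) / √(D(q1)·D(q2))`
(adjacency version; ≤ 1, can be negative) and `1 − cor(E_q1, E_q2)`
(eigennode version). In unsigned mode the eigennode version uses `1 − |cor|`
— anti-correlated eigennodes count as connected, consistent with unsigned
adjacency logic; signed mode keeps the sign. A module's single separability
value is the minimum over all other proper modules — the most stringent
aggregation, since a module is only as distinct as its closest neighbour.
The aggregation rule and sign convention are recorded in the run metadata.

**Quality**: the density and separability statistics evaluated with the
test set equal to the reference set measure module quality in a single
network (`meanSignAwareKME` then reduces to mean |kME| automatically).

## Permutation Z statistics

The null hypothesis is "the test network carries no information about this
module". It is simulated by randomly relabeling the test network's nodes:
each replicate draws a permutation `π` of the node universe (grey nodes
included by default; configurable), keeps every module's reference node set
fixed, and evaluates the test side on the module's image under `π`, pairing
reference node `i` with test node `π(i)`. Under no preservation the observed
statistic is then *exchangeable* with its null replicates — an exact
permutation test — so `Z = (observed − μ̂)/σ̂` (σ̂ with divisor n−1) is
approximately standard normal, and one-sided p-values from the normal upper
tail are meaningful.

An alternative scheme — redefining the module's node set on *both* sides per
replicate, i.e. scoring random same-size modules — was implemented first and
rejected: whenever the test network contains structure anywhere, the
observed module keeps its coherent reference-side correlation signs while
the null modules get random ones, which inflates the sign-aware statistics
(in a fully label-permuted study, Z for `meanSignAwareCorDat` reached ≈ 40
for a module that is not preserved at all). The test-relabeling null
conditions on the reference module, which is the question actually asked.

Defaults: 100 permutations, seed 1. `nPermutations = 0` skips Z computation
and reports observed statistics only. Replicates yielding an undefined
statistic contribute missing null samples (counted); a null sd of zero (a
statistic constant under permutation, detected up to 1e−12 relative float
noise) makes Z undefined rather than infinite. With fixed seed, config and
inputs the whole run is bit-identical.

`grey` (unassigned nodes) and `gold` (a random sample of min(1000, n) nodes,
drawn once per run from the seed) are evaluated and reported, flagged
improper, and excluded from medianRank ranking. Empirical note: in a
partially preserved network the gold module legitimately shows high
*connectivity* preservation — a network-wide sample inherits the network's
preserved correlation structure — while its density preservation is nil.

## Composites, ranks, p-values

For correlation runs, `Zdensity = median(Z.meanSignAwareCorDat,
Z.propVarExplained, Z.meanSignAwareKME)`, `Zconnectivity = median(Z.cor.adj,
Z.cor.kIM, Z.cor.cor, Z.cor.kME)`, `Zsummary = (Zdensity + Zconnectivity)/2`.
For adjacency-only runs, `Zdensity.adj = Z.meanAdj`, `Zconnectivity.adj =
median(Z.cor.adj, Z.cor.kIM)`, `Zsummary.adj` their mean. Separability and
`cor.kMEall` are deliberately excluded from composites (the former often
disagrees with the other statistics, the latter is diluted by the many
non-members). Missing components are dropped from the median with a warning.

`medianRank`: for each of the seven composite-feeding statistics, proper
modules are ranked with rank 1 = largest observed value, average ranks on
ties, undefined values last; the density and connectivity rank medians are
averaged. Being built from observed values only, it is insensitive to module
size, at the price of being purely relative.

`summary_log10_p` is the median of the component statistics' log10 p-values
(a descriptive summary — `Zsummary` itself, being a median-mean hybrid, has
no usable null distribution). Bonferroni-adjusted log10 p-values (over the
number of modules tested) are emitted alongside raw ones; no other
multiplicity correction is applied. Reported evidence bands: `Zsummary > 10`
strong, `2–10` weak to moderate, `< 2` none.

## Synthetic studies

Each proper module is seeded by a latent standard-normal profile; member
`i` is `r_i·seed + √(1−r_i²)·noise` with `r_i` evenly spaced over
`[minCor, maxCor]`. Preserved modules reuse the seed and the `r` assignment
in the test set with fresh noise; non-preserved modules are independent
noise or have their membership permuted away; grey nodes are independent
noise in both sets. Scenario defaults (chosen as typical desk-scale
co-expression conditions; all overridable through `ScenarioSpec`):
100 samples per set, grey count = 25% of proper-module nodes,
membership correlations `[0.3, 0.6]` for the weak scenario and
`[0.6, 0.95]` otherwise.

* **weak / strong**: 20 × 200-node modules (half preserved) / 10 modules
  sized evenly 100–400 (modules 1–5 preserved).
* **permuted**: both sets have modules of the same sizes, but the test
  membership is globally permuted — nothing is preserved.
* **half_permuted**: modules 1–5 preserved; the test columns of modules
  6–10 are permuted among themselves.
* **intramodular_permuted**: modules 1–5 are re-simulated in the test set
  and then shuffled *within* the module — density survives, node-level
  connectivity does not (`density_only` truth).
* **pathway_small / pathway_large**: modules of 25–100 / 100–500 nodes
  assembled by sampling equally from ≥ 3 underlying clusters (4 per truth
  class by default); preserved source clusters reappear in the test set,
  non-preserved ones are permuted among themselves. Pairwise correlation
  patterns survive while module density is low (`connectivity_only` truth).
  Size grids include both endpoints exactly.

Module sizes for scenarios 2–5 (evenly spaced on [100, 400]) and the
correlation ranges are this package's own calibration of "weak" and
"strong"; they reproduce the intended qualitative behavior (strong
preservation clears `Zsummary ≥ 10`, permuted membership stays below 2,
intramodular permutation yields high density Z with near-zero connectivity
Z, pathway scenarios the converse).

The `grade_statistic` harness scores a statistic against ground truth:
grade 4 when every preserved module has `Z ≥ 10` and every non-preserved
`Z ≤ 2`; 3 when the groups separate perfectly but violate a threshold; 2
when the best separating cut misclassifies ≤ 20% of modules (ties broken
toward the stricter cut); 1 otherwise. For `medianRank` (no thresholds
exist) grade 4 means perfect rank separation, then the 2/1 rungs apply.

## What the simulations do and do not show

The generator produces Gaussian profiles, a single latent factor per module,
non-negative membership correlations, equal sample sizes, and no batch
effects, outliers, or missingness. Passing tests therefore demonstrate the
statistics' behavior under clean factor-structured data — size calibration
of the null, threshold semantics, and the density/connectivity dissociation
— not robustness to the heavy tails, nested modules or confounding of real
microarray/RNA-seq data. The bicor option exists precisely because real
data violate Gaussianity, but the simulations do not exercise it.

Null calibration is checked over 100 null modules (ten permuted-scenario
studies): per-statistic Z mean within ±0.2, sd within [0.8, 1.2], and a KS
test against N(0,1) not rejected at 0.01. Two caveats: soft-thresholding at
`β = 6` makes `cor.adj`'s observed-statistic null right-skewed for small
modules (the adjacency vector is dominated by its few largest entries), so
its Z departs from normality earlier than the other statistics as module
size shrinks; and Z values of modules within one run share permutations and
are therefore not independent.

## Numerical choices and degenerate inputs

* Pairwise-complete correlation (≥ 3 complete pairs, else NaN) in
  `compute_correlation`; the permutation engine instead mean-imputes missing
  values per node once, up front — recomputing pairwise-complete
  correlations inside every replicate would dominate the runtime, and the
  imputation is logged.
* Constant profiles: NaN correlations (with a warning), dropped from
  eigennode computation; an all-constant module raises.
* Correlations are clipped to [−1, 1] after the matrix products; adjacency
  symmetry on file input is validated to 1e−8 and then symmetrized by
  averaging; the diagonal is forced to 1.
* Vector-vector correlations inside statistics require ≥ 3 finite pairs and
  nonzero variance on both sides, else NaN.
* Modules smaller than 3 nodes are skipped with a warning and recorded in
  the run metadata; `gold` is a reserved label and rejected in user input;
  `0` and `grey` both parse as unassigned.
* All randomness flows through one `numpy.random.Generator` seeded from the
  run seed.

## Problem sizes

The bundled scenarios are desk-scale by design: ~3 000 nodes, 100 samples,
100 permutations, giving about a minute per full run on one CPU (the
reference side of every statistic is computed once and cached across
replicates; per-module work is dense linear algebra on sub-matrices). The
test suite's end-to-end checks use 50 permutations and scaled-down variants
of the scenarios where the property under test permits it.

## Known limitations

* Directed networks, topological overlap, consensus modules and module
  *detection* are out of scope; labels are inputs.
* Permutation p-values are asymptotic-normal conversions of Z, not exact
  tail counts; at extreme significance they are descriptive only.
* `Zsummary` grows with module size (more pairs, tighter nulls); use
  `medianRank` when comparing modules of very different sizes.
* The grade-3 rung of the rank-based grading rule is unreachable (there are
  no thresholds to be on the wrong side of); this mirrors the rule's
  definition rather than a gap in the implementation.
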