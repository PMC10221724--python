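# Methods

## Model and pipeline

A structural covariance network treats each cortical region as a node
and the across-subject correlation of a morphometric measure (mean
cortical thickness per Desikan–Killiany parcel) as the basis for edges.
The pipeline is group-wise: adjustment → correlation → density
thresholding → graph metrics → permutation comparison.

### Mean-thickness adjustment

"Adjusted for overall mean thickness" is implemented as per-region
ordinary-least-squares residualisation on the subject-level mean
thickness, with intercept, computed *within each group* (and within
each permuted pseudo-group — the adjustment is part of the group
pipeline, so it is recomputed inside every permutation replicate).
Residuals are exactly zero-mean and uncorrelated with the covariate.
If the covariate is constant across subjects the adjustment degrades to
mean centering, with a warning; a constant region column yields zero
residuals, with a warning.  Regression residualisation is the standard
covariate treatment in structural covariance work and the only one
computable from the stated inputs; other treatments (e.g. proportional
scaling) would be a sensitivity analysis, not the default.

### Binarization and the density grid

Edges are ranked by **signed** correlation (largest positive first),
not |r|: connectivity in thickness covariance is grounded in positive
co-variation, and negative correlations are only admitted — with a
logged warning — when the requested edge count exceeds the number of
positive entries.  The edge count at density *d* is
round-half-away-from-zero of *d·P* with *P = N(N−1)/2*.  Ties in r are
broken by lexicographic (label_i, label_j) order so that binarization
is deterministic under permutation, where exact ties can occur.  By
construction the edge set at density *d* nests inside the edge set at
any *d′ > d*.

`D_min`, the minimum density giving a single connected component, is
found by admitting ranked edges into a union–find structure until the
graph connects, then taking the smallest multiple of the resolution
(default 0.01, matching the two-decimal reporting convention) whose
rounded edge count reaches that point.  Note that with the
round-half-away rule the answer can sit one grid step below the naive
`m/P` quotient: 9 edges out of 45 are already realised at d = 0.19
because round(8.55) = 9.

The contrast grid runs from max(D_min_a, D_min_b) upward in steps of
0.05 while ≤ 0.5 (beyond half density such graphs approach random
configurations).  The endpoint 0.5 is included only when the step
arithmetic hits it exactly — e.g. a lower bound of 0.17 ends at 0.47,
and 0.11 ends at 0.46.

### Graph metrics

All metrics operate on dense binary adjacency matrices:

* degree: row sums;
* nodal clustering: `2·t_i / (k_i(k_i−1))` with triangle counts from
  `((A·A)∘A)·1`, defined 0 for degree < 2; global clustering is the
  arithmetic mean over all nodes;
* characteristic path length L: BFS distances
  (`scipy.sparse.csgraph`), averaging **finite** pairwise distances
  only — unreachable pairs are excluded and surfaced as a count.
  Permutation replicates thresholded at a contrast grid anchored on the
  *observed* groups can fragment, and this convention (common in
  brain-connectivity toolboxes) keeps L finite while making
  fragmentation visible in every result;
* global efficiency: mean of 1/d over pairs with 1/∞ = 0 (handles
  disconnection natively);
* local efficiency of node i: global efficiency of the subgraph induced
  by i's neighbours (i excluded), 0 for degree < 2;
* small-worldness σ = (CC/⟨CC_rand⟩)/(L/⟨L_rand⟩) against
  degree-preserving Maslov–Sneppen rewired nulls (networkx
  `double_edge_swap`), default 20 nulls with a budget of 10·|E|
  accepted swaps; if the try budget is exhausted the achieved
  randomisation is used and logged.  σ requires a connected graph by
  default; the permutation engine relaxes this (finite-distance L) for
  fragmented replicates.

The implementation is hand-vectorised because the permutation test
recomputes these quantities on the order of 10⁵ times per analysis;
networkx serves as an independent cross-check in the test suite, next
to brute-force oracles (double-loop degree, O(N³) triangle enumeration,
Floyd–Warshall distances).

### Permutation/FDA comparison

The functional statistic is the trapezoidal integral of the
between-group metric difference over the density grid divided by the
grid span — the mean functional difference.  The normalisation makes
statistics comparable across contrasts whose grids differ in span; a
degenerate single-point grid reduces to the plain difference.  The
permutation scheme reassigns whole subjects (regional vector plus
mean-thickness covariate) without replacement, preserving group sizes,
and recomputes adjustment, correlation, binarization at every grid
density, and the metric curve per pseudo-group.  The two-tailed p-value
uses the add-one estimator `p = (1 + #{|null| ≥ |obs|})/(n_perm + 1)`,
so p ∈ (0, 1] and ties at zero observed difference give p = 1.
Permutations run in a canonical label-sorted orientation, so reversing
a contrast negates the statistic and leaves p exactly unchanged.  The
density grid is fixed from the observed groups and not re-estimated per
replicate (the same thresholding procedure is applied to every
randomised group).

Nodal metrics are tested per node with the same permutations; they are
corrected across densities by construction (the statistic integrates
the range) but **not** across the 68 nodes by default, mirroring common
reporting practice; `node_fdr=True` applies Benjamini–Hochberg across
nodes for users who want it.

### Demographic-table statistics

`cohort_stats` recomputes one-way ANOVA and two-sample t statistics
from printed group moments (n, mean, sd).  The pooled-variance t is
used because the degrees of freedom such tables print
(n_a + n_b − 2) identify the pooled test.  The chi-square of
independence uses no continuity correction.

## Synthetic cohorts: what they emulate and what they do not

The generator draws subject × region thickness as

    y_ij = baseline_j + g_sd · G_i + noise_sd · s_ij

with `G_i` a shared standard-normal global factor and `s` a
unit-variance factor model whose correlation is block-constant:
`rho_within` inside modules, `rho_between` across them (PSD guaranteed
when rho_between ≤ rho_within).  Group effects multiply `rho_within`,
so a multiplier below 1 de-segregates that group's network.  The block
model is the minimal structure that lets segregation effects be
injected and recovered; defaults are

| parameter | default | rationale |
|---|---|---|
| n_subjects_per_group | 21 | target study design |
| n_regions | 68 | Desikan–Killiany cortex |
| modules | 4 contiguous blocks of 17 | lobe-like community scale |
| rho_within / rho_between | 0.5 / 0.15 | strong but not saturated modular covariance, typical of thickness data |
| baseline_mean | 2.5 mm | adult cortical thickness scale |
| noise_sd | 0.12 mm | inter-subject regional variability |
| global_factor_sd | 0.08 mm | shared global-thickness variance for the adjustment to remove |

The generator does **not** emulate spatial autocorrelation on the
cortical sheet, hemispheric asymmetries, region-specific means and
variances, segmentation error, or site/scanner effects.  Passing tests
therefore demonstrate the statistical machinery (calibration, recovery,
determinism) under the assumed covariance model — not that any
particular real dataset would yield a given topology.

## Validation experiments

* **Type-I calibration**: 200 independent null datasets (two groups of
  21 from one configuration), 99 permutations each; the empirical
  rejection rate of the global-clustering test at α = 0.05 is checked
  against [0.03, 0.08] and the null p-value distribution against
  uniformity.  99 permutations per dataset keeps the 200-dataset run in
  tens of seconds while the add-one estimator remains valid.
* **Recovery**: 20 replicates with one group's within-module
  correlation halved, 199 permutations; detection rate and sign
  agreement of the observed statistic are reported.
* **Determinism**: two executions of one seeded run configuration must
  be byte-identical across every output file.  All randomness descends
  from a single root seed through named `SeedSequence` substreams
  (cohort, permutation, rewiring), and the manifest records enough to
  reproduce a run.

## Numerical choices and edge cases

* Correlations are clipped to [−1, 1] and symmetrised after
  `np.corrcoef`; zero-variance regions get zero rows/columns with a
  warning.
* Metric curves require finite values; fragmented replicates keep L
  finite via the finite-distance convention.
* Degenerate hooks used in testing: the σ null model can be replaced by
  the identity (σ = 1 exactly), and the FDA statistic of identical
  curves is exactly 0.
* Adjacency matrices are validated (symmetry, binary, zero diagonal,
  stated density) at construction.

## Known limitations

* Weighted-network analysis is out of scope; only binary matrices are
  analysed.
* The σ permutation test is expensive (nulls × densities × replicates);
  `sigma_n_null` and `include_sigma` exist to scale it, and the
  reported experiments use the cheaper global clustering metric.
* Nodal tests default to no across-node correction (see above); users
  scanning many contrasts should enable `node_fdr`.
* The minimum-density search assumes all node pairs are rankable; with
  massive ties the lexicographic tie-break makes the result
  deterministic but label-order dependent.
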