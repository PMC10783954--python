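# Methods

## Model and procedure

`mipath` scores the association between a pathway's *sample-module
structure* and a discrete phenotype. The pipeline per pathway:

1. restrict the samples × genes matrix to the pathway's genes (exact,
   case-sensitive identifier match; genes absent from the matrix are
   ignored and the count used is reported);
2. z-score each gene (population SD; zero-variance genes become all-zero
   columns and drop out of the distances);
3. build a directed kNN graph under Euclidean distance in that subspace;
4. weight each edge (i, j) by shared-nearest-neighbor similarity
   `|N(i) ∩ N(j)| / k`, obtained from `B = A·Aᵀ`;
5. partition the samples by Leiden optimization of directed weighted
   modularity;
6. score the partition against the phenotype with adjusted mutual
   information (AMI), optionally conditioned on a confounder; attach a
   permutation p-value and, across pathways, Storey q-values and
   tied-average ranks on AMI descending.

The only modelling assumption is that samples cluster differently in
different gene subspaces; no functional form links expression to phenotype.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 25 | neighbors per sample; trades local for global structure. Values well below the within-group sample count fragment groups into sub-modules (lowering AMI without reordering pathways); values approaching group size blur groups. |
| `n_permutations` | 10 000 | size of the empirical null; 0 disables p-values. p = (1+b)/(1+B) never returns 0. |
| `min_pathway_genes` | 5 | pathways matching fewer genes are reported as skipped: kNN in a ≤4-dimensional noisy subspace is unstable. |
| `resolution` | 1.0 | modularity resolution; 1.0 is the classic objective. |
| `normalization` | zscore | per-gene standardization before distances. |
| `neighbor_mode` | auto | exact brute-force ≤ 2000 samples, seeded NN-descent above. |

Seeds: every pathway derives its own 31-bit seed from the master seed and
the pathway name (BLAKE2b), so results are independent of pathway iteration
order and of any parallel scheduling.

## Information-theoretic details

MI is computed from the empirical contingency table in nats; the
KL-divergence form and the entropy form H(X)+H(Y)−H(X,Y) agree to 1e-12 and
both are exercised in tests. Normalization uses maxMI = ½(H(X)+H(Y)), the
attainable maximum for partitions. E[MI] under random labelings with fixed
margins is the exact finite sum over each cell's hypergeometric support
(starting at max(a_i+b_j−n, 1); the zero cell contributes nothing),
evaluated with log-factorials. AMI = (MI − E[MI])/(maxMI − E[MI]); when the
denominator vanishes (e.g. both partitions constant) no association is
detectable and the score is defined as 0. Natural log is an internal
convention only — NMI and AMI are base-invariant.

**Conditional scores.** MI(X,Y|Z) stratifies the data:
Σ_z p(z)·MI(X,Y|z), with maxMI(X,Y|Z) = ½(H(X|Z)+H(Y|Z)). For the expected
value we adopt the stratified construction E[MI|Z] = Σ_z p(z)·E[MI] on the
within-stratum margins — the direct analogue of the conditional MI
decomposition; this is an interpretation (a design choice of this package)
rather than a transcription of a published derivation. Strata of size 1
contribute zero to every term. Conditional permutation tests shuffle
phenotype labels within confounder strata, preserving Pr(Y|Z).

**Var(MI)** is provided as an exhaustive-enumeration oracle for n ≤ 9 (all
distinct arrangements of the label multiset are equiprobable under the
permutation null). The analytic route through E[MI²] is numerically
delicate, and the permutation test supersedes it in practice.

**Storey q-values.** π0 is estimated from the p-value distribution over a
λ grid {0.05, …, 0.95} with a cubic smoothing spline evaluated at λ = 0.95,
falling back to the λ = 0.5 point estimate below 100 p-values, clipped to
(0, 1]; an explicit `pi0` argument overrides the estimate. q_i is the
step-up minimum of π0·m·p_j/rank_j over p_j ≥ p_i, clipped to [0, 1].

## Graph and clustering choices

- A sample is never its own neighbor; self-edges would add a constant to
  every SNN weight.
- Distance ties at the k-th neighbor break toward the smaller sample index
  (stable sort), making exact mode fully deterministic.
- SNN weights exist only on kNN edges; zero-overlap edges are kept with an
  explicit weight 0 so the out-degree-k invariant stays testable (zero
  weights do not affect modularity).
- Modularity uses total edge weight for m, the convention of the Louvain /
  Leiden literature, and the directed variant with weighted in-/out-degrees;
  the graph is passed to the optimizer as directed.
- The optimizer is leidenalg's RBConfiguration partition (resolution 1.0 =
  modularity), seeded; the contract is the objective and seed
  reproducibility, not the code path. If the optimizer ever returns a
  partition below the Q = 0 one-community baseline, the baseline is
  returned; a graph with zero total edge weight yields singleton modules.
- Labels are canonicalized to 0..G−1 by first appearance, so any relabeling
  of the optimizer's raw output maps to the same partition.

## Synthetic data

The generator emulates the structure the method assumes, not real scRNA-seq
count distributions. Signal genes are Gaussian with per-(gene, group) mean
offsets drawn N(0, 1) and scaled by `effect_size` (so effects are in
within-group SD units); noise genes are standard normal; decoy pathways
draw size-matched gene sets from the noise genes (without replacement per
pathway, with replacement across pathways). Dropout zeroes entries
independently at the given rate. The confounded variant drives a separate
gene block from Z and couples the phenotype to Z with probability
`coupling` (default 0.9), leaving the block conditionally independent of
the phenotype given Z — the signature case for conditional scoring;
`coupling=0` is the no-confounding control. Defaults (1000 samples, two
equal groups, 20 signal genes at 2 SD, 500 noise genes, 50 decoys, no
dropout) are the package's standard planted-signal benchmark.

What passing tests on this generator do **not** show: robustness to
library-size variation, UMI count noise, batch effects beyond the single
confounder block, or correlated gene-gene structure within pathways.

## Benchmark problem sizes

The statistical suites run at sizes chosen to make their expected behavior
sharp while staying desk-scale: expected-MI oracle equivalence over all 917
margin configurations with n ≤ 8 (tolerance 1e-10); type-I calibration over
200 null pipelines of 150 samples at 199 permutations (binomial 95% CI
around α = 0.05); planted-signal recovery at n = 1000 with 50 decoys over
20 seeds (rank 1 in ≥ 19); subsample reproducibility on n = 2000 with ten
20% subsamples (mean pairwise Pearson r ≥ 0.9); k-stability at
k ∈ {15, 25, 40} (rank ≤ 3). The effect-size monotonicity check uses k = 40
at 300 samples so that strong effects saturate at AMI 1 instead of
fragmenting groups into sub-modules (see the `k` note above).

## Known limitations

- Only discrete phenotypes: continuous variables (age, survival) must be
  pre-discretized into quantiles by the user.
- Module detection needs enough samples per biological state for the kNN
  graph to resolve it; very small datasets give unstable partitions.
- The AMI chance adjustment assumes the fixed-margin permutation model;
  structured nulls (e.g. batch-driven) are only addressed through explicit
  conditioning.
- Gene identifiers are matched exactly; no cross-namespace mapping.
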