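# Methods

## Problem and overall procedure

`smrt` discovers patient subtypes from one or more omics layers (mRNA,
DNA methylation, miRNA, copy number, ...), each a samples x features matrix,
optionally scoring the result against survival data. The procedure is:

1. **Split.** Patients present in *every* layer form the candidate pool for
   the *sampled set*; at most `max_sampled` (default 2,000) of them are drawn
   uniformly at random. Everyone else — patients beyond the threshold or
   missing from some layer — forms the *propagated set*. When the cohort is
   small and fully matched, the propagated set is empty and the pipeline is
   a direct clustering.
2. **Reduce.** Each layer, restricted to the sampled rows, is mean-centered
   per feature and decomposed with a randomized SVD (Gaussian projection,
   QR range finding with power iterations, small exact SVD). The retained
   rank is the smallest explaining 90% of the computed squared-spectrum
   energy, capped at 100. Scores are `X' = (X - mean) V`.
3. **Cluster per layer.** Perturbation clustering: for each candidate k
   (2..10), k-means (10 restarts) partitions the unperturbed scores, giving
   a binary co-clustering ("connectivity") matrix; the scores are then
   perturbed `n_perturb` times (default 50) with i.i.d. Gaussian noise and
   re-clustered, and the binary connectivity matrices are averaged. The
   *stability* of k is `1 - mean |original - averaged|` over off-diagonal
   pairs; the most stable k wins. An exact stability tie resolves to the
   *larger* k. This matters in the strong-separation regime: merging two
   true classes at a too-small k can itself be perfectly stable (whenever
   class-size imbalance makes the same merge win in every replicate), so
   both the true k and smaller k can sit at stability 1 exactly; splitting
   a homogeneous cluster, by contrast, is never perfectly stable because
   the split plane flips under noise. The finest maximally stable
   partition is therefore the structure-revealing one, and the rule cannot
   inflate k on noise-only data, where no k is perfectly stable and the
   argmax is unique.
4. **Integrate.** Per-layer averaged connectivity matrices are merged by an
   unweighted entrywise mean into one similarity matrix S. Candidate final
   partitions come from average-linkage hierarchical cuts of distance
   `1 - S` at each k, partitioning around medoids at each k, and one
   adaptive dendrogram cut; the candidate with the highest mean adjusted
   Rand index (ARI) against the per-layer partitions is selected (ties:
   fewer clusters, then hierarchical < medoid < adaptive cut).
5. **Propagate.** Each propagated patient is projected into every layer's
   component space with the rotation fitted on the sampled set, and
   classified per layer by k-nearest-neighbor vote counting among the
   sampled patients (Euclidean distance in component space). The
   neighborhood size is chosen per layer by 5-fold cross-validated
   misclassification rate on the sampled set over k = 5..50 (argmin,
   smallest k on ties). Per-layer subtype probabilities (vote fractions)
   are averaged over the layers in which the patient appears; the argmax
   (lowest subtype index on ties) is the final label. A patient present in
   a single layer is classified from that layer alone, which is how
   unmatched data types are handled.

Connectivity and similarity matrices are only ever allocated over the
sampled set, so memory grows quadratically in `max_sampled`, never in the
cohort size. The kNN search and the projection of propagated samples are
processed in row blocks for the same reason.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `max_sampled` | 2000 | size cap of the directly clustered set; balances accuracy against the quadratic connectivity cost. Results are insensitive to it (see threshold-invariance test). |
| `k_min`, `k_max` | 2, 10 | cluster-number search range. |
| `n_perturb` | 50 | perturbation replicates per k; the connectivity average and hence the stability estimate sharpen with more replicates. |
| `noise_sd` | median feature-wise sd of the reduced scores | perturbation scale; auto value tracks the data's own noise floor. Overridable — for data whose feature sds are dominated by between-cluster separation, the within-cluster scale is the better choice. |
| `var_threshold`, `max_rank` | 0.9, 100 | retained-variance rank policy for the randomized SVD. |
| `oversample`, `power_iters` | 10, 2 | randomized range-finder accuracy knobs; each power iteration is followed by a QR re-orthogonalization for numerical stability. |
| `knn_k_min..knn_k_max`, `folds` | 5..50, 5 | cross-validation grid for the propagation neighborhood (grid truncated to the training-fold size minus one). |
| `seed` | 0 | master seed; every stage draws child seeds from it, so runs are bit-reproducible and invariant to scheduling. |

## Synthetic data

`simulate_multiomics` emulates a multi-layer cohort with planted subtypes:
a Gaussian background (sd `noise_sd`, default 1) in which each of
`n_classes` (default 3) balanced classes up-regulates its own disjoint
block of `n_markers` (default 100) features by `shift` (default 2)
background standard deviations, identically structured across `n_layers`
layers (default 2) of `m` features (default 5,000) with shared labels.
An add-on draws exponential survival times with class-specific hazards
under uniform censoring.

What it does *not* emulate: real platform marginals (methylation beta
values, count overdispersion), feature correlation, batch effects, class
imbalance, or class-specific missingness. Passing the recovery tests shows
the machinery is correct and calibrated under the planted model, not that
any particular cancer cohort will yield survival-distinct subtypes.

## Numerical choices and edge cases

- **Centering.** Features are mean-centered before decomposition (PCA
  convention); no variance scaling. Projection of new samples subtracts the
  *fitting-set* means.
- **Rank selection from a truncated spectrum.** The variance threshold is
  applied to the spectrum actually computed (capped at `max_rank`), since
  the full spectrum is never formed.
- **Hierarchical candidates** use `cut_tree`, which cuts between merges and
  therefore returns exactly k non-empty clusters even when merge heights
  tie (an all-equal-distance matrix is the degenerate case).
- **Medoid partitioning** is a seeded Voronoi-style PAM on the precomputed
  `1 - S` distances: maxmin initialization, alternating assignment and
  within-cluster medoid updates; empty clusters are rescued with the
  worst-fit point.
- **Adaptive dendrogram cut**: a deliberately simple variant of dynamic
  branch cutting — a static cut just below the top joins (99% of the
  maximum merge height) lets the branch count emerge from tree shape, after
  which branches smaller than 5 are dissolved into the nearest branch by
  average distance. A single-cluster outcome is retained as a candidate but
  scores ARI 0, so it cannot beat any informative candidate.
- **Ties.** Stability ties break to the largest k (see above); ensemble ties to fewer
  clusters then algorithm order; kNN distance ties to reference order
  (stable sort); vote ties to the lowest subtype index; CV-error ties to
  the smallest neighborhood. All deterministic.
- **Degenerate inputs.** Layers with missing/non-finite cells, duplicate
  ids, or fewer than 2 samples are rejected at load; all-identical rows are
  rejected by the clustering with a zero-variance error; an all-zero
  spectrum fails rank selection; all-censored survival data fails the Cox
  test.
- **Randomized-SVD accuracy.** Oracle-equivalence tests use random matrices
  with geometrically decaying spectra. On a flat i.i.d.-noise spectrum no
  truncated range finder can pin the top singular values to fine relative
  error — the error is governed by the spectral tail ratio — whereas in the
  decaying (correlated-features) regime the method targets, agreement with
  a full SVD is at machine-precision level.

## Evaluation statistics

Survival difference is the likelihood-ratio p-value of a Cox proportional-
hazards fit with subtype membership dummy-coded against the largest
subtype. Under equal hazards the empirical type-I error at alpha = 0.05 is
verified to sit within 0.05 +/- 0.03 (50 simulations of 200 patients).
Partition agreement uses ARI (chance-corrected) and NMI (arithmetic-mean
normalization; a zero-entropy labeling scores 0 against a non-constant
one). The bundled 39-cohort x 9-method Cox p-value table supports the
significance-count summaries and a pooled one-tailed rank-sum comparison of
one method's p-values against all others. The pooled construction is one of
two defensible readings (the other being a paired signed-rank across
cohorts); the pooled form is implemented and reported as such.

## Problem sizes used in the checks

The shipped checks run at desk scale, chosen to finish on a single CPU
while keeping every contrast far from its decision boundary: cluster-number
recovery at n = 300 (20 seeds, single layer, 5,000 features), the
propagation path at n = 5,000 with 2,000 features and two layers (run at
thresholds 2,000 and 1,000 for the invariance check), and a completion
smoke run at n = 50,000 x 5,000 with a reduced search budget (rank cap 20,
10 perturbation replicates, k <= 4) under the quadratic-memory contract.

## Known limitations

- Dense matrices only; no sparse or out-of-core decomposition.
- k-means is the only built-in base clusterer for the perturbation stage
  (the interface accepts the reduced scores, so alternatives are easy to
  add but untested).
- The adaptive dendrogram cut is a simplification of full dynamic branch
  cutting; it contributes one candidate to an ensemble in which the two
  exhaustive-k algorithms dominate in practice.
- The largest-k rule for exact stability ties assumes over-segmentation is
  never perfectly stable; data with exactly duplicated groups of samples
  (where splits between duplicates are degenerate) could in principle
  escalate k, though k-means tie-handling makes this contrived in practice.
- Exact kNN search only; no approximate index.
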