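# smrt — scalable multi-omics subtyping

`smrt` partitions cancer patients into molecular subtypes from multi-omics
data (mRNA, DNA methylation, miRNA, copy number, ...), scaling to cohorts of
tens of thousands of samples on a laptop. It is aimed at computational
biologists who have one samples x features matrix per platform and want
subtypes that are consistent across platforms and, ideally, prognostic.

## Method

For each omics layer *X* (n samples x m features, mean-centered), a
randomized SVD estimates the top right singular vectors *V*: draw a Gaussian
projection *P*, orthogonalize *Z = XP* by QR, take the exact SVD of the small
matrix *Y = QᵀX*, and keep scores *X′ = XV*. Each reduced layer is then
clustered by **perturbation clustering**: for every candidate number of
clusters k, k-means on the unperturbed scores gives a binary co-clustering
(connectivity) matrix *C(k)*; re-clustering many Gaussian-noise perturbations
of the scores gives an averaged connectivity *C̄(k)*; the stability

&nbsp;&nbsp;&nbsp;&nbsp;stab(k) = 1 − mean₍i≠j₎ |C(k)ᵢⱼ − C̄(k)ᵢⱼ|

is maximized over k. The per-layer averaged connectivities are merged
entrywise into one patient-similarity matrix *S*, and the final partition is
the ensemble candidate — average-linkage hierarchical cuts, partitioning
around medoids, or an adaptive dendrogram cut of distance 1 − *S* — that
maximizes the mean adjusted Rand index with the per-layer partitions.

Connectivity matrices cost O(n²) memory, so beyond a threshold (default
2,000) only a *sampled set* of patients present in every layer is clustered
directly. Every remaining patient is projected into the sampled set's
component space and classified per layer by k-nearest-neighbor vote counting
(neighborhood size chosen by 5-fold cross-validation over k = 5..50), with
per-layer subtype probabilities averaged and the argmax taken. This same
mechanism handles layers with unequal sample sets and unmatched patients.

Subtype quality can be scored against survival with a Cox proportional-
hazards likelihood-ratio test. See `docs/methods.md` for assumptions,
parameter details, and numerical choices.

## Worked example

```python
import smrt

# two synthetic omics layers, 300 patients, 3 planted classes whose marker
# genes are shifted by 2 background standard deviations
sim = smrt.simulate_multiomics(n=300, m=2000, n_layers=2, shift=2.0, seed=7)
surv = smrt.simulate_survival(sim, rate_ratio=3.0, seed=8)

result = smrt.subtype(sim.dataset, smrt.SmrtParams(seed=42))
print("subtypes found:", result.final_labels.max())
for name, part in result.per_type_partitions.items():
    print(f"  {name}: k={part.k} stability={part.stability:.3f}")
print("ARI vs ground truth:", round(smrt.agreement(result.final_labels, sim.true_labels), 3))
print("Cox LR p-value:", f"{smrt.survival_pvalue(result.final_labels, surv):.3g}")
```

prints

```
subtypes found: 3
  layer1: k=3 stability=1.000
  layer2: k=3 stability=1.000
ARI vs ground truth: 1.0
Cox LR p-value: 3.01e-33
```

Both layers independently select three clusters with perfect perturbation
stability, the integrated labels match the planted classes exactly
(ARI = 1), and — because the survival generator gave each class a 3-fold
hazard ratio — the subtypes separate survival overwhelmingly.

The same workflow is available from the shell:

```sh
smrt simulate --n 300 --m 2000 --layers 2 --shift 2 --rate-ratio 3 --seed 7 --out data/
smrt subtype --data mRNA=data/layer1.csv --data meth=data/layer2.csv \
             --survival data/survival.csv --out run/ --seed 42
smrt evaluate --labels run/subtypes.csv --survival data/survival.csv
```

Input matrices are CSV with sample ids in the first column and feature ids
in the header row; survival tables have columns `id,time,event`.

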