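# atlaskit

Statistical procedures for tissue immune-atlas analysis: single-cell QC
and marker testing, cluster-level doublet flagging, penalized-multinomial
cell-type label transfer with outlier-based significance calling, gene-set
scoring, receptor–ligand permutation testing, spatial-transcriptomics
colocalization, and bulk deconvolution with survival stratification — plus
a synthetic-data generator that emulates the structure all of these stages
assume, so the entire pipeline can be exercised and validated without
access to restricted patient data.

## Who this is for

Computational biologists analysing droplet single-cell RNA-seq of solid
tissue (e.g. tumour/normal biopsy pairs) alongside spatial transcriptomics
and bulk expression cohorts with survival annotations, who want the
bespoke statistical steps of that kind of study as tested, reusable
library functions rather than one-off scripts.

## The statistics at the core

* **Cluster-level doublet flagging.** Per-cluster median doublet score
  `m_k`; robust z `z_k = (m_k − median(m)) / (1.4826·MAD(m) + ε)` referred
  one-tailed to t(K−1); BH correction; clusters flagged at q < 0.1.
* **Cell-type similarity / label transfer.** Ridge multinomial regression
  minimizing `(1/N)·NLL + (λ/2)‖B‖²` with 10-fold CV over a 50-point λ
  grid, **one-SE** penalty selection (`lambda.1se`), probabilities averaged
  over 50 refits with reshuffled folds; per (query cluster, reference
  class) the median probability enters the same MAD-outlier test, and a
  pair is significant when BH q < 0.05 **and** median probability > 50%.
* **Gene-set scores.** Bin-matched control module score (mean over set
  genes minus mean over expression-matched controls) and the
  recovery-curve AUC score (normalized area of the cumulative count of set
  genes among each cell's top 5% ranked genes).
* **Receptor–ligand testing.** For ordered cluster pair (A, B) and gene
  pair (L, R): score `= (mean_A L + mean_B R)/2`, reported only when both
  partners are expressed in ≥ 30% of their cluster's cells; p-value from
  1000 seeded label permutations, `p = (1 + #{null ≥ obs})/(n_perm + 1)`.
* **Spatial colocalization.** Pearson correlation between a feature and a
  spot-level cell-type score within each spot's k = 5 nearest-neighbor
  neighborhood, averaged over neighborhoods (all-zero / constant
  neighborhoods excluded; positive-only masking applies to maps, not the
  statistic).
* **Deconvolution + survival.** Per-sample NNLS against single-cell
  reference signatures, top/bottom-quartile stratification of a chosen
  cell type's proportion, Kaplan-Meier product-limit curves, and the
  two-group log-rank test `(Σ(O−E))²/ΣV ~ χ²(1)`.

See `docs/methods.md` for assumptions, parameter defaults and what the
synthetic generators do and do not emulate.

## Worked example

```python
from atlaskit import (AtlasConfig, CohortConfig, flag_doublet_clusters,
                      logrank_test, nnls_deconvolve, simulate_atlas,
                      simulate_cohort, stratify_quartiles)
from atlaskit.synthetic import cluster_profiles

atlas = simulate_atlas(AtlasConfig(seed=0))   # 5 clusters + planted doublets

calls = flag_doublet_clusters(atlas.obs["doublet_score"],
                              atlas.obs["cluster"], alpha=0.1)
print(calls.clusters.round(4))
```

```
           median_score  robust_z       p       q  flagged
cluster
cluster_0        0.1788   -0.2413  0.5905  0.8093    False
cluster_1        0.1727   -0.7123  0.7459  0.8093    False
cluster_2        0.1902    0.6367  0.2762  0.8093    False
cluster_3        0.1695   -0.9596  0.8093  0.8093    False
cluster_4        0.1851    0.2413  0.4095  0.8093    False
doublet          0.8098   48.3827  0.0000  0.0000     True
```

The five genuine clusters have statistically indistinguishable median
doublet scores (~0.18); the planted doublet cluster's median of 0.81 is an
extreme upper outlier (the MAD of the medians is tiny, so its robust z is
huge) and is the only cluster flagged at BH q < 0.1.

Continuing to the bulk survival arm — deconvolve a synthetic 400-sample
cohort against the atlas profiles, stratify by one cell type's estimated
proportion, and test the strata:

```python
profiles = cluster_profiles(atlas)
cohort = simulate_cohort(CohortConfig(seed=0), atlas)   # hazard tied to cluster_0
props = nnls_deconvolve(cohort.expression, profiles.T).proportions
groups = stratify_quartiles(props["cluster_0"])
m = groups != "excluded"
chi2, p = logrank_test(cohort.survival["time"][m], cohort.survival["event"][m],
                       groups[m])
print(f"log-rank chi2 = {chi2:.2f}, p = {p:.3g}")
```

```
log-rank chi2 = 17.16, p = 3.43e-05
```

100 samples land in each quartile stratum, and the planted hazard ratio of
2 between high and low deconvolved `cluster_0` proportion is detected
decisively.

An `atlaskit` command-line interface wraps the same functions
(`atlaskit simulate atlas`, `atlaskit qc`, `atlaskit doublets`,
`atlaskit transfer`, `atlaskit score`, `atlaskit interactions`,
`atlaskit spatialcorr`, `atlaskit survival`); all data travel as
Matrix Market + TSV sidecars or CSV.

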