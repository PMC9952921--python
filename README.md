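# dlonmf

Dual-Laplacian orthogonal non-negative matrix factorization (DL-ONMF) for
unsupervised subtype discovery in gene-expression data.

## The problem

Disease cohorts are often heterogeneous: patients measured on the same gene
panel can belong to molecular subtypes with different biology and prognosis —
for example, kidney-transplant recipients after renal ischemia-reperfusion
injury profiled on a pyroptosis-related gene panel. Plain non-negative matrix
factorization (NMF) finds a low-dimensional, parts-based representation of
such data but ignores two kinds of prior structure: the connectivity among
samples and among genes, and the redundancy between factors. `dlonmf`
implements a graph-regularized, orthogonality-constrained NMF that uses both,
plus everything needed to run it end to end: matrix I/O, kNN-graph
construction, rank and hyperparameter selection, spectral clustering of the
embedding with silhouette-based choice of the cluster number, baselines for
comparison, and a two-group differential screen for the resulting subtypes.

It is aimed at computational biologists who want a graph-aware factorization
they can validate on synthetic data with known ground truth before applying
it to a real cohort.

## The model

Given a non-negative expression matrix X ∈ R^{m×n} (m genes, n samples),
DL-ONMF seeks non-negative U ∈ R^{m×k} (gene loadings) and V ∈ R^{k×n}
(sample embedding) minimizing

```
‖X − UV‖²_F  +  λ₁‖V‖²_F + λ₂‖U‖²_F
             +  γ₁ Tr(UᵀL_u U) + γ₂ Tr(V L_v Vᵀ)
             +  β₁‖UᵀU − I‖²_F + β₂‖VVᵀ − I‖²_F      s.t.  U, V ≥ 0
```

where L_u = D_u − S_u and L_v = D_v − S_v are graph Laplacians of symmetric
kNN affinity graphs over the genes (m×m) and samples (n×n). The ridge terms
control factor growth, the Laplacian terms pull connected genes/samples
toward similar representations, and the orthogonality terms suppress
redundant factors. Optimization is by KKT-derived multiplicative updates
(see `docs/methods.md`), which preserve non-negativity by construction and
reduce exactly to the classical Lee–Seung NMF rules when all six weights
are zero.

Model selection follows a two-stage protocol: the rank k is scanned (default
1–5) and chosen by reconstruction quality — the Pearson correlation
PCC(X, UV) over matrix entries, with the squared Frobenius error
‖X − UV‖²_F as the companion metric — then the six weights are grid-searched
over a shared value set (default [0.001, 0.01, 0.1, 1], 4096 combinations,
seeded subsampling available). Samples are clustered in the V embedding by
normalized-cut spectral clustering; the cluster number (default candidates
2–5) is the one maximizing the mean silhouette
s(i) = (b(i) − a(i)) / max{a(i), b(i)}.

## Worked example

The built-in generator plants known subtype structure so every step can be
checked against ground truth. The `cohort` preset is a 110-gene × 451-sample
matrix with two planted subtypes and rank-5 signal:

```bash
dlonmf simulate --preset cohort --seed 7 --out data/
dlonmf fit --input data/X.tsv -k 5 --seed 7 --out fit/
dlonmf cluster --coefficients fit/V.tsv --clusters 2:5 --seed 7 --out clusters/
dlonmf diffexp --input data/X.tsv --labels clusters/labels.tsv --out de.tsv
```

prints

```
wrote 110x451 dataset to data/
fitted k=5 in 100 iterations; final objective 7431.83 (fit term 3219.88)
c=2: mean silhouette 0.5472
c=3: mean silhouette 0.4837
c=4: mean silhouette 0.3857
c=5: mean silhouette 0.2977
selected c=2 clusters (mean silhouette 0.5472); wrote clusters
110 of 110 genes significant at alpha=0.05 (welch-t)
```

Reading the output: the fit ran the default 100 multiplicative updates; the
silhouette is maximized at two clusters, recovering the planted subtype
count; and because every gene loads some factor whose weight differs between
the planted subtypes, the Welch-t screen at p < 0.05 flags all 110 genes
(`clusters/labels.tsv` matches the generator's `data/truth_labels.tsv`
exactly — adjusted Rand index 1.0). The same pipeline is available as a
library (`generate_planted`, `laplacian_pair_for`, `fit_dlonmf`,
`choose_cluster_number`, `differential_expression`, ...), and
`dlonmf select` / `dlonmf benchmark` expose rank/weight selection and the
NMF / K-means comparison.

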