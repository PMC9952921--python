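# Methods

## Objective and derivation of the updates

DL-ONMF minimizes, over U ∈ R^{m×k} ≥ 0 and V ∈ R^{k×n} ≥ 0,

```
Γ(U, V) = ‖X − UV‖²_F + λ₁‖V‖²_F + λ₂‖U‖²_F
        + γ₁ Tr(UᵀL_u U) + γ₂ Tr(V L_v Vᵀ)
        + β₁‖UᵀU − I_k‖²_F + β₂‖VVᵀ − I_k‖²_F .
```

Internally the ridge weights are named by the matrix they act on
(`lambda_u` on ‖U‖²_F, `lambda_v` on ‖V‖²_F) to avoid any ambiguity about
which subscript belongs where. The orthogonality penalties are the standard
orthogonal-NMF column penalties ‖UᵀU − I_k‖²_F; the alternative m×m form
‖UUᵀ − I_m‖²_F is unsatisfiable for k < m, and both forms have the identical
gradient 4(UUᵀU − U), so the choice affects only the reported penalty value,
never the optimization path.

The unconstrained gradients are

```
∂Γ/∂U = −2XVᵀ + 2UVVᵀ + 2λ_u U + 2γ₁ L_u U + 4β₁(UUᵀU − U)
∂Γ/∂V = −2UᵀX + 2UᵀUV + 2λ_v V + 2γ₂ V L_v + 4β₂(VVᵀV − V) .
```

Applying the KKT conditions for the non-negativity constraints and splitting
each gradient into its non-negative positive and negative parts — the
Laplacian splits as L = D − S with D, S ≥ 0 — gives the multiplicative rules

```
U ← U ⊙ (XVᵀ + γ₁ S_u U + 2β₁ U) ⊘ (UVVᵀ + λ_u U + γ₁ D_u U + 2β₁ UUᵀU + ε)
V ← V ⊙ (UᵀX + γ₂ V S_v + 2β₂ V) ⊘ (UᵀUV + λ_v V + γ₂ V D_v + 2β₂ VVᵀV + ε) ,
```

U updated first and V against the fresh U, with ε = 1e-10 guarding 0/0 at
zero-locked entries. Both rules have non-negative numerators and
denominators, so non-negativity is preserved exactly and zero entries stay
zero. With all six weights at zero they are elementwise identical to the
Lee–Seung rules; the test suite verifies this per-iteration against an
independent implementation, and checks the gradients against central finite
differences with every penalty active.

Without the orthogonality terms the scheme is a majorize–minimize method
(the classical auxiliary-function argument for graph-regularized NMF covers
the fit, ridge and Laplacian terms), so the total objective is
non-increasing; this is asserted over many random instances. With β > 0 the
quartic penalty breaks the standard majorization proof, so only the weaker
empirical property (final objective below the initial one) is asserted —
observed without exception on all test instances.

## Graph construction

Affinities are symmetric kNN graphs on Euclidean distance: an edge is kept
if either endpoint is among the other's k nearest neighbors (default
k = 5), ties broken by lower index for determinism, self-loops removed.
Weights are binary by default — the common choice in graph-regularized NMF,
and the option that keeps S as sparse 0/1 structure — with two alternatives:
heat-kernel exp(−d²/σ²) where the "auto" bandwidth is the median kept-edge
distance (scale-free), and non-negative Pearson correlation max(0, r)
(zero-variance points fall back to binary with a warning). All options keep
S ≥ 0, which the multiplicative numerator requires. The feature graph is
built over the m gene rows, the sample graph over the n sample columns, so
Tr(UᵀL_u U) and Tr(V L_v Vᵀ) are well formed. Externally built graphs (e.g.
from a protein-interaction network) can be injected via edge-list TSV.

## Defaults and tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| k | selected from 1..5 | factorization rank (number of metagenes) |
| λ₁ (`lambda_v`), λ₂ (`lambda_u`) | 0.001, 1 | ridge on V and U (unitless weights) |
| γ₁, γ₂ | 0.001 | gene-/sample-graph smoothness weights |
| β₁, β₂ | 0.001 | U-/V-orthogonality weights |
| n_iter | 100 | multiplicative updates (objective terms plateau well within this on the preset) |
| tol | 0 (off) | optional early stop on relative objective change |
| k_neighbors | 5 | kNN graph degree (both graphs) |
| ε | 1e-10 | denominator guard |

The shipped weight combination is the best cell of the default
[0.001, 0.01, 0.1, 1] six-way grid at k = 5 for this method's reference
protocol. Initialization is i.i.d. uniform(0, 1) scaled by sqrt(mean(X)/k)
so UV starts at the data's magnitude; the seed is a mandatory part of the
API. No between-iteration normalization is performed by default — the
update rules are derived for the raw parameterization — but
`normalize="u-columns"` rescales U's columns to unit norm (compensating in
V) for users who want comparable loading scales.

Grid search enumerates the 4⁶ weight combinations in odometer order
(`itertools.product` over (λ₁, λ₂, γ₁, γ₂, β₁, β₂): first component
slowest), every cell refit from the same seeded initialization so that only
the weights differ; a seeded uniform subsample (`budget`) makes large grids
tractable. Rank selection offers two rules: `max-pcc` (argmax of
reconstruction PCC) and the default `parsimony` (smallest k reaching 99.5%
of the best PCC), because on low-noise data the PCC is flat above the true
rank and argmax degenerates to the largest candidate.

## Clustering and evaluation

Samples are clustered in the V-column embedding (the method's
dimension-reduction output); raw-X k-means is kept only as the baseline.
Spectral clustering is the standard normalized-cut recipe (kNN affinity,
normalized Laplacian eigenvectors, seeded k-means assignment, 10 restarts)
via scikit-learn. The affinity uses min(10, n/10) neighbors floored at 5:
below 5 the graph of small sample sets fragments into spurious components
and spectral clustering fails even on trivially separable data. The cluster
number is chosen by mean silhouette over the candidate counts (default
2..5), ties to the smaller count.

The silhouette uses the Rousseeuw definition: b(i) is the *minimum* over
other clusters of the mean distance to that cluster (the phrase "some other
cluster" is ambiguous; the minimum is what keeps s(i) ∈ [−1, 1] behaving as
described). Singleton-cluster samples get s(i) = 0, as do points with
max(a, b) = 0 (exact duplicates). The implementation is an explicit O(q²)
pairwise-distance computation, cross-checked in tests against both a
brute-force loop and scikit-learn.

The differential screen between two subtypes is a per-gene two-sided Welch
t-test (or Mann–Whitney), log fold change = difference of group means
(log-scale input assumed), significance at unadjusted p < 0.05 by default —
matching the reference protocol — with Benjamini–Hochberg adjustment as an
opt-in. Zero-variance genes get statistic 0, p = 1, with a warning.

## Synthetic data: what it emulates and what it does not

`generate_planted` builds X = max(0, U*V* + N(0, noise_sd)) (or
Poisson(U*V*)) with block structure: factors load disjoint gene modules over
a small uniform background, sample clusters are dominated by disjoint factor
blocks, and `separation` (default 6) sets the in-block/off-block magnitude
ratio — the single task-difficulty knob. Cluster assignment is round-robin
(balanced) unless explicit proportions are given. The `cohort` preset
is 110 genes × 451 samples, rank 5, two subtypes, separation 6, Gaussian
noise sd 0.2 — a curated-panel-sized problem at realistic cohort scale with
low noise, chosen so planted structure is recoverable but not trivial.

What passing on this generator shows: the optimizer, the model-selection
protocol and the clustering stack correctly recover structure that matches
the model's own assumptions (non-negative low-rank signal, block factors,
roughly balanced clusters, homoscedastic noise). What it does not show:
robustness to batch effects, platform differences, heavy-tailed or
correlated noise, unbalanced or nested subtypes, or real gene–gene
covariance — none of which the generator attempts to emulate.

## Numerical choices and degenerate inputs

- Non-negativity of input data is enforced explicitly; the default mode
  rejects negatives (no silent mangling), with global-shift and clip as
  opt-ins. NaNs are a hard error everywhere; no imputation.
- Ties in neighbor distances break toward the lower index; graph
  construction is therefore permutation-equivariant only up to ties.
- `reconstruction_pcc` refuses constant matrices (undefined correlation);
  `relative_error` is the absolute squared Frobenius error by definition,
  with an explicitly non-standard `normalized=True` variant.
- k = n clustering returns singletons directly; k-means on identical points
  is deterministic given the seed.
- Problem sizes in the test suite are kept small (tens × tens for unit
  tests, the 110×451 preset for end-to-end checks, 100–500 iterations),
  which the method's cost profile — O(mnk) per update — handles in seconds.

## Known limitations

- Per-step monotonicity with orthogonality penalties active is empirical,
  not proven.
- Only multiplicative updates are provided (no HALS/ANLS/projected
  gradient), no missing-data masking, no minibatching.
- The six-weight grid is exhaustive or uniformly subsampled; no adaptive
  search.
- Spectral clustering inherits scikit-learn's eigensolver behavior on
  disconnected affinity graphs (component indicators), which is the desired
  outcome for well-separated clusters but means the "number of neighbors"
  floor matters for very small n.
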