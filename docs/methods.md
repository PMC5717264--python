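# Methods

## Problem setting

An undirected, unweighted bipartite network `G(V, W, E)` with
`n = |V|`, `m = |W|` is held as a binary biadjacency matrix
`A ∈ {0,1}^{n×m}`. The observed links are split uniformly at random
into a training set `E^T` (fraction `f`, default 0.9, size
`round(f·|E|)` with ties-to-even) and a probe set `E^P = E − E^T`; both
matrices keep the full `n×m` shape, so nodes isolated by the split
retain their rows/columns and all shape invariants (`A^T + A^P = A`)
hold exactly. Predictors see only `A^T` and rank the candidate pairs
`U − E^T`; the probe links are the positives.

## Bipartite similarity indices

For a pair `(x, y)` with `x ∈ V`, `y ∈ W`, common neighbours are
defined through quadrangles `x–w–u–y`: the V-side set `cn_v` holds the
`u ≠ x` adjacent to `y` that share a W-neighbour `w ≠ y` with `x`, and
symmetrically for `cn_w`. The two sets are type-disjoint and
`CN = |cn_v| + |cn_w|`. On unlinked pairs this coincides with the set
formula `N(y) ∩ N(N(x)) ∪ N(x) ∩ N(N(y))`; on pairs that are
themselves linked the quadrangle reading additionally excludes a
co-neighbour whose only shared node is the endpoint — the package uses
the quadrangle semantics everywhere so that the per-pair and vectorized
paths agree with an explicit 4-cycle enumeration oracle.

The Local Community Paradigm quantities are `LCL` (number of edges
between `cn_v` and `cn_w`), `|γ(z)|` (LCL edges incident to the common
neighbour `z`; summing `|γ(z)|` over either side gives `LCL`) and the
external degrees `e(x) = |N(x)| − |cn_w|`, `e(y) = |N(y)| − |cn_v|`.
The ten indices:

| index | score |
|---|---|
| CN  | `|cn_v| + |cn_w|` |
| JC  | `CN / |N(x) ∪ N(y)|` (the union size is `|N(x)|+|N(y)|`: the sets live on opposite sides) |
| AA  | `Σ_z 1/log₂|N(z)|` over all common neighbours |
| RA  | `Σ_z 1/|N(z)|` |
| PA  | `|N(x)|·|N(y)|` |
| CAR | `CN · LCL` |
| CJC | `CAR / |N(x) ∪ N(y)|` |
| CAA | `Σ_z |γ(z)|/log₂|N(z)|` |
| CRA | `Σ_z |γ(z)|/|N(z)|` |
| CPA | `e(x)e(y) + (e(x)+e(y))·CAR + CAR²` |

Degenerate conventions: 0/0 → 0 for JC/CJC; empty sums are 0; a common
neighbour with degree 1 (possible only when scoring an existing
training link) would make `log₂|N(z)| = 0`, so its AA/CAA term is
skipped (with a logged warning on the per-pair path). For every
*unlinked* pair each common neighbour provably has degree ≥ 2, so no
guard fires where prediction actually happens.

The all-pairs matrix is computed with dense matrix algebra for the
counting indices (`CN`, `JC`, `AA`, `RA`, `PA` are products of
co-neighbour indicator matrices with degree-weight diagonals, plus a
correction term active only on training links) and a per-pair loop for
the LCL-dependent family, restricted to pairs with common neighbours on
both sides — all other pairs have `LCL = 0` by construction. Scores are
computed for training-linked pairs too, because the factorization
regularizer sums over all `(i, j)`.

## SRNMF

The model minimises

```
O(X, Y) = ½‖A − XY‖_F² + ½γ Σᵢⱼ (Aᵢⱼ − (XY)ᵢⱼ)² Sᵢⱼ + ½λ(‖X‖_F² + ‖Y‖_F²)
```

over nonnegative `X (n×K)`, `Y (K×m)`, where `S` is one of the ten
index matrices computed **from the training adjacency only** (using the
full adjacency would leak probe links into the fit). The λ-term is the
standard variational form of the nuclear norm of `XY`. Minimisation
alternates the multiplicative updates

```
X ← X ∘ [A Yᵀ + γ(S∘A) Yᵀ] / [X(YYᵀ) + γ(S∘(XY)) Yᵀ + λX + ε]
Y ← Y ∘ [Xᵀ A + γXᵀ(S∘A)] / [(XᵀX)Y + γXᵀ(S∘(XY)) + λY + ε]
```

with the Y-update seeing the freshly updated X. These follow from the
KKT conditions of the Lagrangian and inherit the usual guarantees of
multiplicative NMF updates: nonnegativity is preserved, exact zeros
stay zero, and the objective is non-increasing (asserted in the tests
to a relative tolerance of 1e−8, which absorbs float roundoff).

Numerical and design choices:

- **Initialization** — i.i.d. uniform(0,1), seeded. A strictly positive
  start avoids spurious zero-locking, and determinism makes traces
  bitwise reproducible.
- **Latent dimension K** — smallest `K` with
  `Σ_{i≤K} σᵢ² / Σᵢ σᵢ² ≥ 0.95`, `σᵢ` the singular values of the
  training adjacency in decreasing order (principal-component style
  cumulative contribution; singular values are used uncentered because
  centering would break the nonnegative-matrix semantics). Explicit
  integer `k` overrides; `k > min(n, m)` warns but runs.
- **Stopping** — relative objective change `< tol` (default 1e−6) or
  `max_iter` (default 300) iterations.
- **Denominator guard** — `ε = 1e−12` added to both denominators; the
  KKT derivation assumes strictly positive factors, finite-precision
  code needs the guard. Its price is that an exact fixed point is held
  only to ~1e−12 relative accuracy.
- **Regularization weights** — defaults `γ = 1/2`, `λ = 2`; both must
  be ≥ 0. With `γ = 0` the model is Frobenius-regularized NMF; with
  `γ = λ = 0` it is plain Euclidean (Lee–Seung) NMF, and its objective
  trace matches an independently coded dense implementation to 1e−10.
- **S is used raw** — no normalization, exactly as the objective is
  stated.
- **Sparse-aware products** — the dense `n×m` reconstruction `XY` is
  never materialised during updates: `XYYᵀ` goes through the `K×K` Gram
  matrix, and `S∘(XY)` is evaluated only on the sparse support of `S`
  (gathered per nonzero with an einsum), so one iteration costs
  `O((nnz(S) + nnz(A))·K + (n+m)K²)` — linear in the stored entries,
  matching the sparse complexity budget of the update rules.

Prediction scores every candidate pair by `A* = XY`; the candidate mask
is `U − E^T` (training edges excluded, probe edges kept — they are what
evaluation must rediscover).

## Projection baselines

One-mode projections score `(v, w)` as
`Σ_{u ∈ N(w)} sim(v, u)` with `sim` a same-side profile similarity:
Jaccard `|∩|/|∪|`, cosine, Euclidean distance mapped to `1/(1+d)`, or
Pearson correlation of the 0/1 profile rows (zero-variance profiles →
0; self-similarity excluded). The V-side projection is the default, the
W-side is available. These aggregation and transform choices are the
standard memory-based collaborative-filtering forms; the comparison
methods are specified in the literature only by their similarity names,
so the exact rules are fixed here for reproducibility. NBI spreads unit
resource from the target node's known links through two
degree-normalised steps, `scores = A D_W⁻¹ Aᵀ D_V⁻¹ A`, with
zero-degree nodes absorbing nothing; where no resource meets an
isolated node the spread conserves total resource exactly.

## Evaluation protocol

- **precision@L** — candidates (all non-training pairs) are ranked by
  score; `precision = L_r / L` where `L_r` counts probe links in the
  top `L` and `L` defaults to `|E^P|`. Ties are broken by a seeded
  random permutation: integer-valued indices (CN, CAR, …) tie
  massively, and a deterministic lexical tie-break would bias the
  estimate; random tie-breaking is unbiased, which the tests confirm
  against the hypergeometric expectation under constant scores.
- **AUC** — `(n′ + 0.5 n″)/n` over probe-vs-nonexistent comparisons,
  where the nonexistent set is `U − E` (excluding train *and* probe).
  Exhaustive while `|E^P|·|U−E| ≤ 10⁷` (computed by sorted binary
  search, equal to the Mann–Whitney rank statistic), otherwise sampled
  with 672,400 comparisons by default (the classical ±0.002 at 95%
  bound). The sampled-mode binomial error bound `4·√(0.25/n)` applies
  to the estimator around the score matrix's realized AUC; statements
  about the *random predictor's* AUC being 0.5 additionally require
  score pools large enough that one draw's realized AUC is itself
  tight, which the acceptance checks arrange explicitly.
- **Repeated experiment** — repeat `r` uses split seed `seed + r`; all
  methods share each split; means and standard deviations per method
  are reported. Repeats are independent resamples, not cross-validation
  folds.

## Synthetic generators

`latent_block_network(n, m, k_true, p_in, p_out, seed)` plants
`k_true` blocks round-robin on both sides (deterministic, near-equal
block sizes → tight binomial test bounds) and links each pair
independently with `p_in` within blocks, `p_out` across. The expected
adjacency has rank `k_true`, the structure both the similarity indices
and the factorization can exploit. `random_bipartite(n, m, density,
seed)` is the unstructured control. These fixtures emulate the
low-rank community organisation of real interaction networks but not
their heavy-tailed degree distributions, degree–block correlations, or
assay-driven missingness; passing the planted-structure checks shows
the estimators recover genuine low-rank signal at realistic sparsity,
not that they match any particular real network's numbers.

Problem sizes used in the shipped experiments: oracle-equivalence
checks run on networks up to 12×12 (200 instances), monotonicity on up
to 15×15 (100 instances), and the planted-recovery benchmark on 60×60
networks with 3 blocks, `p_in = 0.4`, `p_out = 0.02`, 90/10 splits and
20 seeds — sizes at which exhaustive AUC is exact and a full run of the
suite stays fast on one CPU.

## Known limitations

- The LCL-dependent indices (CAR family) use a per-pair loop over
  pairs with two-sided common neighbourhoods; on large dense networks
  (thousands of nodes at high density) this is the dominant cost.
- The KL-divergence loss variant of the factorization is not
  implemented (no multiplicative rules are derived for it here), nor
  are weighted or directed bipartite networks, or random-walk
  projection baselines.
- Convergence is to a local minimum of a non-convex objective;
  different seeds give different factors (the evaluation protocol
  averages over splits/seeds for this reason).
- `select_k` at the 95% threshold on noisy sparse matrices typically
  selects a K much larger than any planted rank, because the noise
  spectrum carries substantial energy; this follows the stated
  selection rule rather than any oracle knowledge of the true rank.
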