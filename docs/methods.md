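# Methods

## Count model and size factors

UMI counts are modelled as gamma-Poisson: Y ~ GP(μ, α) with
Var[Y] = μ + αμ². α = 0 is the Poisson boundary; typical droplet data show
α of order 0.01–0.1 per gene. Size factors are the simple depth ratios
s_c = Σ_g y_gc / L. In the default `mean_depth` mode L is the mean
per-cell total, so mean(s) = 1 and transformed values stay on the scale of
the raw counts. A fixed L (10,000 or 10⁶) is supported because it is
common practice, but it silently sets the pseudo-count of a subsequent
log1p: at depth D the induced pseudo-count is y₀ = D/L, and through
y₀ = 1/(4α) this corresponds to assuming overdispersion α = L/(4D) —
α = 50 for CPM at D = 5,000, two orders of magnitude above realistic
values. This is why `mean_depth` is the default and fixed L is opt-in.

Cells with zero total counts have s_c = 0 and no meaningful normalized
expression; they are dropped with a warning before any transformation
rather than silently imputed.

## Delta-method transformations

For a mean–variance law v(μ), the delta method yields a
variance-stabilizing g with g′(μ) ∝ 1/√v(μ). For the gamma-Poisson law
this integrates to g(y) = acosh(2αy + 1)/√α; the shifted logarithm
log(y + y₀) approximates it when y₀ = 1/(4α). Both are applied to y/s.

Numerical conventions:

- Natural logarithm throughout; the algebra linking the two shifted-log
  forms assumes a single base and nothing here depends on base 2 or 10.
- The shifted log is computed as log1p(y/(y₀·s)), i.e. the identity
  log(y/s + y₀) = log(y/(y₀s) + 1) + log(y₀) with the constant log y₀
  dropped. This maps zero counts exactly to zero, preserves sparsity, and
  leaves variances untouched. The two forms agree to better than 1e−10
  elementwise (tested).
- acosh with α = 0 delegates to the exact Poisson limit 2√(y/s).

Post-processing steps compose left to right as declared:
`rescale_cell_sum` divides each cell by its transformed column sum u_c;
`hvg` keeps the n (default 1,000) genes with the largest variance of the
already-transformed data, without recomputation, ties broken toward the
lower gene index for determinism; `zscore` standardizes each gene to mean
0, variance 1. Variance is the unbiased (n−1) sample variance in both the
HVG criterion and the z-score denominator — the two must use the same
estimator for the composed transformation to be self-consistent; the
choice of n−1 over n is a convention, flagged here because either is
defensible. Constant genes are dropped with a warning before z-scoring.

## Gamma-Poisson GLM and residuals

Per gene: log(μ_gc) = β₀_g + β₁_g·log(s_c), fitted by IRLS for β
alternating with a bounded profile-likelihood search for α on a log grid
over [1e−8, 10] (alternation capped at 10 rounds, tolerance 1e−5 on α;
non-convergence falls back to a method-of-moments α with a warning). The
slope is free by default, matching the model as written; `offset` mode
fixes it at 1. When log(s) is constant across cells (equal depths) the
slope column is degenerate and the fit reduces to intercept-only — the
reported slope is then 0 and the log-linear invariant holds trivially.
Estimates at or below the lower search bound are reported as exactly 0
(the Poisson boundary). No information is shared across genes: no
shrinkage, no regularization. This keeps the estimator transparent and
testable; on very small cell numbers per-gene estimates are accordingly
noisy.

Residual transformations hang off the fitted results object:

- Pearson: r = (y − μ̂)/√(μ̂ + α̂μ̂²), clipped to ±√(no. cells) by default
  (no. cells counted after cell filtering). Residuals of all-zero genes
  are defined as 0 and the genes flagged — any finite convention works,
  and 0 keeps downstream PCA unaffected.
- Analytic Pearson: μ̂_gc = (gene total · cell total)/grand total with a
  shared fixed α (default 0.01, configurable), clipped. This is the
  rank-one approximation that skips the GLM fit; it agrees with the full
  GLM residuals to within 10% RMS when means really are proportional to
  depth (tested).
- Randomized quantile: r = Φ⁻¹(u), u uniform on (F(y−1), F(y)] with F the
  fitted gamma-Poisson CDF (F(−1) ≡ 0), evaluated through scipy's
  negative binomial, i.e. the regularized incomplete beta — stable for
  large counts. u is clamped to [1e−10, 1−1e−10] before the normal
  quantile. Exactly standard normal under the true model; deterministic
  given a seed.

## Embedding, graphs, metrics

PCA centers genes but never scales them (scaling is the explicit z-score
variant, kept separate so its effect is measurable). Scores are computed
by dense SVD; each component's sign is fixed by making its
largest-magnitude gene loading positive, so embeddings are bit-identical
across runs. k-NN search is exact brute force with Euclidean distance,
self excluded, distance ties broken toward the lower cell index — the
datasets used here (≤ ~10⁴ cells) do not need approximate search, and
exactness makes the graphs testable against enumeration oracles. The
overlap of two graphs is the mean per-cell neighbor-set intersection,
in [0, k]; independent random graphs sit at k²/(n−1). Community detection
uses the walktrap algorithm (4-step random walks, igraph implementation),
cutting the dendrogram at maximum modularity; ARI and AMI come from
scikit-learn. The size-factor diagnostic is the first canonical
correlation between s and the top 10 PC scores, which for a single
variable equals the multiple regression correlation; values near 1 mean
the embedding mostly encodes sequencing depth.

## Simulators

The generators produce data whose ground-truth neighbor structure is
known, which no real dataset offers.

- `simulate_homogeneous`: one latent state; gene means log-uniform over
  [0.01, 1000] by default (spanning the dynamic range of droplet data);
  size factors log-uniform with a chosen max/min ratio, normalized to
  mean 1; counts gamma-Poisson via the Poisson–gamma mixture
  (shape 1/α, scale αμ), default α = 0.05. An optional `target_depth`
  rescales the mean profile so the expected per-cell total matches a
  desired sequencing depth (used for deeply sequenced matrices).
- `simulate_linear_walk`: branching trajectories; each branch
  interpolates linearly between a start and an end log-expression
  vector. Branch 1 starts at a base profile (log-uniform means over
  [0.01, 10], keeping per-cell totals in the few-thousand range typical
  of droplet data); each later branch roots at a uniformly chosen point
  of a previously laid branch, so the trajectory tree is connected.
  Endpoints drift from their start by N(0, 1) per gene — about one
  natural-log unit, a strong but not separable signal. Cells sit at
  uniform positions on uniformly chosen branches. Default α = 0.01, a
  small non-zero overdispersion mimicking real data; size factors span
  25× by default to exercise the depth-confounding diagnostics.
- `simulate_random_walk`: as above, but the latent state performs a
  Gaussian random walk along each branch (per-cell increments
  N(0, step_sd²) per gene). The default step_sd = 1/√(branch length)
  makes the expected drift over a branch one log unit, matching the
  linear walk's scale. The branch topology ("each new branch roots on a
  uniformly chosen existing cell") is a declared parameter of this
  implementation, not a hidden constant.
- `downsample_counts`: binomial thinning, y → Binomial(y, p_c) with
  p_c = min(1, target/total_c). Thinning a Poisson count by p yields
  Poisson(pμ) (tested distributionally), so thinned data remain within
  the model family.

What the simulators do **not** emulate: doublets, ambient RNA, batch
effects, gene–gene correlation beyond the shared trajectory, and
empirically calibrated mean profiles. Benchmarks passing on these data
therefore demonstrate correctness of the machinery and the documented
qualitative orderings (e.g. raw counts recovering fewer true neighbors
than the shifted log under depth variation), not performance claims about
any particular real dataset.

## Benchmark protocols

- Consistency: each gene goes to one of two groups independently with
  p = ½ (a degenerate all-one-side draw is replaced by a half-half
  split); both halves keep all cells; size factors are recomputed within
  each half — each benchmark arm sees only its own data. Cells with zero
  counts in either half are dropped from both, jointly, and logged.
- Simulation: the truth graph comes from the latent coordinates, never
  from counts. ARI/AMI are computed only here, where a truth clustering
  exists.
- Downsampling: reliable neighbors are the per-cell intersection of the
  k-NN sets over all supplied transformations on the deep data; cells
  with ≤ 1 reliable neighbor are excluded from the score. The score is
  bounded by the reliable-set sizes, not by k. If no cell qualifies, the
  run errors with advice to use fewer or more concordant transformations.
- Relative overlap divides each overlap by the mean across
  transformations within the same dataset (same k and dims), so relative
  values average to 1 per dataset and datasets of different difficulty
  become comparable.

Defaults: k = 50 (10 and 100 are the other conventional settings);
the PCA dimension is an explicit argument everywhere because no single
value suits all datasets.

## Problem sizes

The test suite and the acceptance script run simulations at
desk scale: hundreds to a couple of thousand cells and up to a few
thousand genes (e.g. 2,000 × 500 for the downsampling depth check,
1,000 genes × 2,000 cells for overdispersion recovery). These sizes were
chosen so every statistical assertion has comfortable Monte-Carlo margins
while the whole suite completes in well under a minute of compute for the
transforms and a few seconds per GLM sweep.

## Known limitations

- α estimation is per-gene maximum likelihood without shrinkage; for few
  cells or tiny means the estimates are noisy and the MoM fallback can
  trigger.
- The analytic Pearson approximation inherits its rank-one mean
  structure; it degrades when expression is not proportional to depth.
- Brute-force k-NN is quadratic in cells; beyond ~3×10⁴ cells an
  approximate index would be needed.
- The CLI covers the common paths (simulate, transform, knn, bench); the
  full parameter surface (e.g. trajectory mean profiles) is
  library-only.
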