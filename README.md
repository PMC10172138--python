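# countform

Variance-stabilizing transformations for UMI count matrices and a
k-nearest-neighbor-overlap benchmarking harness for comparing them.

## The problem

Droplet-based single-cell RNA-seq produces a genes × cells table of UMI
counts *y<sub>gc</sub>*. Counts are heteroskedastic — their variance follows
the gamma-Poisson (negative binomial) law

> Var[*Y*] = *μ* + *α μ*²,

where *α* is the overdispersion (*α* = 0 is Poisson) — and per-cell
sequencing depth varies by an order of magnitude or more. Before generic
tools (PCA, k-NN graphs, clustering) can be applied, the counts are
adjusted by a per-cell size factor and passed through a transformation
that makes the variance roughly constant across the dynamic range. Which
transformation to use is a perennial preprocessing question; this package
implements the main candidates and the benchmark protocols that
discriminate between them.

## What is implemented

**Size factors.** *s<sub>c</sub>* = Σ<sub>g</sub> *y<sub>gc</sub>* / *L*,
with *L* the mean per-cell depth (so mean *s* = 1) or a fixed constant
(*L* = 10⁴, or 10⁶ for "counts per million").

**Delta-method transformations.**

- acosh: *g*(*y*) = acosh(2*α* *y*/*s* + 1)/√*α*, the variance-stabilizing
  transformation implied by the gamma-Poisson mean–variance law
  (→ 2√(*y*/*s*) as *α* → 0);
- shifted logarithm: *g*(*y*) = log(*y*/*s* + *y*₀), computed in the
  sparsity-preserving form log(*y*/(*y*₀*s*) + 1) which maps zeros to
  zeros exactly;
- the pseudo-count/overdispersion calculus *y*₀ = 1/(4*α*): a fixed
  *L* = 10⁶ at a typical depth of 5,000 counts/cell corresponds to
  *y*₀ = 0.005 and hence assumes *α* = 50, far above what real data show;
  *L* = 10,000 implies *y*₀ = 0.5 and *α* = 0.5;
- post-processing variants: per-cell rescaling by the transformed column
  sum, highly-variable-gene selection (top 1,000 by transformed variance),
  and per-gene z-scoring.

**Gamma-Poisson GLM residuals** (statsmodels-style `Model.fit() → Results`):

```
Y_gc ~ gamma-Poisson(mu_gc, alpha_g),  log(mu_gc) = beta0_g + beta1_g * log(s_c)
```

fitted per gene by IRLS alternating with a profile-likelihood search for
*α*. The results object provides Pearson residuals
*r* = (*y* − *μ̂*)/√(*μ̂* + *α̂μ̂*²) with optional clipping at ±√(no. cells),
an analytic approximation based on the margin-product means
*μ̂<sub>gc</sub>* = (gene total · cell total)/grand total, and randomized
quantile residuals Φ⁻¹(*u*), *u* ~ Uniform(*F*(*y*−1), *F*(*y*)], which are
exactly standard normal under the true model.

**Benchmarks.** All three protocols reduce transformation quality to the
overlap of k-NN graphs, overlap = (1/n) Σ<sub>c,d</sub>
N¹<sub>cd</sub>N²<sub>cd</sub> ∈ [0, k]:

- *consistency*: split genes randomly in two halves, process each
  independently, compare the two graphs;
- *simulation*: compare the inferred graph against the ground-truth graph
  of a simulated dataset (homogeneous droplets, linear-walk or
  random-walk branching trajectories with *α* = 0.01), optionally with
  ARI/AMI after walktrap clustering;
- *downsampling*: intersect the k-NN sets of all transformations on
  deeply sequenced data ("reliable neighbors"), thin to ≈5,000
  counts/cell by binomial downsampling, and score the overlap of the
  re-inferred neighbors with the reliable sets.

## Worked example

```python
from countform import (TransformSpec, relative_overlap, results_frame,
                       simulate_linear_walk, simulation_benchmark)

data = simulate_linear_walk(n_genes=1000, n_cells=500, n_branches=4, seed=0)
specs = [
    TransformSpec(family="raw"),
    TransformSpec(family="shifted_log"),
    TransformSpec(family="acosh", alpha=0.05),
    TransformSpec(family="pearson"),
]
results = relative_overlap(simulation_benchmark(data, specs, k=50, dims=10))
print(results_frame(results)[["transform", "overlap", "relative_overlap"]]
      .to_string(index=False))
```

```
       transform  overlap  relative_overlap
             raw   16.176          0.598358
     shifted_log   30.720          1.136347
acosh+alpha=0.05   29.618          1.095583
         pearson   31.622          1.169712
```

Of each cell's 50 true nearest neighbors (known from the simulated latent
trajectory), raw counts recover about 16 — depth variation dominates the
embedding — while the shifted log, acosh and Pearson-residual
transformations recover 29–32. The relative overlap divides each row by
the dataset mean, so values above 1 beat the average transformation.

The same pipelines are scriptable from a shell:

```sh
countform simulate --kind linear_walk --genes 1000 --cells 500 --seed 0 --out sim/
countform transform --input sim/ --family shifted_log --output transformed.mtx
countform bench consistency --input sim/ --transforms shifted_log,acosh --alpha 0.05 \
    --k 50 --dims 10 --out results.tsv
```

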