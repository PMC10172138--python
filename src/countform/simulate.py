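"""Synthetic single-cell datasets with known ground-truth neighbors.

Three generators cover the benchmark settings:

- :func:`simulate_homogeneous` — droplets from a single latent expression
  state (gamma-Poisson noise around fixed gene means, variable sequencing
  depth), emulating a homogeneous RNA solution encapsulated in droplets;
- :func:`simulate_linear_walk` — cells interpolated linearly between random
  start and end points of branching trajectories;
- :func:`simulate_random_walk` — latent log-expression following a Gaussian
  random walk along each branch.

Counts are drawn from a gamma-Poisson with mean s_c * exp(latent) and
overdispersion alpha (default 0.01 for the trajectory simulations, a small
non-zero value mimicking real data).  Because the latent coordinates are
known, the true k-nearest-neighbor graph is available as ground truth.
:func:`downsample_counts` implements binomial thinning to a target
sequencing depth per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp

from .embed import KnnGraph, knn_graph
from .io import CountMatrix

__all__ = [
    "SimulatedDataset",
    "simulate_homogeneous",
    "simulate_linear_walk",
    "simulate_random_walk",
    "downsample_counts",
    "true_knn",
    "sample_gamma_poisson",
]


@dataclass
class SimulatedDataset:
    """Counts plus the latent truth that generated them.

    ``latent`` holds the true log-expression (cells × genes);
    ``truth_knn`` caches the k-NN graph computed from the latent
    coordinates, never from the counts.
    """

    counts: CountMatrix
    latent: np.ndarray
    size_factors_true: np.ndarray
    branch_id: np.ndarray
    params: dict[str, Any] = field(default_factory=dict)
    _truth_knn: KnnGraph | None = None

    @property
    def n_cells(self) -> int:
        return self.latent.shape[0]

    @property
    def n_genes(self) -> int:
        return self.latent.shape[1]

    def truth_knn(self, k: int) -> KnnGraph:
        if self._truth_knn is None or self._truth_knn.k != k:
            self._truth_knn = true_knn(self, k)
        return self._truth_knn


def sample_gamma_poisson(
    rng: np.random.Generator, mu: np.ndarray, alpha: float
) -> np.ndarray:
    """Draw gamma-Poisson counts with mean mu and Var = mu + alpha*mu^2.

    Sampled as a Poisson–gamma mixture: rate ~ Gamma(shape=1/alpha,
    scale=alpha*mu); alpha = 0 is plain Poisson.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    mu = np.asarray(mu, dtype=float)
    if alpha == 0:
        return rng.poisson(mu)
    lam = np.zeros_like(mu)
    pos = mu > 0
    lam[pos] = rng.gamma(1.0 / alpha, alpha * mu[pos])
    return rng.poisson(lam)


def _draw_size_factors(
    rng: np.random.Generator, n_cells: int, spread: float
) -> np.ndarray:
    """Log-uniform size factors with max/min ratio ``spread``, mean ≈ 1."""
    if spread < 1:
        raise ValueError("size_factor_spread must be >= 1")
    if spread == 1:
        return np.ones(n_cells)
    s = np.exp(rng.uniform(0.0, np.log(spread), size=n_cells))
    return s / s.mean()


def simulate_homogeneous(
    n_genes: int = 2000,
    n_cells: int = 1000,
    mean_profile: tuple[float, float] = (0.01, 1000.0),
    alpha: float = 0.05,
    size_factor_spread: float = 1.0,
    seed: int = 0,
    target_depth: float | None = None,
) -> SimulatedDataset:
    """Homogeneous droplets: one latent state, gamma-Poisson noise.

    Gene means are drawn log-uniformly over ``mean_profile``; size factors
    are log-uniform with max/min ratio ``size_factor_spread`` (1 = equal
    depth).  ``target_depth`` rescales the gene means so the expected
    per-cell total equals it (useful for deeply sequenced matrices).
    """
    rng = np.random.default_rng(seed)
    lo, hi = mean_profile
    if not (0 < lo <= hi):
        raise ValueError("mean_profile bounds must be positive and ordered")
    mu_g = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    if target_depth is not None:
        mu_g *= target_depth / mu_g.sum()
    s = _draw_size_factors(rng, n_cells, size_factor_spread)
    mu = s[None, :] * mu_g[:, None]  # genes × cells
    counts = sample_gamma_poisson(rng, mu, alpha)
    latent = np.tile(np.log(mu_g), (n_cells, 1))  # cells × genes, constant
    params = dict(
        kind="homogeneous",
        n_genes=n_genes,
        n_cells=n_cells,
        mean_profile=mean_profile,
        alpha=alpha,
        size_factor_spread=size_factor_spread,
        seed=seed,
        target_depth=target_depth,
    )
    return SimulatedDataset(
        counts=CountMatrix(sp.csc_matrix(counts)),
        latent=latent,
        size_factors_true=s,
        branch_id=np.zeros(n_cells, dtype=np.int64),
        params=params,
    )


def _assign_branches(
    rng: np.random.Generator, n_cells: int, n_branches: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform branch membership and positions u in [0, 1] along the branch."""
    branch = rng.integers(0, n_branches, size=n_cells)
    pos = rng.uniform(0.0, 1.0, size=n_cells)
    return branch, pos


def _base_log_expression(
    rng: np.random.Generator, n_genes: int, mean_profile: tuple[float, float]
) -> np.ndarray:
    lo, hi = mean_profile
    return rng.uniform(np.log(lo), np.log(hi), size=n_genes)


def simulate_linear_walk(
    n_genes: int = 2000,
    n_cells: int = 1000,
    n_branches: int = 4,
    alpha: float = 0.01,
    drift_sd: float = 1.0,
    mean_profile: tuple[float, float] = (0.01, 10.0),
    size_factor_spread: float = 25.0,
    seed: int = 0,
) -> SimulatedDataset:
    """Branching trajectory with linear interpolation between endpoints.

    Each branch runs from a start to an end log-expression vector; the
    first branch starts at a base profile (log-uniform means), every later
    branch starts at a uniformly chosen point on a previously laid branch,
    keeping the trajectory tree connected.  Branch endpoints differ from
    their start by independent N(0, drift_sd²) per gene, so a branch drifts
    about one natural-log unit per gene by default.  Cells sit at uniform
    positions along uniformly chosen branches; counts are gamma-Poisson
    with overdispersion ``alpha`` (default 0.01).
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    rng = np.random.default_rng(seed)
    base = _base_log_expression(rng, n_genes, mean_profile)
    starts = np.empty((n_branches, n_genes))
    ends = np.empty((n_branches, n_genes))
    starts[0] = base
    ends[0] = base + rng.normal(0.0, drift_sd, size=n_genes)
    for b in range(1, n_branches):
        parent = rng.integers(0, b)
        u = rng.uniform()
        starts[b] = starts[parent] + u * (ends[parent] - starts[parent])
        ends[b] = starts[b] + rng.normal(0.0, drift_sd, size=n_genes)
    branch, pos = _assign_branches(rng, n_cells, n_branches)
    latent = starts[branch] + pos[:, None] * (ends[branch] - starts[branch])
    s = _draw_size_factors(rng, n_cells, size_factor_spread)
    mu = s[None, :] * np.exp(latent).T  # genes × cells
    counts = sample_gamma_poisson(rng, mu, alpha)
    params = dict(
        kind="linear_walk",
        n_genes=n_genes,
        n_cells=n_cells,
        n_branches=n_branches,
        alpha=alpha,
        drift_sd=drift_sd,
        mean_profile=mean_profile,
        size_factor_spread=size_factor_spread,
        seed=seed,
        positions=pos,
    )
    return SimulatedDataset(
        counts=CountMatrix(sp.csc_matrix(counts)),
        latent=latent,
        size_factors_true=s,
        branch_id=branch,
        params=params,
    )


def simulate_random_walk(
    n_genes: int = 2000,
    n_cells: int = 1000,
    n_branches: int = 4,
    step_sd: float | None = None,
    alpha: float = 0.01,
    mean_profile: tuple[float, float] = (0.01, 10.0),
    size_factor_spread: float = 25.0,
    seed: int = 0,
) -> SimulatedDataset:
    """Branching trajectory whose latent state follows a Gaussian random walk.

    Cells on a branch are ordered; each cell's log-expression is the
    previous cell's plus independent N(0, step_sd²) increments per gene.
    The default step size makes the expected total drift along a branch
    about one natural-log unit per gene (step_sd = 1/sqrt(branch length)).
    Branch topology matches the linear walk: each new branch roots at a
    uniformly chosen cell of a previous branch.  The base profile is drawn
    log-uniformly over ``mean_profile`` (log-normal-like reference means).
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    rng = np.random.default_rng(seed)
    base = _base_log_expression(rng, n_genes, mean_profile)

    sizes = np.full(n_branches, n_cells // n_branches)
    sizes[: n_cells % n_branches] += 1
    if step_sd is None:
        step_sd = 1.0 / np.sqrt(max(int(sizes.max()), 1))
    if step_sd <= 0:
        raise ValueError("step_sd must be > 0")

    latent = np.empty((n_cells, n_genes))
    branch = np.empty(n_cells, dtype=np.int64)
    branch_cells: list[np.ndarray] = []
    idx = 0
    for b in range(n_branches):
        m = int(sizes[b])
        cells = np.arange(idx, idx + m)
        idx += m
        branch[cells] = b
        if b == 0:
            state = base.copy()
        else:
            parent_cells = branch_cells[rng.integers(0, b)]
            state = latent[rng.choice(parent_cells)].copy()
        for i, c in enumerate(cells):
            if i > 0 or b > 0:
                state = state + rng.normal(0.0, step_sd, size=n_genes)
            latent[c] = state
        branch_cells.append(cells)

    s = _draw_size_factors(rng, n_cells, size_factor_spread)
    mu = s[None, :] * np.exp(latent).T
    counts = sample_gamma_poisson(rng, mu, alpha)
    params = dict(
        kind="random_walk",
        n_genes=n_genes,
        n_cells=n_cells,
        n_branches=n_branches,
        step_sd=step_sd,
        alpha=alpha,
        mean_profile=mean_profile,
        size_factor_spread=size_factor_spread,
        seed=seed,
    )
    return SimulatedDataset(
        counts=CountMatrix(sp.csc_matrix(counts)),
        latent=latent,
        size_factors_true=s,
        branch_id=branch,
        params=params,
    )


def downsample_counts(
    m: CountMatrix, target_per_cell: float, seed: int = 0
) -> CountMatrix:
    """Binomial thinning of each cell to roughly ``target_per_cell`` counts.

    Every count is replaced by Binomial(y, p_c) with
    p_c = min(1, target / total_c), so cells already at or below the target
    are left unchanged and the thinned matrix is elementwise ≤ the input.
    """
    if target_per_cell <= 0:
        raise ValueError("target_per_cell must be > 0")
    rng = np.random.default_rng(seed)
    totals = m.cell_totals().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, np.minimum(1.0, target_per_cell / totals), 1.0)
    coo = m.values.tocoo()
    keep = p[coo.col]
    data = np.where(
        keep >= 1.0, coo.data, rng.binomial(coo.data, np.minimum(keep, 1.0))
    )
    out = sp.coo_matrix((data, (coo.row, coo.col)), shape=m.shape)
    return CountMatrix(out.tocsc(), gene_ids=m.gene_ids, cell_ids=m.cell_ids)


def true_knn(d: SimulatedDataset, k: int) -> KnnGraph:
    """Ground-truth k-NN graph from the latent log-expression coordinates.

    Euclidean distance with the same lower-index tie rule as the inferred
    graphs; deterministic given the latent matrix.
    """
    if k >= d.n_cells:
        raise ValueError("k must be < n_cells")
    return knn_graph(d.latent, k)
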