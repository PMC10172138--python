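"""The three k-NN-overlap benchmark protocols and their aggregation.

- Consistency: split genes at random into two disjoint halves, run the
  same transformation → PCA → k-NN pipeline on each half independently and
  measure the mean per-cell neighbor overlap between the two graphs.  A
  transformation that extracts real structure reproduces the same
  neighbors from either half; pure noise gives the chance level
  k²/(n−1).
- Simulation: with simulated data the true latent coordinates (and hence
  the true k-NN graph) are known; overlap of the inferred graph with the
  truth scores the transformation, optionally together with cluster
  agreement (ARI/AMI after walktrap clustering of both graphs).
- Downsampling: on deeply sequenced data, "reliable nearest neighbors"
  are the per-cell intersection of the k-NN sets across all
  transformations; after binomial thinning to a typical droplet depth
  (≈5,000 counts/cell) the score is the mean, over cells with more than
  one reliable neighbor, of the overlap between the inferred k-NN sets
  and the reliable sets.

Relative overlap divides each transformation's overlap by the mean over
all transformations on the same dataset, making datasets comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .embed import KnnGraph, ami, ari, cluster_graph, knn_graph, pca_embed
from .io import CountMatrix
from .simulate import SimulatedDataset, downsample_counts
from .transforms import TransformSpec, apply_transform

__all__ = [
    "BenchmarkResult",
    "consistency_benchmark",
    "simulation_benchmark",
    "reliable_neighbors",
    "downsampling_benchmark",
    "relative_overlap",
    "results_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 50
DOWNSAMPLE_TARGET = 5000.0


@dataclass
class BenchmarkResult:
    """One row of a benchmark: a (dataset, transformation, k, dims, replicate)."""

    dataset_id: str
    transform: str
    k: int
    pca_dims: int
    replicate_seed: int
    overlap: float
    relative_overlap: float | None = None
    extras: dict = field(default_factory=dict)


def _spec_name(spec: TransformSpec) -> str:
    parts = [spec.family]
    if spec.alpha not in (None, "genewise"):
        parts.append(f"alpha={spec.alpha}")
    if spec.y0 is not None:
        parts.append(f"y0={spec.y0}")
    parts.extend(spec.post)
    return "+".join(map(str, parts))


def _pipeline_graph(
    m: CountMatrix, spec: TransformSpec, dims: int, k: int
) -> KnnGraph:
    """transform → PCA(dims) → exact k-NN, the shared benchmark pipeline."""
    t = apply_transform(m, spec)
    d = min(dims, min(t.shape) - 1)
    emb = pca_embed(t, d)
    return knn_graph(emb, k)


def _subset_genes(m: CountMatrix, idx: np.ndarray) -> CountMatrix:
    return CountMatrix(
        m.values[idx, :],
        gene_ids=[m.gene_ids[i] for i in idx],
        cell_ids=m.cell_ids,
    )


def _drop_cells(m: CountMatrix, keep: np.ndarray) -> CountMatrix:
    return CountMatrix(
        m.values[:, keep],
        gene_ids=m.gene_ids,
        cell_ids=[c for c, kp in zip(m.cell_ids, keep) if kp],
    )


def consistency_benchmark(
    m: CountMatrix,
    specs: Sequence[TransformSpec],
    k: int = DEFAULT_K,
    dims: int = 10,
    n_replicates: int = 1,
    seed: int = 0,
    dataset_id: str = "dataset",
) -> list[BenchmarkResult]:
    """Gene-splitting consistency benchmark.

    Per replicate, each gene goes independently to one of two groups with
    probability ½; each half is processed separately (size factors are
    recomputed within the half) and the two k-NN graphs are compared by
    mean overlap.  Cells that end up with zero counts in either half are
    dropped from both halves.
    """
    if m.n_genes < 2 * dims:
        raise ValueError("need at least 2*dims genes to split")
    results = []
    for rep in range(n_replicates):
        rep_seed = seed + rep
        rng = np.random.default_rng(rep_seed)
        group = rng.integers(0, 2, size=m.n_genes).astype(bool)
        if group.all() or not group.any():  # degenerate split, reshuffle
            group[: m.n_genes // 2] = True
            group[m.n_genes // 2 :] = False
        half_a = _subset_genes(m, np.flatnonzero(group))
        half_b = _subset_genes(m, np.flatnonzero(~group))
        keep = (half_a.cell_totals() > 0) & (half_b.cell_totals() > 0)
        if not keep.all():
            logger.warning(
                "dropping %d cell(s) with a zero-count half", int((~keep).sum())
            )
            half_a = _drop_cells(half_a, keep)
            half_b = _drop_cells(half_b, keep)
        for spec in specs:
            ga = _pipeline_graph(half_a, spec, dims, k)
            gb = _pipeline_graph(half_b, spec, dims, k)
            inter = ga.adjacency().multiply(gb.adjacency()).sum()
            results.append(
                BenchmarkResult(
                    dataset_id=dataset_id,
                    transform=_spec_name(spec),
                    k=k,
                    pca_dims=dims,
                    replicate_seed=rep_seed,
                    overlap=float(inter) / ga.n_cells,
                )
            )
    return results


def simulation_benchmark(
    d: SimulatedDataset,
    specs: Sequence[TransformSpec],
    k: int = DEFAULT_K,
    dims: int = 10,
    compute_cluster_metrics: bool = False,
    seed: int = 0,
    dataset_id: str | None = None,
) -> list[BenchmarkResult]:
    """Score transformations against the simulation's ground-truth k-NN graph.

    Overlap is the mean per-cell intersection of the inferred and true
    neighbor sets.  With ``compute_cluster_metrics`` both graphs are
    clustered (walktrap) and ARI/AMI are reported in ``extras``.
    """
    truth = d.truth_knn(k)
    dataset_id = dataset_id or d.params.get("kind", "simulation")
    truth_labels = (
        cluster_graph(truth, seed=seed) if compute_cluster_metrics else None
    )
    results = []
    for spec in specs:
        g = _pipeline_graph(d.counts, spec, dims, k)
        if g.n_cells != truth.n_cells:
            raise ValueError(
                "transformation dropped cells; simulated data should have "
                "no zero-count cells"
            )
        inter = g.adjacency().multiply(truth.adjacency()).sum()
        extras = {}
        if compute_cluster_metrics:
            labels = cluster_graph(g, seed=seed)
            extras = {
                "ari": ari(labels, truth_labels),
                "ami": ami(labels, truth_labels),
            }
        results.append(
            BenchmarkResult(
                dataset_id=dataset_id,
                transform=_spec_name(spec),
                k=k,
                pca_dims=dims,
                replicate_seed=seed,
                overlap=float(inter) / truth.n_cells,
                extras=extras,
            )
        )
    return results


def reliable_neighbors(graphs: Sequence[KnnGraph]) -> list[set[int]]:
    """Per-cell intersection of neighbor sets across all graphs.

    The result is the set of neighbors every transformation agrees on; it
    may be much smaller than k (or empty) for cells whose neighborhoods are
    ambiguous.
    """
    if not graphs:
        raise ValueError("need at least one graph")
    n = graphs[0].n_cells
    for g in graphs[1:]:
        if g.n_cells != n:
            raise ValueError("graphs cover different cell sets")
    sets = graphs[0].neighbor_sets()
    for g in graphs[1:]:
        other = g.neighbor_sets()
        sets = [a & b for a, b in zip(sets, other)]
    return sets


def downsampling_benchmark(
    deep: CountMatrix,
    specs: Sequence[TransformSpec],
    k: int = DEFAULT_K,
    dims: int = 10,
    target_per_cell: float = DOWNSAMPLE_TARGET,
    n_replicates: int = 1,
    seed: int = 0,
    dataset_id: str = "deep",
) -> list[BenchmarkResult]:
    """Downsampling benchmark against reliable nearest neighbors.

    Reliable neighbors are computed from the deep matrix by intersecting
    the k-NN sets of all transformations.  Each replicate thins the deep
    matrix to ``target_per_cell`` counts per cell (binomial), reruns each
    transformation, and scores the mean size of inferred ∩ reliable over
    the cells with more than one reliable neighbor.  Note the score is
    bounded by the reliable-set sizes, not by k.
    """
    deep_graphs = [_pipeline_graph(deep, spec, dims, k) for spec in specs]
    reliable = reliable_neighbors(deep_graphs)
    eligible = np.array([len(s) > 1 for s in reliable])
    if not eligible.any():
        raise ValueError(
            "no cell has more than one reliable nearest neighbor; "
            "use fewer or more concordant transformations"
        )
    reliable_eligible = [s for s, e in zip(reliable, eligible) if e]
    results = []
    for rep in range(n_replicates):
        rep_seed = seed + rep
        thin = downsample_counts(deep, target_per_cell, seed=rep_seed)
        for spec, _ in zip(specs, deep_graphs):
            g = _pipeline_graph(thin, spec, dims, k)
            inferred = [s for s, e in zip(g.neighbor_sets(), eligible) if e]
            score = float(
                np.mean(
                    [len(a & b) for a, b in zip(inferred, reliable_eligible)]
                )
            )
            results.append(
                BenchmarkResult(
                    dataset_id=dataset_id,
                    transform=_spec_name(spec),
                    k=k,
                    pca_dims=dims,
                    replicate_seed=rep_seed,
                    overlap=score,
                    extras={
                        "n_eligible_cells": int(eligible.sum()),
                        "mean_reliable_set_size": float(
                            np.mean([len(s) for s in reliable_eligible])
                        ),
                    },
                )
            )
    return results


def relative_overlap(results: Sequence[BenchmarkResult]) -> list[BenchmarkResult]:
    """Fill ``relative_overlap``: overlap divided by the dataset mean.

    Within each dataset (same k and dims policy), each result's overlap is
    divided by the mean overlap across all transformations, so relative
    overlaps average to 1 per dataset.
    """
    by_dataset: dict[tuple, list[BenchmarkResult]] = {}
    for r in results:
        by_dataset.setdefault((r.dataset_id, r.k, r.pca_dims), []).append(r)
    out = []
    for group in by_dataset.values():
        mean = float(np.mean([r.overlap for r in group]))
        for r in group:
            r.relative_overlap = 1.0 if mean == 0 else r.overlap / mean
            out.append(r)
    return out


def results_frame(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    """Tidy table with one row per (dataset, transform, k, dims, replicate)."""
    rows = []
    for r in results:
        row = {
            "dataset_id": r.dataset_id,
            "transform": r.transform,
            "k": r.k,
            "pca_dims": r.pca_dims,
            "replicate_seed": r.replicate_seed,
            "overlap": r.overlap,
            "relative_overlap": r.relative_overlap,
        }
        row.update(r.extras)
        rows.append(row)
    return pd.DataFrame(rows)
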