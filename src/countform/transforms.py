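"""Size factors and delta-method variance-stabilizing transformations.

The mean–variance relationship of UMI counts is well described by the
gamma-Poisson law Var[Y] = μ + αμ².  The delta method turns this into the
acosh variance-stabilizing transformation g(y) = acosh(2αy + 1)/√α, which
the familiar shifted logarithm log(y + y0) approximates when the
pseudo-count is chosen as y0 = 1/(4α).  This module implements:

- size-factor estimation s_c = (Σ_g y_gc) / L, with L either the mean
  per-cell depth or a fixed constant (10,000; 10⁶ for "counts per million"),
- the shifted-log and acosh transformations in their sparsity-preserving
  forms (zero counts map exactly to zero),
- the pseudo-count ↔ overdispersion calculus y0 = 1/(4α),
- the post-processing variants: per-cell rescaling, highly-variable-gene
  (HVG) selection and per-gene z-scoring,
- a dispatcher :func:`apply_transform` covering the residual-based
  transformations as well.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix

__all__ = [
    "SizeFactors",
    "TransformSpec",
    "TransformedMatrix",
    "compute_size_factors",
    "pseudo_count_from_overdispersion",
    "overdispersion_from_pseudo_count",
    "shifted_log",
    "acosh_transform",
    "rescale_cell_sum",
    "select_hvg",
    "z_score",
    "apply_transform",
    "drop_zero_cells",
]

logger = logging.getLogger(__name__)

FAMILIES = (
    "shifted_log",
    "acosh",
    "shifted_log_cpm",
    "pearson",
    "pearson_noclip",
    "analytic_pearson",
    "random_quantile",
    "raw",
    "raw_scaled",
)

POST_STEPS = ("rescale_cell_sum", "hvg", "zscore")


@dataclass
class SizeFactors:
    """Per-cell scaling factors s_c with their normalizer L.

    ``s_c · L`` equals the cell's total UMI count.  In ``mean_depth`` mode L
    is the average per-cell depth, so mean(s) = 1; in ``fixed_L`` mode L is a
    user-supplied constant such as 10⁶ (counts per million).
    """

    s: np.ndarray
    L: float
    mode: str  # "mean_depth" | "fixed_L"

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if self.mode not in ("mean_depth", "fixed_L"):
            raise ValueError(f"unknown size-factor mode {self.mode!r}")


@dataclass
class TransformSpec:
    """A named transformation with its parameters and post-processing.

    ``y0="derived"`` (or ``alpha="derived"``) links pseudo-count and
    overdispersion through y0 = 1/(4α).  ``post`` is applied left to right.
    """

    family: str = "shifted_log"
    y0: float | str | None = None
    alpha: float | str | None = None
    post: tuple[str, ...] = ()
    hvg_n: int = 1000
    seed: int = 0
    size_factor_mode: str = "mean_depth"
    L_fixed: float | None = None
    slope_mode: str = "free"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown transformation family {self.family!r}")
        self.post = tuple(self.post)
        for step in self.post:
            if step not in POST_STEPS:
                raise ValueError(f"unknown post-processing step {step!r}")

    def resolve_y0_alpha(self) -> tuple[float | None, float | str | None]:
        """Apply the y0 = 1/(4α) link where either side is declared derived."""
        y0, alpha = self.y0, self.alpha
        if y0 == "derived":
            if not isinstance(alpha, (int, float)):
                raise ValueError("y0='derived' requires a numeric alpha")
            y0 = pseudo_count_from_overdispersion(alpha)
        if alpha == "derived":
            if not isinstance(y0, (int, float)):
                raise ValueError("alpha='derived' requires a numeric y0")
            alpha = overdispersion_from_pseudo_count(y0)
        return y0, alpha


@dataclass
class TransformedMatrix:
    """Real-valued genes × cells output of a transformation.

    Sparse whenever the transformation maps zero counts to zero (shifted
    log, acosh, raw); dense for residual-based transformations.
    ``genes_kept`` records the surviving gene indices after HVG selection or
    constant-gene dropping.
    """

    values: sp.spmatrix | np.ndarray
    spec: TransformSpec | None = None
    gene_ids: list[str] | None = None
    cell_ids: list[str] | None = None
    genes_kept: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.genes_kept is None:
            self.genes_kept = np.arange(self.values.shape[0])
        self.genes_kept = np.asarray(self.genes_kept)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def toarray(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)

    def gene_variances(self, ddof: int = 1) -> np.ndarray:
        """Unbiased per-gene variance across cells (the HVG criterion)."""
        return _row_variances(self.values, ddof=ddof)


def _row_means(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.mean(axis=1)).ravel()
    return np.asarray(values).mean(axis=1)


def _row_variances(values, ddof: int = 1) -> np.ndarray:
    n = values.shape[1]
    if n - ddof <= 0:
        return np.zeros(values.shape[0])
    if sp.issparse(values):
        mean = np.asarray(values.mean(axis=1)).ravel()
        sq = np.asarray(values.multiply(values).sum(axis=1)).ravel()
        var = (sq - n * mean**2) / (n - ddof)
        return np.maximum(var, 0.0)
    arr = np.asarray(values)
    return arr.var(axis=1, ddof=ddof)


def compute_size_factors(
    m: CountMatrix, mode: str = "mean_depth", L_fixed: float | None = None
) -> SizeFactors:
    """Estimate size factors s_c = (Σ_g y_gc) / L.

    ``mode="mean_depth"`` sets L to the mean per-cell total so that
    mean(s) = 1; ``mode="fixed_L"`` uses ``L_fixed`` (e.g. 10,000 or 10⁶ for
    counts per million).  Cells with zero total get s_c = 0; downstream
    transformations drop them explicitly.
    """
    totals = m.cell_totals().astype(float)
    if not totals.any():
        raise ValueError("count matrix has no nonzero cell")
    if mode == "mean_depth":
        L = float(totals.mean())
    elif mode == "fixed_L":
        if L_fixed is None or L_fixed <= 0:
            raise ValueError("fixed_L mode requires a positive L_fixed")
        L = float(L_fixed)
    else:
        raise ValueError(f"unknown size-factor mode {mode!r}")
    return SizeFactors(s=totals / L, L=L, mode=mode)


def pseudo_count_from_overdispersion(alpha: float) -> float:
    """Pseudo-count implied by an overdispersion: y0 = 1/(4α)."""
    if alpha <= 0:
        raise ValueError("overdispersion must be positive")
    return 1.0 / (4.0 * alpha)


def overdispersion_from_pseudo_count(y0: float) -> float:
    """Overdispersion implied by a pseudo-count: α = 1/(4·y0)."""
    if y0 <= 0:
        raise ValueError("pseudo-count must be positive")
    return 1.0 / (4.0 * y0)


def drop_zero_cells(
    m: CountMatrix, s: SizeFactors
) -> tuple[CountMatrix, SizeFactors]:
    """Remove cells with zero total counts (s_c = 0), with a warning."""
    keep = s.s > 0
    if keep.all():
        return m, s
    n_drop = int((~keep).sum())
    warnings.warn(f"dropping {n_drop} cell(s) with zero total counts")
    logger.warning("dropping %d zero-count cell(s)", n_drop)
    sub = CountMatrix(
        m.values[:, keep],
        gene_ids=m.gene_ids,
        cell_ids=[c for c, k in zip(m.cell_ids, keep) if k],
    )
    return sub, SizeFactors(s=s.s[keep], L=s.L, mode=s.mode)


def _scaled_data_transform(m: CountMatrix, s: SizeFactors, fn) -> sp.csc_matrix:
    """Apply an elementwise fn(y/s) that maps 0 → 0, staying sparse."""
    if (s.s <= 0).any():
        raise ValueError(
            "size factors contain zeros; drop zero-total cells first "
            "(drop_zero_cells)"
        )
    out = m.values.tocsc().astype(float)
    inv = 1.0 / s.s
    # scale column c by 1/s_c in place on the CSC data array
    reps = np.diff(out.indptr)
    out.data *= np.repeat(inv, reps)
    out.data = fn(out.data)
    out.eliminate_zeros()
    return out


def shifted_log(m: CountMatrix, s: SizeFactors, y0: float = 1.0) -> TransformedMatrix:
    """Shifted logarithm log(y/s + y0), in the sparsity-preserving form.

    Uses the identity log(y/s + y0) = log(y/(y0·s) + 1) + log(y0) and drops
    the constant log(y0), which leaves the variance-stabilizing behaviour
    unchanged while mapping zero counts exactly to zero.  Natural log.
    """
    if y0 is None or y0 <= 0:
        raise ValueError("pseudo-count y0 must be positive")
    inv_y0 = 1.0 / y0
    vals = _scaled_data_transform(m, s, lambda d: np.log1p(d * inv_y0))
    return TransformedMatrix(vals, gene_ids=m.gene_ids, cell_ids=m.cell_ids)


def acosh_transform(
    m: CountMatrix, s: SizeFactors, alpha: float
) -> TransformedMatrix:
    """Delta-method VST for the gamma-Poisson law: acosh(2α·y/s + 1)/√α.

    ``alpha = 0`` delegates to the Poisson limit 2√(y/s).  Zero counts map
    to zero (acosh(1) = 0), so the output stays sparse.
    """
    if alpha is None or alpha < 0:
        raise ValueError("overdispersion alpha must be non-negative")
    if alpha == 0:
        fn = lambda d: 2.0 * np.sqrt(d)  # noqa: E731 - small local closure
    else:
        inv_sqrt = 1.0 / np.sqrt(alpha)
        fn = lambda d: np.arccosh(2.0 * alpha * d + 1.0) * inv_sqrt  # noqa: E731
    vals = _scaled_data_transform(m, s, fn)
    return TransformedMatrix(vals, gene_ids=m.gene_ids, cell_ids=m.cell_ids)


def rescale_cell_sum(t: TransformedMatrix) -> TransformedMatrix:
    """Divide each cell's transformed values by their sum u_c = Σ_g x_gc."""
    if sp.issparse(t.values):
        u = np.asarray(t.values.sum(axis=0)).ravel()
    else:
        u = np.asarray(t.values).sum(axis=0)
    zero = np.flatnonzero(u == 0)
    if zero.size:
        cell = t.cell_ids[zero[0]] if t.cell_ids else str(zero[0])
        raise ValueError(f"cell {cell!r} has zero transformed column sum")
    if sp.issparse(t.values):
        vals = t.values @ sp.diags(1.0 / u)
    else:
        vals = t.values / u
    return replace(t, values=vals)


def select_hvg(t: TransformedMatrix, n: int = 1000) -> TransformedMatrix:
    """Keep the ``n`` genes with the largest variance of the transformed data.

    The transformation is not recomputed on the subset.  Ties are broken in
    favour of the lower gene index for determinism.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    variances = t.gene_variances(ddof=1)
    n_keep = min(n, t.n_genes)
    # stable sort on -variance → equal variances keep ascending index order
    order = np.argsort(-variances, kind="stable")[:n_keep]
    order = np.sort(order)  # preserve original gene order in the output
    vals = t.values[order, :]
    gene_ids = [t.gene_ids[i] for i in order] if t.gene_ids else None
    return replace(
        t,
        values=vals,
        gene_ids=gene_ids,
        genes_kept=t.genes_kept[order],
    )


def z_score(t: TransformedMatrix) -> TransformedMatrix:
    """Per-gene standardization z = (x − mean(x_g)) / sd(x_g).

    Uses the unbiased (n−1) variance, matching the HVG criterion.  Genes
    with zero variance are dropped with a warning; if all genes are
    constant this is an error.
    """
    arr = t.toarray().astype(float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    keep = sd.ravel() > 0
    if not keep.any():
        raise ValueError("all genes are constant; z-scoring undefined")
    if not keep.all():
        n_drop = int((~keep).sum())
        warnings.warn(f"dropping {n_drop} constant gene(s) before z-scoring")
        logger.warning("dropping %d constant gene(s) in z_score", n_drop)
    arr = (arr[keep] - mean[keep]) / sd[keep]
    gene_ids = (
        [g for g, k in zip(t.gene_ids, keep) if k] if t.gene_ids else None
    )
    return replace(
        t, values=arr, gene_ids=gene_ids, genes_kept=t.genes_kept[keep]
    )


def _raw(m: CountMatrix) -> TransformedMatrix:
    return TransformedMatrix(
        m.values.astype(float), gene_ids=m.gene_ids, cell_ids=m.cell_ids
    )


def _raw_scaled(m: CountMatrix, s: SizeFactors) -> TransformedMatrix:
    vals = _scaled_data_transform(m, s, lambda d: d)
    return TransformedMatrix(vals, gene_ids=m.gene_ids, cell_ids=m.cell_ids)


def apply_transform(m: CountMatrix, spec: TransformSpec) -> TransformedMatrix:
    """Apply a named transformation family and its post-processing chain.

    Families: ``shifted_log`` (default y0 = 1, or derived 1/(4α)),
    ``acosh``, ``shifted_log_cpm`` (fixed L = 10⁶, y0 = 1), the
    residual-based families (``pearson``, ``pearson_noclip``,
    ``analytic_pearson``, ``random_quantile``) and the negative controls
    ``raw`` / ``raw_scaled``.  Post-processing steps run left to right as
    declared in ``spec.post``.
    """
    from . import glm  # deferred: glm imports this module's size factors

    y0, alpha = spec.resolve_y0_alpha()

    if spec.family == "shifted_log_cpm":
        s = compute_size_factors(m, mode="fixed_L", L_fixed=1e6)
    elif spec.size_factor_mode == "fixed_L":
        s = compute_size_factors(m, mode="fixed_L", L_fixed=spec.L_fixed)
    else:
        s = compute_size_factors(m, mode="mean_depth")
    if spec.family != "raw":
        m, s = drop_zero_cells(m, s)

    if spec.family == "shifted_log":
        t = shifted_log(m, s, y0 if y0 is not None else 1.0)
    elif spec.family == "shifted_log_cpm":
        t = shifted_log(m, s, 1.0 if y0 is None else y0)
    elif spec.family == "acosh":
        if alpha is None or isinstance(alpha, str):
            raise ValueError("acosh requires a numeric alpha")
        t = acosh_transform(m, s, alpha)
    elif spec.family == "raw":
        t = _raw(m)
    elif spec.family == "raw_scaled":
        t = _raw_scaled(m, s)
    elif spec.family in ("pearson", "pearson_noclip", "random_quantile"):
        alpha_mode = "genewise" if alpha in (None, "genewise") else float(alpha)
        fit = glm.GammaPoissonGLM(
            m, size_factors=s, slope_mode=spec.slope_mode
        ).fit(alpha=alpha_mode)
        if spec.family == "random_quantile":
            res = fit.quantile_residuals(seed=spec.seed)
        else:
            res = fit.pearson_residuals(clip=spec.family == "pearson")
        t = TransformedMatrix(
            res.values, gene_ids=m.gene_ids, cell_ids=m.cell_ids
        )
    elif spec.family == "analytic_pearson":
        a = 0.01 if alpha in (None, "genewise") else float(alpha)
        res = glm.analytic_pearson(m, alpha_fixed=a)
        t = TransformedMatrix(
            res.values, gene_ids=m.gene_ids, cell_ids=m.cell_ids
        )
    else:  # pragma: no cover - guarded in TransformSpec
        raise ValueError(f"unknown transformation family {spec.family!r}")

    for step in spec.post:
        if step == "rescale_cell_sum":
            t = rescale_cell_sum(t)
        elif step == "hvg":
            t = select_hvg(t, spec.hvg_n)
        elif step == "zscore":
            t = z_score(t)
    t.spec = spec
    return t
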