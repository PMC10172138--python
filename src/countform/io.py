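"""Reading and writing UMI count matrices.

Counts live in a :class:`CountMatrix`: a sparse genes × cells matrix of
non-negative integers with gene and cell identifiers.  Supported on-disk
formats are MatrixMarket coordinate files with 10x-style annotation TSVs
(``genes.tsv``/``features.tsv`` + ``barcodes.tsv``, optionally gzipped) and a
dense CSV layout for small examples.
"""

from __future__ import annotations

import gzip
import io as _io
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["CountMatrix", "CountFormatError", "read_mtx", "write_mtx", "read_dense_csv"]


class CountFormatError(ValueError):
    """Raised when an input file violates the count-matrix contract."""


def _synthetic_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


@dataclass
class CountMatrix:
    """Genes × cells matrix of non-negative integer UMI counts.

    Parameters
    ----------
    values
        Sparse matrix with genes as rows and cells as columns.  Any
        scipy sparse format is accepted and converted to CSC.
    gene_ids, cell_ids
        Unique row/column identifiers; generated as ``g0001…``/``c0001…``
        when omitted.
    """

    values: sp.spmatrix
    gene_ids: list[str] = field(default=None)  # type: ignore[assignment]
    cell_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csc_matrix(np.asarray(self.values))
        self.values = self.values.tocsc()
        if self.gene_ids is None:
            self.gene_ids = _synthetic_ids("g", self.values.shape[0])
        if self.cell_ids is None:
            self.cell_ids = _synthetic_ids("c", self.values.shape[1])
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        self._validate()

    def _validate(self) -> None:
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise CountFormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise CountFormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise CountFormatError("gene ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise CountFormatError("cell ids are not unique")
        data = self.values.data
        if data.size:
            bad = np.flatnonzero((data < 0) | (data != np.floor(data)))
            if bad.size:
                coo = self.values.tocoo()
                g, c = coo.row[bad[0]], coo.col[bad[0]]
                raise CountFormatError(
                    f"entry at gene {g}, cell {c} is {coo.data[bad[0]]!r}; "
                    "counts must be non-negative integers"
                )
        if not np.issubdtype(self.values.dtype, np.integer):
            self.values = self.values.astype(np.int64)
        self.values.eliminate_zeros()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_totals(self) -> np.ndarray:
        """Total UMI count per cell (column sums)."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def gene_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CountMatrix({self.n_genes} genes × {self.n_cells} cells, "
            f"{self.values.nnz} stored counts)"
        )


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_with_gz(directory: Path, names: tuple[str, ...]) -> Path | None:
    for name in names:
        for candidate in (directory / name, directory / (name + ".gz")):
            if candidate.exists():
                return candidate
    return None


def _read_id_tsv(path: Path) -> list[str]:
    # genes.tsv has 2 columns (id, symbol); features.tsv has 3; barcodes 1.
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def read_mtx(path: str | os.PathLike) -> CountMatrix:
    """Read a MatrixMarket count matrix, optionally with 10x annotations.

    ``path`` may be the ``.mtx`` file itself or a directory containing
    ``matrix.mtx`` plus optional ``genes.tsv``/``features.tsv`` and
    ``barcodes.tsv`` (gzipped variants accepted).  Matrices stored
    cells × genes are transposed when the annotation lengths disambiguate
    the orientation.
    """
    path = Path(path)
    genes: list[str] | None = None
    barcodes: list[str] | None = None
    if path.is_dir():
        mtx_path = _find_with_gz(path, ("matrix.mtx",))
        if mtx_path is None:
            candidates = sorted(path.glob("*.mtx")) + sorted(path.glob("*.mtx.gz"))
            if not candidates:
                raise CountFormatError(f"no .mtx file found in {path}")
            mtx_path = candidates[0]
        gene_path = _find_with_gz(path, ("genes.tsv", "features.tsv"))
        barcode_path = _find_with_gz(path, ("barcodes.tsv",))
        if gene_path is not None:
            genes = _read_id_tsv(gene_path)
        if barcode_path is not None:
            barcodes = _read_id_tsv(barcode_path)
    else:
        mtx_path = path

    with _open_maybe_gzip(mtx_path, "rt") as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:
            raise CountFormatError(f"cannot parse {mtx_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    bad = np.flatnonzero((mat.data < 0) | (mat.data != np.floor(mat.data)))
    if bad.size:
        i = bad[0]
        raise CountFormatError(
            f"{mtx_path}: entry at row {mat.row[i] + 1}, column {mat.col[i] + 1} "
            f"is {mat.data[i]!r}; counts must be non-negative integers"
        )

    n_rows, n_cols = mat.shape
    if genes is not None and barcodes is not None:
        if len(genes) == n_rows and len(barcodes) == n_cols:
            pass
        elif len(genes) == n_cols and len(barcodes) == n_rows:
            mat = mat.T  # stored cells × genes
        else:
            raise CountFormatError(
                f"annotation lengths ({len(genes)} genes, {len(barcodes)} barcodes)"
                f" do not match matrix shape {n_rows}×{n_cols}"
            )
    elif genes is not None and len(genes) != n_rows:
        if len(genes) == n_cols:
            mat = mat.T
        else:
            raise CountFormatError(
                f"{len(genes)} gene ids do not match matrix shape {n_rows}×{n_cols}"
            )
    elif barcodes is not None and len(barcodes) != n_cols:
        if len(barcodes) == n_rows:
            mat = mat.T
        else:
            raise CountFormatError(
                f"{len(barcodes)} barcodes do not match matrix shape {n_rows}×{n_cols}"
            )
    return CountMatrix(mat.astype(np.int64), gene_ids=genes, cell_ids=barcodes)


def write_mtx(m: CountMatrix, path: str | os.PathLike) -> None:
    """Write counts as ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``.

    Coordinates are 1-based per the MatrixMarket standard; values are
    written with the ``integer`` field type.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    coo = m.values.tocoo()
    # mmwrite writes "integer" for integer dtypes
    target = path / "matrix.mtx"
    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, coo, field="integer")
    target.write_bytes(buf.getvalue())
    pd.DataFrame({"id": m.gene_ids, "symbol": m.gene_ids}).to_csv(
        path / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(m.cell_ids).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_dense_csv(path: str | os.PathLike) -> CountMatrix:
    """Read a dense CSV with gene rows, a header of cell ids and a first
    column of gene ids.  Zeros are stored implicitly in the result."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        coerced = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(coerced.isna().to_numpy() & df.notna().to_numpy())
        if bad.size:
            r, c = bad[0]
            raise CountFormatError(
                f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
                f"{df.index[r]!r}, cell {df.columns[c]!r}"
            )
        arr = coerced.to_numpy()
    if np.isnan(arr).any():
        r, c = np.argwhere(np.isnan(arr))[0]
        raise CountFormatError(
            f"{path}: missing value at gene {df.index[r]!r}, cell {df.columns[c]!r}"
        )
    if ((arr < 0) | (arr != np.floor(arr))).any():
        r, c = np.argwhere((arr < 0) | (arr != np.floor(arr)))[0]
        raise CountFormatError(
            f"{path}: value {arr[r, c]!r} at gene {df.index[r]!r}, cell "
            f"{df.columns[c]!r}; counts must be non-negative integers"
        )
    return CountMatrix(
        sp.csc_matrix(arr.astype(np.int64)),
        gene_ids=list(map(str, df.index)),
        cell_ids=list(map(str, df.columns)),
    )
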