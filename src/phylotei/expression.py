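"""Cells × genes expression container and file readers.

The container keeps the matrix in whatever representation it arrived in —
scipy CSR for sparse data, numpy for dense TSVs — and downstream statistics
are computed without ever densifying, so cost stays proportional to the
number of nonzero entries.  Cell-level metadata (group labels, computed
indices) lives in a pandas DataFrame indexed by cell name, mirroring the
``obs`` convention of annotated single-cell containers; thin adapters
convert to and from AnnData at the package boundary.
"""

from __future__ import annotations

import os
from typing import IO, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ConfigError, ParseError

__all__ = [
    "ExpressionMatrix",
    "read_expression_tsv",
    "read_mtx",
    "from_anndata",
    "to_anndata",
]

PathLike = Union[str, os.PathLike]


class ExpressionMatrix:
    """Nonnegative cells × genes matrix with names and optional cell groups.

    Parameters
    ----------
    values
    	cells × genes array or scipy sparse matrix; negative entries are
    	rejected.
    cell_names, gene_names
    	row and column labels; gene names must be unique.
    cell_groups
    	optional per-cell labels (embryo stage, cell type, ...), aligned
    	with ``cell_names``.
    """

    def __init__(
        self,
        values,
        cell_names: Sequence[str],
        gene_names: Sequence[str],
        cell_groups: Sequence[str] | None = None,
    ):
        if sp.issparse(values):
            values = values.tocsr()
            if values.nnz and values.data.min() < 0:
                raise ConfigError("expression matrix contains negative entries")
        else:
            values = np.asarray(values)
            if values.ndim != 2:
                raise ConfigError("expression matrix must be 2-dimensional")
            if values.size and values.min() < 0:
                raise ConfigError("expression matrix contains negative entries")
        if values.shape != (len(cell_names), len(gene_names)):
            raise ConfigError(
                f"matrix shape {values.shape} does not match "
                f"{len(cell_names)} cells x {len(gene_names)} genes"
            )
        gene_list = [str(g) for g in gene_names]
        if len(set(gene_list)) != len(gene_list):
            raise ConfigError("gene names are not unique")
        self.values = values
        self.cell_names = [str(c) for c in cell_names]
        self.gene_names = gene_list
        self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_names, name="cell"))
        if cell_groups is not None:
            if len(cell_groups) != len(self.cell_names):
                raise ConfigError("cell_groups length does not match cell count")
            self.cell_meta["group"] = list(cell_groups)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.values)

    @property
    def cell_groups(self) -> pd.Series | None:
        if "group" in self.cell_meta.columns:
            return self.cell_meta["group"]
        return None

    def subset_cells(self, keep: Sequence[int] | Sequence[bool]) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given cells (index or mask);
        all cell metadata columns subset consistently."""
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        sub = ExpressionMatrix(
            self.values[idx],
            [self.cell_names[i] for i in idx],
            self.gene_names,
        )
        sub.cell_meta = self.cell_meta.iloc[idx].copy()
        return sub

    def __repr__(self) -> str:
        kind = "sparse" if self.is_sparse else "dense"
        return f"ExpressionMatrix({self.n_cells} cells x {self.n_genes} genes, {kind})"


def read_expression_tsv(
    source: Union[PathLike, IO[str]], orientation: str = "cells_by_genes"
) -> ExpressionMatrix:
    """Read a dense labelled TSV matrix.

    ``orientation`` says what the rows of the *file* are: ``cells_by_genes``
    (rows = cells) or ``genes_by_cells`` (rows = genes, transposed on load).
    """
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(source, sep="\t", index_col=0)
    if orientation == "genes_by_cells":
        df = df.T
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ParseError("expression TSV contains missing values")
    return ExpressionMatrix(values, list(df.index), list(df.columns))


def _read_names(path: PathLike) -> list[str]:
    with open(path, "r", encoding="utf-8") as handle:
        return [line.rstrip("\n").split("\t")[0] for line in handle if line.strip()]


def read_mtx(
    mtx_path: PathLike,
    barcodes_path: PathLike,
    features_path: PathLike,
    orientation: str = "genes_by_cells",
) -> ExpressionMatrix:
    """Read a MatrixMarket triplet matrix plus name files.

    The default orientation follows the single-cell convention of features
    (genes) as rows and barcodes (cells) as columns; the matrix is stored
    internally as cells × genes CSR.
    """
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    matrix = sp.csr_matrix(scipy.io.mmread(os.fspath(mtx_path)))
    cells = _read_names(barcodes_path)
    genes = _read_names(features_path)
    if orientation == "genes_by_cells":
        matrix = matrix.T.tocsr()
    return ExpressionMatrix(matrix, cells, genes)


def from_anndata(adata) -> ExpressionMatrix:
    """Build an :class:`ExpressionMatrix` view of an AnnData object
    (``X`` as cells × genes, ``obs`` copied into cell metadata)."""
    expr = ExpressionMatrix(
        adata.X if sp.issparse(adata.X) else np.asarray(adata.X),
        list(adata.obs_names),
        list(adata.var_names),
    )
    for column in adata.obs.columns:
        expr.cell_meta[column] = adata.obs[column].to_numpy()
    return expr


def to_anndata(expr: ExpressionMatrix):
    """Convert to an AnnData object, carrying cell metadata into ``obs``."""
    import anndata

    adata = anndata.AnnData(
        X=expr.values if expr.is_sparse else np.asarray(expr.values, dtype=float),
        obs=expr.cell_meta.copy(),
    )
    adata.var_names = expr.gene_names
    return adata
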