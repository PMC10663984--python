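"""Transcriptome evolutionary index (TEI) and its decompositions.

The TEI of a cell (or cell type) *c* is the expression-weighted arithmetic
mean of per-gene age classes:

    TEI_c = sum_i(e_ic * ps_i) / sum_i(e_ic)

where e_ic is the expression of gene *i* in cell *c* and ps_i its
phylostratum (integer age class, 1 = oldest).  The same machinery accepts
any binned per-gene metric — nucleotide diversity, Tajima's D, F statistics
— in place of age classes, via :func:`get_bins`.

All computations honor a sparse contract: cost is proportional to the
number of nonzero expression entries and a dense cells × genes product is
never materialized, so per-cell indices scale to very large matrices.

Conventions adopted here:

* genes absent from the age mapping are excluded from *both* the numerator
  and denominator (they carry no age information, and a fake ps of 0 would
  drag every index toward "infinitely old");
* cells whose mapped expression sums to zero get NaN, not 0 — an empty cell
  has no defined index;
* no library-size normalization is applied internally: TEI is invariant to
  per-cell scaling by construction, and callers keep control over what
  get_rematrix averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError, PhyloteiError
from .expression import ExpressionMatrix

__all__ = [
    "TEIResult",
    "PartialTEIMatrix",
    "GroupedExpressionMatrix",
    "get_tei",
    "get_pstrata",
    "get_rematrix",
    "get_bins",
    "add_tei_annotation",
]

TRANSFORMS = ("none", "log1p", "sqrt")
SCALES = ("none", "minmax")


@dataclass
class TEIResult:
    """Per-cell TEI values; undefined cells (no mapped expression) are NaN."""

    tei: np.ndarray
    cell_names: list[str]
    n_genes_used: int
    unmapped_genes: list[str]

    def to_series(self) -> pd.Series:
        return pd.Series(self.tei, index=self.cell_names, name="TEI")


@dataclass
class PartialTEIMatrix:
    """Additive per-stratum decomposition of TEI (strata × cells).

    Column sums reproduce the corresponding TEI values; each row shows one
    age class's contribution to the global pattern.
    """

    values: np.ndarray
    stratum_labels: list[int]
    cell_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.stratum_labels, name="PSnum"),
            columns=self.cell_names,
        )


@dataclass
class GroupedExpressionMatrix:
    """Mean expression per age class and cell group (strata × groups).

    With min–max scaling each row is rescaled to [0, 1] across groups
    ("relative expression"); rows constant across groups become all-zero and
    are listed in ``constant_strata``.
    """

    values: np.ndarray
    stratum_labels: list[int]
    group_labels: list[str]
    transform: str
    scale: str
    constant_strata: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.stratum_labels, name="PSnum"),
            columns=self.group_labels,
        )


def _mapped_columns(
    expr: ExpressionMatrix, ps: Mapping[str, int]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Indices and age values of the expression genes present in ``ps``."""
    idx, values, unmapped = [], [], []
    for j, gene in enumerate(expr.gene_names):
        if gene in ps:
            p = int(ps[gene])
            if p < 1:
                raise PhyloteiError(f"age class for gene {gene!r} must be >= 1, got {p}")
            idx.append(j)
            values.append(p)
        else:
            unmapped.append(gene)
    if not idx:
        raise ConfigError("no overlap between expression genes and the age mapping")
    return np.asarray(idx), np.asarray(values, dtype=float), unmapped


def _mapped_submatrix(expr: ExpressionMatrix, idx: np.ndarray):
    # avoid a column-slice copy when every gene is mapped (the common case
    # after upstream filtering, and the large-matrix fast path)
    if len(idx) == expr.n_genes:
        return expr.values
    return expr.values[:, idx]


def _row_sums(matrix) -> np.ndarray:
    if sp.issparse(matrix):
        return np.asarray(matrix.sum(axis=1)).ravel()
    return np.asarray(matrix).sum(axis=1)


def get_tei(expr: ExpressionMatrix, ps: Mapping[str, int]) -> TEIResult:
    """Compute per-cell TEI.

    ``ps`` maps gene name → positive integer age class (or bin index from
    :func:`get_bins`).  Genes absent from ``ps`` are ignored entirely; cells
    with zero mapped expression get NaN.

    Examples
    --------
    A cell expressing genes with classes (1, 4) at levels (2, 1) has
    TEI = (2·1 + 1·4) / 3 = 2.0.
    """
    idx, ps_vec, unmapped = _mapped_columns(expr, ps)
    sub = _mapped_submatrix(expr, idx)
    numerator = np.asarray(sub @ ps_vec).ravel()
    denominator = _row_sums(sub)
    with np.errstate(invalid="ignore", divide="ignore"):
        tei = np.where(denominator > 0, numerator / denominator, np.nan)
    return TEIResult(tei, list(expr.cell_names), len(idx), unmapped)


def get_pstrata(expr: ExpressionMatrix, ps: Mapping[str, int]) -> PartialTEIMatrix:
    """Decompose TEI into additive per-stratum contributions.

    Entry (s, c) is ``sum_{i: ps_i = s} e_ic * s / sum_i e_ic`` with the same
    denominator as TEI, so columns sum to the TEI vector.  Rows are ordered
    by ascending age class; undefined cells give an all-NaN column.
    """
    idx, ps_vec, _ = _mapped_columns(expr, ps)
    sub = _mapped_submatrix(expr, idx)
    denominator = _row_sums(sub)
    strata, stratum_of_gene = np.unique(ps_vec, return_inverse=True)
    n_strata, n_mapped = len(strata), len(idx)
    # indicator (mapped genes × strata); sub @ indicator gives per-stratum
    # expression sums without densifying
    indicator = sp.csr_matrix(
        (np.ones(n_mapped), (np.arange(n_mapped), stratum_of_gene)),
        shape=(n_mapped, n_strata),
    )
    per_stratum = np.asarray((sub @ indicator).todense() if sp.issparse(sub) else sub @ indicator.toarray())
    values = per_stratum.T * strata[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denominator[None, :] > 0, values / denominator[None, :], np.nan)
    return PartialTEIMatrix(values, [int(s) for s in strata], list(expr.cell_names))


def get_rematrix(
    expr: ExpressionMatrix,
    ps: Mapping[str, int],
    groups: Mapping[str, str] | Sequence[str] | pd.Series | None = None,
    transform: str = "none",
    scale: str = "none",
) -> GroupedExpressionMatrix:
    """Mean expression per age class, grouped by a per-cell annotation.

    Pipeline: (1) optional elementwise transform of the counts
    (``none``/``log1p``/``sqrt`` — both transforms preserve sparsity);
    (2) mean per gene over the cells of each group; (3) mean over the genes
    of each stratum; (4) optional per-stratum min–max scaling across groups.
    Averaging cells before genes keeps gene-rich strata from dominating.

    ``groups`` may be a per-cell sequence, a cell→label mapping, or omitted
    to use the matrix's own group annotation; every cell must have a label.
    """
    if transform not in TRANSFORMS:
        raise ConfigError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")
    if scale not in SCALES:
        raise ConfigError(f"unknown scale {scale!r}; choose from {SCALES}")
    if groups is None:
        series = expr.cell_groups
        if series is None:
            raise ConfigError("no group labels: pass `groups` or annotate the matrix")
        labels = [str(v) for v in series.to_numpy()]
    elif isinstance(groups, Mapping):
        missing = [c for c in expr.cell_names if c not in groups]
        if missing:
            raise ConfigError(f"{len(missing)} cells lack a group label (e.g. {missing[0]!r})")
        labels = [str(groups[c]) for c in expr.cell_names]
    else:
        if len(groups) != expr.n_cells:
            raise ConfigError("group label sequence length does not match cell count")
        labels = [str(v) for v in groups]

    idx, ps_vec, _ = _mapped_columns(expr, ps)
    sub = _mapped_submatrix(expr, idx)
    if transform != "none":
        fn = np.log1p if transform == "log1p" else np.sqrt
        if sp.issparse(sub):
            sub = sub.copy()
            sub.data = fn(sub.data)
        else:
            sub = fn(np.asarray(sub, dtype=float))

    group_names = sorted(set(labels))
    group_index = {g: k for k, g in enumerate(group_names)}
    cell_group = np.asarray([group_index[g] for g in labels])
    n_groups = len(group_names)
    sizes = np.bincount(cell_group, minlength=n_groups).astype(float)
    # group-mean weights (groups × cells), sparse so big matrices stay cheap
    weights = sp.csr_matrix(
        (1.0 / sizes[cell_group], (cell_group, np.arange(expr.n_cells))),
        shape=(n_groups, expr.n_cells),
    )
    gene_means = weights @ sub  # groups × mapped genes
    if sp.issparse(gene_means):
        gene_means = np.asarray(gene_means.todense())

    strata, stratum_of_gene = np.unique(ps_vec, return_inverse=True)
    values = np.empty((len(strata), n_groups))
    for s in range(len(strata)):
        values[s] = gene_means[:, stratum_of_gene == s].mean(axis=1)

    constant: list[int] = []
    if scale == "minmax":
        lo = values.min(axis=1, keepdims=True)
        hi = values.max(axis=1, keepdims=True)
        span = hi - lo
        flat = span.ravel() == 0
        constant = [int(strata[s]) for s in np.flatnonzero(flat)]
        span[span == 0] = 1.0
        values = (values - lo) / span
        values[flat] = 0.0
    return GroupedExpressionMatrix(
        values, [int(s) for s in strata], group_names, transform, scale, constant
    )


def get_bins(
    metric: Mapping[str, float],
    n_bins: int,
    method: str = "quantile",
) -> tuple[pd.Series, list[str]]:
    """Bin a continuous per-gene metric into integer classes 1..n_bins.

    The result plugs in anywhere an age-class mapping does, so expression
    can be weighted by e.g. Tajima's D or F-statistic bins instead of gene
    age.  ``method='quantile'`` gives (near) equal-count bins, ``'uniform'``
    equal-width bins; bin 1 holds the smallest values.  Values tied at a
    quantile boundary all fall in the lower bin.  Non-finite metric values
    are dropped and returned in the report list.
    """
    if n_bins < 1:
        raise PhyloteiError(f"n_bins must be >= 1, got {n_bins}")
    if method not in ("quantile", "uniform"):
        raise ConfigError(f"unknown binning method {method!r}")
    genes, raw = list(metric.keys()), np.asarray(list(metric.values()), dtype=float)
    finite = np.isfinite(raw)
    dropped = [g for g, ok in zip(genes, finite) if not ok]
    genes = [g for g, ok in zip(genes, finite) if ok]
    values = raw[finite]
    if values.size == 0:
        raise PhyloteiError("metric has no finite values")
    if method == "quantile":
        edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    else:
        lo, hi = values.min(), values.max()
        edges = lo + (hi - lo) * np.linspace(0, 1, n_bins + 1)[1:-1]
    # side='left': a value equal to a boundary goes to the lower bin
    bins = 1 + np.searchsorted(edges, values, side="left")
    return pd.Series(bins, index=genes, name="bin", dtype=int), dropped


def add_tei_annotation(expr, result: TEIResult, key: str = "tei", overwrite: bool = False):
    """Attach per-cell TEI values as a metadata column.

    Works on an :class:`ExpressionMatrix` (``cell_meta``) or an AnnData
    object (``obs``).  Undefined cells keep their NaN marker.  An existing
    column of the same name is an error unless ``overwrite`` is set.
    """
    if isinstance(expr, ExpressionMatrix):
        meta = expr.cell_meta
        names = expr.cell_names
    else:  # AnnData-like
        meta = expr.obs
        names = list(expr.obs_names)
    if list(names) != list(result.cell_names):
        raise ConfigError("TEI result was not computed from this matrix's cells")
    if key in meta.columns and not overwrite:
        raise ConfigError(f"annotation key {key!r} already present; pass overwrite=True")
    meta[key] = result.tei
    return expr
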