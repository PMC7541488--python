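"""Expression-matrix container, file I/O and preprocessing.

The container is deliberately light: a dense float matrix with gene and
sample/cell identifiers, an optional categorical label per column (tissue,
phenotype or timepoint) and a flag recording the normalization state.  All
downstream steps (network inference, activity estimation) consume this type.

Supported on-disk formats are a dense TSV (first column = gene id, first row
= column ids) and MatrixMarket coordinate files with ``genes.tsv`` /
``barcodes.tsv`` sidecars, the two formats expression matrices are typically
distributed in.
"""

from __future__ import annotations

import enum
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class NormState(enum.Enum):
    """Normalization state of an expression matrix."""

    RAW_COUNTS = "raw_counts"
    LOG2_NORMALIZED = "log2_normalized"
    ZSCORED = "zscored"


def _check_unique(ids: np.ndarray, what: str) -> None:
    vals, counts = np.unique(ids, return_counts=True)
    dups = vals[counts > 1]
    if dups.size:
        raise ValueError(f"duplicate {what}: {', '.join(map(str, dups[:10]))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples (or cells) expression matrix.

    Parameters
    ----------
    values
        Dense numeric matrix, rows = genes, columns = samples/cells.
    gene_ids, column_ids
        Unique identifiers per row / column.
    column_labels
        Optional categorical label per column (tissue type, phenotype,
        timepoint).
    norm_state
        One of :class:`NormState`; transforms check and update it.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    column_ids: np.ndarray
    column_labels: np.ndarray | None = None
    norm_state: NormState = NormState.RAW_COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.column_ids = np.asarray(self.column_ids, dtype=object)
        if isinstance(self.norm_state, str):
            self.norm_state = NormState(self.norm_state)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_genes, n_cols = self.values.shape
        if self.gene_ids.shape != (n_genes,):
            raise ValueError(
                f"gene_ids length {self.gene_ids.size} != {n_genes} rows"
            )
        if self.column_ids.shape != (n_cols,):
            raise ValueError(
                f"column_ids length {self.column_ids.size} != {n_cols} columns"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.column_ids, "column ids")
        if np.isnan(self.values).any():
            bad = int(np.isnan(self.values).sum())
            raise ValueError(f"values contain {bad} missing entries")
        if self.column_labels is not None:
            self.column_labels = np.asarray(self.column_labels, dtype=object)
            if self.column_labels.shape != (n_cols,):
                raise ValueError("column_labels length mismatch")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.column_ids)

    def subset_genes(self, row_mask: np.ndarray) -> "ExpressionMatrix":
        return replace(self, values=self.values[row_mask],
                       gene_ids=self.gene_ids[row_mask])

    def subset_columns(self, col_mask: np.ndarray) -> "ExpressionMatrix":
        labels = (None if self.column_labels is None
                  else self.column_labels[col_mask])
        return replace(self, values=self.values[:, col_mask],
                       column_ids=self.column_ids[col_mask],
                       column_labels=labels)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _mtx_sidecars(path: str) -> tuple[str, str]:
    d = os.path.dirname(os.path.abspath(path))
    return os.path.join(d, "genes.tsv"), os.path.join(d, "barcodes.tsv")


def read_expression(path: str, format: str | None = None,
                    norm_state: NormState | str = NormState.RAW_COUNTS,
                    labels: Sequence | None = None) -> ExpressionMatrix:
    """Read an expression matrix from a dense TSV or a MatrixMarket file.

    For ``mtx``, row and column names are read from ``genes.tsv`` and
    ``barcodes.tsv`` next to the matrix file.  ``norm_state`` declares the
    normalization state of the stored values (default: raw counts).
    """
    if format is None:
        format = "mtx" if path.endswith((".mtx", ".mtx.gz")) else "tsv"
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, header=0,
                             float_precision="round_trip")
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed TSV {path}: {exc}") from exc
        if df.isna().any().any():
            rows = df.index[df.isna().any(axis=1)][:5].tolist()
            raise ValueError(f"missing values in {path} (rows {rows})")
        return ExpressionMatrix(df.to_numpy(dtype=np.float64),
                                df.index.to_numpy(dtype=object),
                                df.columns.to_numpy(dtype=object),
                                column_labels=None if labels is None
                                else np.asarray(labels, dtype=object),
                                norm_state=NormState(norm_state)
                                if isinstance(norm_state, str) else norm_state)
    if format == "mtx":
        genes_f, cells_f = _mtx_sidecars(path)
        for f in (genes_f, cells_f):
            if not os.path.exists(f):
                raise FileNotFoundError(f"missing MTX sidecar {f}")
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise ValueError(f"malformed MTX {path}: {exc}") from exc
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat)
                           else mat, dtype=np.float64)
        gene_ids = pd.read_csv(genes_f, sep="\t", header=None)[0].to_numpy(
            dtype=object)
        col_ids = pd.read_csv(cells_f, sep="\t", header=None)[0].to_numpy(
            dtype=object)
        return ExpressionMatrix(dense, gene_ids, col_ids,
                                column_labels=None if labels is None
                                else np.asarray(labels, dtype=object),
                                norm_state=NormState(norm_state)
                                if isinstance(norm_state, str) else norm_state)
    raise ValueError(f"unknown format {format!r}")


def write_expression(x: ExpressionMatrix, path: str,
                     format: str | None = None) -> None:
    """Write to dense TSV or MatrixMarket (with genes/barcodes sidecars).

    Values round-trip through :func:`read_expression` at full precision.
    """
    if format is None:
        format = "mtx" if path.endswith(".mtx") else "tsv"
    if format == "tsv":
        x.to_frame().to_csv(path, sep="\t")
    elif format == "mtx":
        scipy.io.mmwrite(path if path.endswith(".mtx") else path + ".mtx",
                         scipy.sparse.coo_matrix(x.values), precision=17)
        genes_f, cells_f = _mtx_sidecars(path)
        pd.Series(x.gene_ids).to_csv(genes_f, sep="\t", header=False,
                                     index=False)
        pd.Series(x.column_ids).to_csv(cells_f, sep="\t", header=False,
                                       index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Normalization / QC
# ---------------------------------------------------------------------------

def log_normalize_counts(x: ExpressionMatrix,
                         scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize counts and log-transform.

    Each column is divided by its total count, multiplied by a common scale
    factor (default 1e4) and transformed as log2(v + 1), so a zero count maps
    to zero.  The transform is invariant to rescaling all counts of a column.
    """
    if x.norm_state is not NormState.RAW_COUNTS:
        raise ValueError("log_normalize_counts expects raw counts")
    if (x.values < 0).any():
        raise ValueError("negative counts")
    totals = x.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"columns with zero total count: {list(x.column_ids[zero[:10]])}")
    out = np.log2(x.values / totals * scale + 1.0)
    return replace(x, values=out, norm_state=NormState.LOG2_NORMALIZED)


def log_transform_fpkm(x: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(v + 1) for already-normalized FPKM/TPM values."""
    if x.norm_state is NormState.ZSCORED:
        raise ValueError("input is already z-scored")
    if (x.values < 0).any():
        raise ValueError("negative expression values")
    return replace(x, values=np.log2(x.values + 1.0),
                   norm_state=NormState.LOG2_NORMALIZED)


class QCResult(NamedTuple):
    matrix: ExpressionMatrix
    n_removed: int
    removed_ids: list


def qc_filter_cells(x: ExpressionMatrix,
                    min_total: float = 2400) -> QCResult:
    """Remove cells with total count strictly below ``min_total``.

    The default of 2400 UMIs marks the boundary of the bimodal total-count
    distribution separating empty/low-quality from good cells; a cell with
    exactly ``min_total`` counts is kept.
    """
    if x.norm_state is not NormState.RAW_COUNTS:
        raise ValueError("qc_filter_cells expects raw counts")
    totals = x.values.sum(axis=0)
    keep = totals >= min_total
    if not keep.any():
        raise ValueError("QC removed every cell")
    removed = [c for c, k in zip(x.column_ids, keep) if not k]
    return QCResult(x.subset_columns(keep), len(removed), removed)


def variance_filter(x: ExpressionMatrix, sd_min: float = 0.25
                    ) -> ExpressionMatrix:
    """Keep genes whose sample SD (ddof=1) strictly exceeds ``sd_min``."""
    if x.norm_state is not NormState.LOG2_NORMALIZED:
        raise ValueError("variance_filter expects log2-normalized data")
    sd = x.values.std(axis=1, ddof=1)
    keep = sd > sd_min
    if not keep.any():
        raise ValueError(f"no genes with SD > {sd_min}")
    return x.subset_genes(keep)


class ZScoreResult(NamedTuple):
    matrix: ExpressionMatrix
    dropped_genes: list


def zscore_rows(x: ExpressionMatrix) -> ZScoreResult:
    """Center and scale every gene to mean 0, SD 1 (ddof=1).

    Constant genes carry no information for the downstream regression and
    would produce 0/0; they are dropped and their ids reported.
    """
    if x.norm_state is NormState.ZSCORED:
        return ZScoreResult(x, [])
    if x.n_columns < 3:
        raise ValueError("z-scoring needs at least 3 columns")
    sd = x.values.std(axis=1, ddof=1)
    # variation at the floating-point rounding level of the row's magnitude
    # is indistinguishable from a constant gene
    scale = np.abs(x.values).max(axis=1)
    keep = sd > 1e-10 * np.maximum(scale, 1.0)
    dropped = list(x.gene_ids[~keep])
    if not keep.any():
        raise ValueError("all genes constant; nothing to z-score")
    vals = x.values[keep]
    vals = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep, None]
    # second pass: rows whose SD is tiny relative to their magnitude lose
    # precision to cancellation; renormalizing the standardized values
    # restores mean 0 / SD 1 to machine accuracy
    vals = ((vals - vals.mean(axis=1, keepdims=True))
            / vals.std(axis=1, ddof=1, keepdims=True))
    out = replace(x, values=vals, gene_ids=x.gene_ids[keep],
                  norm_state=NormState.ZSCORED)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} constant genes at z-scoring",
                      stacklevel=2)
    return ZScoreResult(out, dropped)
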