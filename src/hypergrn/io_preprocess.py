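"""Reading/writing expression matrices and the preprocessing pipeline.

Filtering and normalization follow the standard single-cell recipe used for
the model: keep genes with non-zero expression in over a fraction (default
1%) of cells and cells with non-zero expression in over the same fraction of
genes; rank genes by standard deviation and keep the most variable ones;
log-transform and z-score per gene.  The hypergraph is then built from raw
positivity (incidence) and the normalized values (features).

File formats
------------
Dense CSV/TSV: first row gene ids, first column cell ids (cells x genes).
Sparse: Matrix Market coordinate file with companion ``cells.txt`` (row ids)
and ``genes.txt`` (column ids), one identifier per line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import ExpressionMatrix, Hypergraph

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gene_list",
    "filter_cells_genes",
    "select_top_variable_genes",
    "normalize",
    "build_hypergraph",
]


def _read_id_file(path: Path) -> list[str]:
    ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if not ids:
        raise ValueError(f"empty identifier file: {path}")
    return ids


def read_expression(path: str | Path, format: str = "csv") -> ExpressionMatrix:
    """Read a cells x genes expression matrix at stage ``raw``.

    ``format`` is one of ``csv``, ``tsv`` or ``mtx_triplet``.  For the
    triplet format, ``cells.txt`` and ``genes.txt`` must sit next to the
    matrix file.  Duplicate identifiers and non-numeric entries are rejected;
    a triplet whose dimensions match only the transposed identifier files is
    an error, never a silent transpose.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        with open(path) as fh:  # pandas mangles duplicate columns silently
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            raise ValueError("duplicate gene identifiers in input")
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.index.has_duplicates:
            raise ValueError("duplicate cell identifiers in input")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("non-numeric entries in expression matrix")
        if np.isnan(values).any():
            raise ValueError("missing (NA/NaN) entries in expression matrix")
        return ExpressionMatrix(values, list(df.index.astype(str)),
                                list(df.columns.astype(str)), stage="raw")
    if format == "mtx_triplet":
        cells = _read_id_file(path.parent / "cells.txt")
        genes = _read_id_file(path.parent / "genes.txt")
        mat = scipy.io.mmread(path)
        mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                         dtype=np.float64)
        if mat.shape != (len(cells), len(genes)):
            if mat.shape == (len(genes), len(cells)):
                raise ValueError(
                    f"matrix is {mat.shape[0]}x{mat.shape[1]} but cells.txt/genes.txt "
                    "imply the transposed orientation; refusing to guess"
                )
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(cells)} cells x {len(genes)} genes"
            )
        return ExpressionMatrix(mat, cells, genes, stage="raw")
    raise ValueError(f"unknown format {format!r}")


def write_expression(X: ExpressionMatrix, path: str | Path, format: str = "csv") -> None:
    """Write a matrix in any of the readable formats (round-trip safe)."""
    path = Path(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(X.values, index=X.cell_ids, columns=X.gene_ids)
        df.to_csv(path, sep=sep)
    elif format == "mtx_triplet":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(X.values))
        (path.parent / "cells.txt").write_text("\n".join(X.cell_ids) + "\n")
        (path.parent / "genes.txt").write_text("\n".join(X.gene_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene/TF list, one symbol per line."""
    return _read_id_file(Path(path))


def filter_cells_genes(X: ExpressionMatrix, min_frac: float = 0.01) -> ExpressionMatrix:
    """Sparsity filter: keep genes expressed in strictly more than
    ``min_frac`` of cells, then cells expressed in strictly more than
    ``min_frac`` of the remaining genes.  Gene axis first, applied once.
    """
    if X.stage != "raw":
        raise ValueError(f"filter expects a raw matrix, got stage={X.stage!r}")
    nz = X.values > 0
    gene_keep = nz.mean(axis=0) > min_frac
    if not gene_keep.any():
        raise ValueError("filtering removed every gene")
    vals = X.values[:, gene_keep]
    cell_keep = (vals > 0).mean(axis=1) > min_frac
    if not cell_keep.any():
        raise ValueError("filtering removed every cell")
    return ExpressionMatrix(
        vals[cell_keep],
        [c for c, k in zip(X.cell_ids, cell_keep) if k],
        [g for g, k in zip(X.gene_ids, gene_keep) if k],
        stage="filtered",
    )


def select_top_variable_genes(
    X: ExpressionMatrix,
    n_top: int,
    tf_list: list[str] | None = None,
) -> ExpressionMatrix:
    """Keep the ``n_top`` genes with the largest standard deviation of
    log1p-transformed expression (ties broken by original column order).

    If ``tf_list`` is given, every listed gene present in the matrix is
    force-included in addition to the ``n_top`` most variable genes, the
    convention used by GRN benchmarks that pair all variable TFs with the
    most-varying targets.
    """
    if X.stage not in ("raw", "filtered"):
        raise ValueError(f"gene selection expects raw/filtered input, got {X.stage!r}")
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    sd = np.log1p(X.values).std(axis=0)
    if n_top >= X.n_genes:
        logger.warning("n_top=%d >= %d genes available; keeping all", n_top, X.n_genes)
        keep_idx = np.arange(X.n_genes)
    else:
        # stable sort on -sd keeps original column order among ties
        order = np.argsort(-sd, kind="stable")
        keep = np.zeros(X.n_genes, dtype=bool)
        keep[order[:n_top]] = True
        if tf_list is not None:
            tf_set = set(tf_list)
            keep |= np.array([g in tf_set for g in X.gene_ids])
        keep_idx = np.flatnonzero(keep)
    return ExpressionMatrix(
        X.values[:, keep_idx],
        X.cell_ids,
        [X.gene_ids[i] for i in keep_idx],
        stage="filtered",
    )


def normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """log(1+x) then per-gene z-score (population sd over cells).

    Genes constant after the log transform map to all-zero columns.
    """
    if X.stage not in ("raw", "filtered"):
        raise ValueError(f"normalize expects raw/filtered input, got {X.stage!r}")
    if np.any(X.values < 0):
        raise ValueError("negative values in input to normalize")
    logged = np.log1p(X.values)
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    z = (logged - mu) / safe
    z[:, sd == 0] = 0.0
    out = ExpressionMatrix.__new__(ExpressionMatrix)
    out.values = z
    out.cell_ids = list(X.cell_ids)
    out.gene_ids = list(X.gene_ids)
    out.stage = "normalized"
    out.validate()
    return out


def build_hypergraph(X_raw: ExpressionMatrix, X_norm: ExpressionMatrix) -> Hypergraph:
    """Assemble the hypergraph: incidence from raw positivity (a gene-node
    belongs to a cell-hyperedge iff its raw expression there is positive),
    features from the normalized matrix.
    """
    if X_raw.gene_ids != X_norm.gene_ids or X_raw.cell_ids != X_norm.cell_ids:
        raise ValueError("raw and normalized matrices must share identifiers")
    if X_raw.values.shape != X_norm.values.shape:
        raise ValueError("raw and normalized matrices must share shape")
    incidence = (X_raw.values > 0).astype(np.float64)
    return Hypergraph(
        incidence=incidence,
        node_features=X_norm.values.T,
        cell_ids=list(X_raw.cell_ids),
        gene_ids=list(X_raw.gene_ids),
    )
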