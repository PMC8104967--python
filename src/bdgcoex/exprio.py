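"""Expression-matrix container and IO.

Matrices are genes x cells (or genes x samples), matching the convention of
10x-style single-cell outputs where the MatrixMarket triplet file carries
features on rows and barcodes on columns.  Two formats are supported: the
10x triplet layout (matrix.mtx + features.tsv + barcodes.tsv) and a dense
TSV with a gene-id index column and one column per cell.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of non-negative values with identifiers.

    ``layer_tag`` records the processing state: raw ``counts``, the
    log1p(CP10K) working scale ``cp10k_log``, or ``imputed``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"dimension mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes, {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def gene_vector(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_ids(path: str, column: int = 0) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, column].tolist()


def _triplet_paths(path: str) -> tuple[str, str, str]:
    def find(*names):
        for n in names:
            for suffix in ("", ".gz"):
                p = os.path.join(path, n + suffix)
                if os.path.exists(p):
                    return p
        raise FileNotFoundError(f"none of {names} found under {path}")

    return (
        find("matrix.mtx"),
        find("features.tsv", "genes.tsv"),
        find("barcodes.tsv"),
    )


def read_matrix(path, fmt: str | None = None) -> ExpressionMatrix:
    """Read a counts matrix.

    ``fmt`` is ``"triplet_mtx"`` (a directory holding matrix.mtx,
    features.tsv/genes.tsv and barcodes.tsv, 10x layout), ``"dense_tsv"``,
    or ``None`` to infer from the path.  Duplicate gene ids are resolved by
    summing their rows (logged).
    """
    path = str(path)
    if fmt is None:
        fmt = "triplet_mtx" if os.path.isdir(path) else "dense_tsv"

    if fmt == "triplet_mtx":
        mtx_path, feat_path, bc_path = _triplet_paths(path)
        mat = scipy.io.mmread(mtx_path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64)
        gene_ids = _read_ids(feat_path)
        cell_ids = _read_ids(bc_path)
        if values.shape != (len(gene_ids), len(cell_ids)):
            raise ValueError(
                f"matrix {values.shape} does not match {len(gene_ids)} features "
                f"x {len(cell_ids)} barcodes"
            )
    elif fmt == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        bad = df.map(lambda v: isinstance(v, str)) if hasattr(df, "map") else df.applymap(lambda v: isinstance(v, str))
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(f"non-numeric value at gene {df.index[r]!r}, cell {df.columns[c]!r}")
        values = df.to_numpy(dtype=np.float64)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")

    gene_ids, values = _sum_duplicate_genes(gene_ids, values)
    return ExpressionMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids, layer_tag="counts")


def _sum_duplicate_genes(gene_ids: list[str], values: np.ndarray):
    if len(set(gene_ids)) == len(gene_ids):
        return gene_ids, values
    order: dict[str, int] = {}
    for g in gene_ids:
        order.setdefault(g, len(order))
    logger.info("summing %d duplicate gene-id rows", len(gene_ids) - len(order))
    out = np.zeros((len(order), values.shape[1]), dtype=np.float64)
    for g, row in zip(gene_ids, values):
        out[order[g]] += row
    return list(order), out


def write_matrix(m: ExpressionMatrix, path, fmt: str = "dense_tsv") -> None:
    """Write in either supported format.  Dense TSV uses 12 significant
    digits so a write->read round-trip is lossless at working precision."""
    path = str(path)
    if fmt == "dense_tsv":
        m.to_frame().to_csv(path, sep="\t", float_format="%.12g")
    elif fmt == "triplet_mtx":
        os.makedirs(path, exist_ok=True)
        sp = scipy.sparse.coo_matrix(m.values)
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), sp, precision=12)
        pd.Series(m.gene_ids).to_csv(os.path.join(path, "features.tsv"), sep="\t", index=False, header=False)
        pd.Series(m.cell_ids).to_csv(os.path.join(path, "barcodes.tsv"), sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


# ---------------------------------------------------------------------------
# filtering / normalization
# ---------------------------------------------------------------------------

def filter_matrix(
    m: ExpressionMatrix,
    min_cells_per_gene: int = 0,
    min_genes_per_cell: int = 0,
) -> ExpressionMatrix:
    """Drop sparse genes then sparse cells.

    A gene is kept when expressed (value > 0) in at least
    ``min_cells_per_gene`` cells; after that, a cell is kept when it
    expresses at least ``min_genes_per_cell`` of the surviving genes.
    """
    if min_cells_per_gene < 0 or min_genes_per_cell < 0:
        raise ValueError("thresholds must be non-negative")
    expressed = m.values > 0
    gene_keep = expressed.sum(axis=1) >= min_cells_per_gene
    if not gene_keep.any():
        raise ValueError("all genes removed; lower min_cells_per_gene")
    cell_keep = expressed[gene_keep].sum(axis=0) >= min_genes_per_cell
    if not cell_keep.any():
        raise ValueError("all cells removed; lower min_genes_per_cell")
    logger.info(
        "filter: kept %d/%d genes, %d/%d cells",
        gene_keep.sum(), m.n_genes, cell_keep.sum(), m.n_cells,
    )
    return ExpressionMatrix(
        values=m.values[np.ix_(gene_keep, cell_keep)],
        gene_ids=[g for g, k in zip(m.gene_ids, gene_keep) if k],
        cell_ids=[c for c, k in zip(m.cell_ids, cell_keep) if k],
        layer_tag=m.layer_tag,
    )


def normalize_cp10k_log(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell to 10,000 total counts, then apply log(1 + x)."""
    if m.layer_tag != "counts":
        raise ValueError(f"expected a counts matrix, got layer {m.layer_tag!r}")
    totals = m.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell {m.cell_ids[zero[0]]!r} has zero total counts")
    values = np.log1p(m.values * (10_000.0 / totals))
    return replace(m, values=values, layer_tag="cp10k_log")


def inverse_cp10k_log(m: ExpressionMatrix, cell_totals: np.ndarray) -> ExpressionMatrix:
    """Undo :func:`normalize_cp10k_log` given the original per-cell totals,
    mapping (possibly imputed) log-scale values back to the count scale."""
    if m.layer_tag not in ("cp10k_log", "imputed"):
        raise ValueError(f"expected a log-scale matrix, got layer {m.layer_tag!r}")
    cell_totals = np.asarray(cell_totals, dtype=np.float64)
    if cell_totals.shape != (m.n_cells,):
        raise ValueError("cell_totals length must match number of cells")
    values = np.expm1(m.values) * (cell_totals / 10_000.0)
    return replace(m, values=values, layer_tag="counts")
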