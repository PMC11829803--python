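"""Reading, filtering and transforming expression matrices.

The canonical in-memory container is :class:`ExpressionMatrix`: a dense
cells x genes array of nonnegative expression values (FPKM/CPM-like scale)
with unique cell and gene identifiers.  On disk the common convention is
genes x cells; readers accept either orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


@dataclass
class ExpressionMatrix:
    """Cells x genes expression matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_cells, n_genes)
        Nonnegative expression values.
    cell_ids, gene_ids : sequences of str
        Unique identifiers matching the matrix dimensions.
    """

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n_cells, n_genes = self.values.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n_cells)]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(n_genes)]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValueError("identifier lists do not match matrix dimensions")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene identifiers")
        if np.any(self.values < 0):
            raise ValueError("negative expression values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ExpressionMatrix(
            self.values[mask],
            [c for c, m in zip(self.cell_ids, mask) if m],
            list(self.gene_ids),
        )

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ExpressionMatrix(
            self.values[:, mask],
            list(self.cell_ids),
            [g for g, m in zip(self.gene_ids, mask) if m],
        )


@dataclass
class CellMetadata:
    """Optional per-cell annotations: cluster labels and/or ordinal stage labels."""

    cell_ids: list[str]
    cluster_label: pd.Series | None = None
    external_label: pd.Series | None = None


def count_expressed_genes(matrix: ExpressionMatrix, threshold: float = 1.0) -> np.ndarray:
    """Number of genes per cell with expression strictly above ``threshold``."""
    if matrix.n_cells == 0 or matrix.n_genes == 0:
        raise ValueError("empty input")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return (matrix.values > threshold).sum(axis=1)


def filter_low_complexity_cells(
    matrix: ExpressionMatrix,
    threshold: float = 1.0,
    quantile: float = 0.1,
    factor: float = 0.75,
) -> ExpressionMatrix:
    """Drop cells whose expressed-gene count falls below ``factor`` times the
    ``quantile``-th percentile of the per-cell counts.

    Percentiles use linear interpolation between order statistics.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    if factor < 0:
        raise ValueError("factor must be >= 0")
    counts = count_expressed_genes(matrix, threshold)
    cutoff = factor * np.percentile(counts, 100 * quantile)
    keep = counts >= cutoff
    if not keep.any():
        raise ValueError("all cells filtered")
    return matrix.subset_cells(keep)


def filter_genes_by_prevalence(
    matrix: ExpressionMatrix, min_fraction: float = 0.05, threshold: float = 1.0
) -> ExpressionMatrix:
    """Keep genes expressed (> threshold) in strictly more than ``min_fraction`` of cells."""
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    frac = (matrix.values > threshold).mean(axis=0)
    keep = frac > min_fraction
    if not keep.any():
        raise ValueError("no gene passes the prevalence filter")
    return matrix.subset_genes(keep)


def normalize_library_size(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell to the median library size (sum over genes)."""
    libs = matrix.values.sum(axis=1)
    if np.any(libs == 0):
        warnings.warn("cells with zero library size left unscaled")
    med = np.median(libs[libs > 0]) if (libs > 0).any() else 0.0
    scale = np.where(libs > 0, med / np.where(libs > 0, libs, 1.0), 1.0)
    return ExpressionMatrix(matrix.values * scale[:, None], matrix.cell_ids, matrix.gene_ids)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) entrywise."""
    if np.any(matrix.values < 0):
        raise ValueError("negative entries")
    return ExpressionMatrix(np.log2(matrix.values + 1.0), matrix.cell_ids, matrix.gene_ids)


def preprocess(
    matrix: ExpressionMatrix,
    *,
    expressed_threshold: float = 1.0,
    cell_quantile: float = 0.1,
    cell_factor: float = 0.75,
    gene_min_fraction: float = 0.05,
    normalize: bool = True,
    log: bool = True,
) -> ExpressionMatrix:
    """Standard preprocessing chain: cell complexity filter, gene prevalence
    filter, optional median library-size normalization, log2(x+1)."""
    out = filter_low_complexity_cells(matrix, expressed_threshold, cell_quantile, cell_factor)
    out = filter_genes_by_prevalence(out, gene_min_fraction, expressed_threshold)
    if normalize:
        out = normalize_library_size(out)
    if log:
        out = log_transform(out)
    return out


# ---------------------------------------------------------------------------
# I/O


def read_dense(path: str | Path, sep: str | None = None, cells_in_rows: bool = False) -> ExpressionMatrix:
    """Read a dense TSV/CSV matrix with row and column names.

    The on-disk convention is genes x cells; pass ``cells_in_rows=True``
    if the file is already cells x genes.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if not cells_in_rows:
        df = df.T
    return ExpressionMatrix(df.to_numpy(dtype=float), list(df.index), list(df.columns))


def write_dense(matrix: ExpressionMatrix, path: str | Path, sep: str | None = None,
                cells_in_rows: bool = False) -> None:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = matrix.to_frame()
    if not cells_in_rows:
        df = df.T
    df.to_csv(path, sep=sep)


def read_mtx(mtx_path: str | Path, gene_path: str | Path, cell_path: str | Path,
             cells_in_rows: bool = False) -> ExpressionMatrix:
    """Read a MatrixMarket matrix with sidecar gene/cell name files (one per line)."""
    m = spio.mmread(str(mtx_path))
    if sparse.issparse(m):
        m = m.toarray()
    genes = [ln.strip() for ln in Path(gene_path).read_text().splitlines() if ln.strip()]
    cells = [ln.strip() for ln in Path(cell_path).read_text().splitlines() if ln.strip()]
    if not cells_in_rows:
        m = m.T
    return ExpressionMatrix(np.asarray(m, dtype=float), cells, genes)


def write_mtx(matrix: ExpressionMatrix, mtx_path: str | Path, gene_path: str | Path,
              cell_path: str | Path, cells_in_rows: bool = False) -> None:
    m = matrix.values if cells_in_rows else matrix.values.T
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(m))
    Path(gene_path).write_text("\n".join(matrix.gene_ids) + "\n")
    Path(cell_path).write_text("\n".join(matrix.cell_ids) + "\n")


def read_metadata(path: str | Path) -> CellMetadata:
    """Read a cell-metadata TSV with header; recognised columns are
    ``cell_id`` (required), ``cluster`` and ``external_label``."""
    df = pd.read_csv(path, sep="\t")
    if "cell_id" not in df.columns:
        raise ValueError("metadata must contain a 'cell_id' column")
    df = df.set_index("cell_id")
    cluster = df["cluster"].astype(str) if "cluster" in df.columns else None
    external = None
    if "external_label" in df.columns:
        external = df["external_label"].astype(int)
        if (external < 0).any():
            raise ValueError("external_label ranks must be >= 0")
    return CellMetadata(list(df.index.astype(str)), cluster, external)
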