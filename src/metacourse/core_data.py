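"""Containers, I/O, normalization and preprocessing shared by all stages.

The central container is :class:`AnnotatedExpressionMatrix`: a sparse
cells x genes raw count matrix together with a natural-log normalized
layer, per-cell metadata (sample, patient, day since symptom onset,
cell type, severity) and an optional low-dimensional embedding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "DEFAULT_TIME_GRID",
    "DEFAULT_SCALE_FACTOR",
    "TimeGrid",
    "AnnotatedExpressionMatrix",
    "MatrixFormatError",
    "read_expression_matrix",
    "write_expression_matrix",
    "normalize_counts",
    "select_hvgs",
    "compute_embedding",
]

#: Days since symptom onset on which the reference dataset was sampled.
DEFAULT_TIME_GRID: tuple[int, ...] = (3, 7, 9, 10, 13, 15, 16, 22, 25, 28)

#: Per-cell scaling applied before the log1p transform (the convention of
#: the normalization routine the upstream data was processed with).
DEFAULT_SCALE_FACTOR: float = 1e4

REQUIRED_META_COLUMNS = (
    "cell_id",
    "sample_id",
    "patient_id",
    "day",
    "cell_type",
    "severity",
)

SEVERITY_LEVELS = ("mild", "severe", "control")


class MatrixFormatError(ValueError):
    """Raised when input files are inconsistent with each other."""


@dataclass(frozen=True)
class TimeGrid:
    """Ordered set of integer sampling days."""

    days: tuple[int, ...] = DEFAULT_TIME_GRID

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.days)
        if len(days) < 2:
            raise ValueError("time grid needs at least two days")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"time grid must be strictly increasing, got {days}")
        object.__setattr__(self, "days", days)

    @property
    def t_min(self) -> int:
        return self.days[0]

    @property
    def t_max(self) -> int:
        return self.days[-1]

    def __contains__(self, day: int) -> bool:
        return int(day) in self.days

    def __iter__(self):
        return iter(self.days)

    def __len__(self) -> int:
        return len(self.days)


@dataclass
class AnnotatedExpressionMatrix:
    """Cells x genes counts with normalized layer, metadata and embedding.

    Attributes
    ----------
    counts
        Sparse non-negative integer matrix, cells in rows.
    cell_meta
        One row per cell, aligned with ``counts`` rows.  Must contain the
        columns in :data:`REQUIRED_META_COLUMNS`.
    gene_ids
        Unique gene identifiers, one per column of ``counts``.
    normalized
        Per-cell total-scaled, log1p-transformed expression; ``None``
        until :meth:`normalize` is called.
    embedding
        Optional cells x d real matrix.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_ids: list[str]
    normalized: sp.csr_matrix | None = None
    embedding: np.ndarray | None = None
    time_grid: TimeGrid = field(default_factory=TimeGrid)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise ValueError("counts must be integral")
        n_cells, n_genes = self.counts.shape
        if len(self.cell_meta) != n_cells:
            raise MatrixFormatError(
                f"metadata has {len(self.cell_meta)} rows but matrix has {n_cells} cells"
            )
        missing = [c for c in REQUIRED_META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise MatrixFormatError(f"metadata missing required columns: {missing}")
        if len(self.gene_ids) != n_genes:
            raise MatrixFormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen, dupes = set(), set()
            for g in self.gene_ids:
                (dupes if g in seen else seen).add(g)
            raise MatrixFormatError(f"duplicate gene ids: {sorted(dupes)[:10]}")
        self.cell_meta = self.cell_meta.reset_index(drop=True)
        off_grid = [
            d
            for d, sev in zip(self.cell_meta["day"], self.cell_meta["severity"])
            if sev != "control" and int(d) not in self.time_grid
        ]
        if off_grid:
            raise ValueError(
                f"days {sorted(set(off_grid))} outside time grid {self.time_grid.days} "
                "(only control cells may sit off-grid)"
            )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> list[str]:
        return self.cell_meta["cell_id"].tolist()

    def normalize(self, scale_factor: float = DEFAULT_SCALE_FACTOR) -> None:
        """Populate the normalized layer (idempotent)."""
        self.normalized = normalize_counts(self.counts, scale_factor, cell_ids=self.cell_ids)

    def dense_normalized(self) -> np.ndarray:
        if self.normalized is None:
            raise ValueError("normalized layer absent; call .normalize() first")
        return np.asarray(self.normalized.todense())

    def subset_cells(self, mask: np.ndarray) -> "AnnotatedExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return AnnotatedExpressionMatrix(
            counts=self.counts[idx],
            cell_meta=self.cell_meta.iloc[idx].reset_index(drop=True),
            gene_ids=list(self.gene_ids),
            normalized=None if self.normalized is None else self.normalized[idx],
            embedding=None if self.embedding is None else self.embedding[idx],
            time_grid=self.time_grid,
        )


def read_expression_matrix(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    meta_path: str | Path,
    genes_in_rows: bool = True,
    time_grid: TimeGrid | None = None,
) -> AnnotatedExpressionMatrix:
    """Assemble a container from MTX + features/barcodes TSV + metadata.

    Parameters
    ----------
    genes_in_rows
        Matrix Market dialect flag: if true (10x convention) the MTX holds
        genes in rows and cells in columns; the matrix is transposed on
        load so cells are always rows in memory.
    """
    matrix_path, features_path = Path(matrix_path), Path(features_path)
    barcodes_path, meta_path = Path(barcodes_path), Path(meta_path)

    mat = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    if genes_in_rows:
        mat = sp.csr_matrix(mat.T)
    features = pd.read_csv(features_path, sep="\t", header=None)
    gene_ids = features.iloc[:, 0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()

    n_cells, n_genes = mat.shape
    if len(gene_ids) != n_genes:
        raise MatrixFormatError(
            f"{features_path.name}: {len(gene_ids)} features but matrix has {n_genes} genes"
        )
    if len(barcodes) != n_cells:
        raise MatrixFormatError(
            f"{barcodes_path.name}: {len(barcodes)} barcodes but matrix has {n_cells} cells"
        )

    sep = "," if meta_path.suffix.lower() == ".csv" else "\t"
    meta = pd.read_csv(meta_path, sep=sep, dtype={"cell_id": str})
    missing_cols = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise MatrixFormatError(f"{meta_path.name}: missing columns {missing_cols}")
    meta = meta.set_index("cell_id", drop=False)
    absent = [b for b in barcodes if b not in meta.index]
    if absent:
        raise MatrixFormatError(
            f"{meta_path.name}: no metadata for barcodes {absent[:10]}"
            + (f" (+{len(absent) - 10} more)" if len(absent) > 10 else "")
        )
    meta = meta.loc[barcodes].reset_index(drop=True)

    kwargs = {} if time_grid is None else {"time_grid": time_grid}
    return AnnotatedExpressionMatrix(counts=mat, cell_meta=meta, gene_ids=gene_ids, **kwargs)


def write_expression_matrix(matrix: AnnotatedExpressionMatrix, out_dir: str | Path) -> dict:
    """Write MTX (genes-in-rows) + features/barcodes TSV + metadata TSV.

    Returns the paths written, keyed by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
        "meta": out_dir / "cell_meta.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(matrix.counts.T), field="integer")
    pd.Series(matrix.gene_ids).to_csv(paths["features"], sep="\t", index=False, header=False)
    pd.Series(matrix.cell_ids).to_csv(paths["barcodes"], sep="\t", index=False, header=False)
    matrix.cell_meta.to_csv(paths["meta"], sep="\t", index=False)
    return paths


def normalize_counts(
    counts: sp.spmatrix | np.ndarray,
    scale_factor: float = DEFAULT_SCALE_FACTOR,
    cell_ids: Sequence[str] | None = None,
) -> sp.csr_matrix:
    """Total-count scale each cell then natural-log transform.

    ``normalized[c, g] = ln(1 + counts[c, g] / total[c] * scale_factor)``

    Raises
    ------
    ValueError
        If any cell has zero total counts (names the cell).
    """
    counts = sp.csr_matrix(counts, dtype=np.float64)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = (
            [cell_ids[i] for i in zero[:10]] if cell_ids is not None else zero[:10].tolist()
        )
        raise ValueError(f"cells with zero total counts: {names}")
    scaled = sp.diags(scale_factor / totals) @ counts
    scaled.data = np.log1p(scaled.data)
    return sp.csr_matrix(scaled)


def select_hvgs(
    matrix: AnnotatedExpressionMatrix, n_top: int, n_bins: int = 20
) -> np.ndarray:
    """Rank genes by binned-normalized dispersion and return the top ``n_top``.

    Statistic: variance of normalized expression across cells, z-scored
    within 20 equal-frequency mean-expression bins.  Ties are broken by
    gene id (lexicographic), making the selection deterministic.
    """
    if matrix.normalized is None:
        raise ValueError("normalized layer absent; call .normalize() first")
    if n_top > matrix.n_genes:
        raise ValueError(f"n_top={n_top} exceeds n_genes={matrix.n_genes}")
    X = matrix.normalized
    n = matrix.n_cells
    means = np.asarray(X.mean(axis=0)).ravel()
    sq_means = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq_means - means**2) * n / max(n - 1, 1)

    # equal-frequency bins on mean expression; z-score variance per bin
    order = np.argsort(means, kind="stable")
    bins = np.empty(matrix.n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(matrix.n_genes) * n_bins) // matrix.n_genes, n_bins - 1
    )
    score = np.zeros(matrix.n_genes)
    for b in range(n_bins):
        in_bin = bins == b
        if not in_bin.any():
            continue
        v = var[in_bin]
        sd = v.std()
        score[in_bin] = (v - v.mean()) / sd if sd > 0 else 0.0

    key = sorted(
        range(matrix.n_genes), key=lambda g: (-score[g], matrix.gene_ids[g])
    )
    return np.asarray(key[:n_top], dtype=int)


def compute_embedding(
    matrix: AnnotatedExpressionMatrix,
    hvg_indices: Sequence[int] | np.ndarray,
    n_components: int = 50,
    clip: float = 10.0,
) -> np.ndarray:
    """PCA of centered, unit-scaled HVG expression.

    Values are clipped at ``|z| = clip`` before decomposition.  Component
    sign is fixed so that each component's largest-magnitude loading is
    positive, making the embedding deterministic.
    """
    if matrix.n_cells < 2:
        raise ValueError("embedding requires at least two cells")
    hvg_indices = np.asarray(hvg_indices, dtype=int)
    n_components = int(min(n_components, matrix.n_cells - 1, len(hvg_indices)))
    if n_components < 1:
        raise ValueError("n_components must be >= 1 after capping")

    X = np.asarray(matrix.normalized[:, hvg_indices].todense())
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -clip, clip)
    Z -= Z.mean(axis=0)  # re-center after clipping

    # deterministic full SVD; cells x hvgs stays desk-scale
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    signs = np.sign(Vt[np.arange(n_components), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    return (U * S) * signs
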