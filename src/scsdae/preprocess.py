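"""Filtering and library-size log normalization of expression matrices.

Cells are rows, genes are columns throughout the package. Normalization is
log(CPM + 1): each cell's counts are scaled to counts-per-million by its
library size, then log-transformed with pseudocount 1, so zero counts map
exactly to zero normalized values. The zero mask marks the observed
(non-zero) entries that the imputation step must preserve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class EmptyMatrixError(ValueError):
    """Raised when filtering leaves no expressed cells or genes."""


@dataclass
class CountMatrix:
    """Raw cells x genes non-negative expression matrix.

    Integer counts for scRNA-seq; continuous non-negative intensities
    (microarray-like) are accepted unchanged.
    """

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expected a 2-D cells x genes matrix")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        n_cells, n_genes = self.values.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(n_cells)]
        if not self.gene_ids:
            self.gene_ids = [f"gene{j}" for j in range(n_genes)]
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValueError("id lengths do not match matrix dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class NormalizedMatrix:
    """log(CPM + 1) expression values with the per-cell library sizes."""

    values: np.ndarray
    library_sizes: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ZeroMask:
    """Boolean cells x genes matrix; True where expression was observed (> 0)."""

    values: np.ndarray


def filter_matrix(counts: CountMatrix) -> CountMatrix:
    """Drop cells with no expressed gene and genes expressed in no cell.

    Removing an all-zero gene cannot silence a cell (counts are
    non-negative), so a single cell pass followed by a gene pass is stable;
    stability is asserted anyway.
    """
    values = counts.values
    cell_keep = np.flatnonzero(values.sum(axis=1) > 0)
    values = values[cell_keep]
    gene_keep = np.flatnonzero(values.sum(axis=0) > 0)
    values = values[:, gene_keep]
    if values.size == 0:
        raise EmptyMatrixError("no expressed cells/genes after filtering")
    assert np.all(values.sum(axis=1) > 0) and np.all(values.sum(axis=0) > 0)
    return CountMatrix(
        values=values,
        cell_ids=[counts.cell_ids[i] for i in cell_keep],
        gene_ids=[counts.gene_ids[j] for j in gene_keep],
    )


def normalize(counts: CountMatrix, log_base: float | str = "e") -> NormalizedMatrix:
    """Library-size normalize to CPM and log-transform with pseudocount 1.

    x_ij = log(count_ij / libsize_i * 1e6 + 1).  Natural log by default;
    pass ``log_base=2`` etc. for other bases.  Requires filtered input
    (every cell must have a positive library size).
    """
    libsize = counts.values.sum(axis=1)
    if np.any(libsize <= 0):
        raise ValueError("unfiltered input: a cell has zero library size")
    cpm = counts.values / libsize[:, None] * 1e6
    x = np.log1p(cpm)
    if log_base != "e":
        x /= np.log(float(log_base))
    return NormalizedMatrix(
        values=x,
        library_sizes=libsize,
        cell_ids=list(counts.cell_ids),
        gene_ids=list(counts.gene_ids),
    )


def compute_mask(x: NormalizedMatrix | np.ndarray) -> ZeroMask:
    """Indicator of observed entries: True exactly where x > 0."""
    values = x.values if isinstance(x, NormalizedMatrix) else np.asarray(x)
    return ZeroMask(values=values > 0)
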