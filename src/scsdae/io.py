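"""Readers and writers for expression matrices.

Dense CSV/TSV (with an orientation flag) and Matrix Market ``.mtx`` with
``genes.tsv`` / ``barcodes.tsv`` sidecars (CellRanger-style layout, where
the .mtx is genes x cells).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .preprocess import CountMatrix


def read_dense(path: str, orientation: str = "cells-by-genes", sep: str | None = None) -> CountMatrix:
    """Read a dense delimited matrix with row/column labels.

    orientation: ``cells-by-genes`` (rows are cells) or ``genes-by-cells``.
    The separator is inferred from the extension unless given.
    """
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "genes-by-cells":
        df = df.T
    elif orientation != "cells-by-genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    return CountMatrix(
        values=df.to_numpy(dtype=np.float64),
        cell_ids=[str(i) for i in df.index],
        gene_ids=[str(c) for c in df.columns],
    )


def write_dense(path: str, values: np.ndarray, cell_ids, gene_ids,
                orientation: str = "cells-by-genes", sep: str | None = None) -> None:
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.DataFrame(values, index=cell_ids, columns=gene_ids)
    if orientation == "genes-by-cells":
        df = df.T
    df.to_csv(path, sep=sep)


def read_mtx(mtx_path: str, genes_path: str | None = None, barcodes_path: str | None = None) -> CountMatrix:
    """Read a Matrix Market genes x cells matrix with name sidecars.

    Sidecars default to ``genes.tsv`` and ``barcodes.tsv`` next to the
    ``.mtx`` file; each holds one identifier per line (first column used
    if tab-separated).
    """
    d = os.path.dirname(mtx_path)
    genes_path = genes_path or os.path.join(d, "genes.tsv")
    barcodes_path = barcodes_path or os.path.join(d, "barcodes.tsv")
    mat = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.float64).T  # to cells x genes
    genes = _read_ids(genes_path)
    barcodes = _read_ids(barcodes_path)
    return CountMatrix(values=mat, cell_ids=barcodes, gene_ids=genes)


def write_mtx(mtx_path: str, values: np.ndarray, cell_ids, gene_ids) -> None:
    """Write genes x cells .mtx plus genes.tsv / barcodes.tsv sidecars."""
    d = os.path.dirname(mtx_path)
    scipy.io.mmwrite(mtx_path, scipy.sparse.coo_matrix(np.asarray(values).T))
    with open(os.path.join(d, "genes.tsv"), "w") as fh:
        fh.write("\n".join(map(str, gene_ids)) + "\n")
    with open(os.path.join(d, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(map(str, cell_ids)) + "\n")


def read_matrix(path: str, orientation: str = "cells-by-genes") -> CountMatrix:
    """Dispatch on extension: .mtx or dense CSV/TSV."""
    if path.endswith(".mtx"):
        return read_mtx(path)
    return read_dense(path, orientation=orientation)


def _read_ids(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
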