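"""Reading and writing expression matrices and label files.

Two on-disk matrix layouts are supported:

* ``dense`` — TSV/CSV with a header row of cell ids and a first column of
  gene ids. Genes-as-rows by default; ``genes_as_rows=False`` transposes.
* ``mtx`` — MatrixMarket coordinate format with sidecar newline-delimited
  gene and cell id files (1-based indices per the MTX standard).

Labels are TSV, either two columns ``cell_id<TAB>label`` (matched to the
paired matrix by id) or a single ordered column.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import DataError, ExpressionMatrix, LabelVector

logger = logging.getLogger(__name__)


def _sidecar_paths(path: Path, genes_path, cells_path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    genes = Path(genes_path) if genes_path else Path(str(stem) + ".genes.txt")
    cells = Path(cells_path) if cells_path else Path(str(stem) + ".cells.txt")
    return genes, cells


def read_expression(
    path,
    format: str = "dense",
    genes_as_rows: bool = True,
    genes_path=None,
    cells_path=None,
    is_normalized: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from ``path``.

    ``format='dense'`` expects a delimited table (tab for .tsv/.txt, comma
    for .csv); ``format='mtx'`` expects MatrixMarket plus sidecar id files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise DataError(f"{path}: empty table")
        if not genes_as_rows:
            df = df.T
        values = df.to_numpy(dtype=np.float64)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    elif format == "mtx":
        gpath, cpath = _sidecar_paths(path, genes_path, cells_path)
        for p in (gpath, cpath):
            if not p.exists():
                raise FileNotFoundError(f"missing sidecar id file: {p}")
        mat = scipy.io.mmread(path)
        gene_ids = gpath.read_text().split()
        cell_ids = cpath.read_text().split()
        mat = scipy.sparse.coo_matrix(mat)
        if mat.shape != (len(gene_ids), len(cell_ids)):
            raise DataError(
                f"{path}: matrix is {mat.shape} but sidecars list "
                f"{len(gene_ids)} genes and {len(cell_ids)} cells"
            )
        values = np.asarray(mat.todense(), dtype=np.float64)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'dense' or 'mtx')")
    return ExpressionMatrix(values, gene_ids, cell_ids, is_normalized=is_normalized)


def write_expression(X: ExpressionMatrix, path, format: str = "dense",
                     genes_path=None, cells_path=None) -> None:
    """Write ``X`` to ``path`` in the chosen layout (genes as rows)."""
    path = Path(path)
    if format == "dense":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.DataFrame(X.values, index=X.gene_ids, columns=X.cell_ids)
        df.to_csv(path, sep=sep)
    elif format == "mtx":
        gpath, cpath = _sidecar_paths(path, genes_path, cells_path)
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(X.values))
        gpath.write_text("\n".join(X.gene_ids) + "\n")
        cpath.write_text("\n".join(X.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path, matrix: ExpressionMatrix | None = None,
                min_types: int = 1) -> LabelVector:
    """Read a label file and, when a matrix is given, align labels to its cells.

    Raises :class:`DataError` when ids mismatch the matrix or when fewer than
    ``min_types`` distinct labels are present (training requires >= 2).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] == 1:
        labels = list(df.iloc[:, 0])
        if matrix is not None and len(labels) != matrix.n_cells:
            raise DataError(
                f"{len(labels)} labels for {matrix.n_cells} cells in the matrix"
            )
    elif df.shape[1] == 2:
        by_cell = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
        if len(by_cell) != len(df):
            raise DataError(f"{path}: duplicate cell ids in label file")
        if matrix is None:
            labels = list(df.iloc[:, 1])
        else:
            missing = [c for c in matrix.cell_ids if c not in by_cell]
            if missing:
                raise DataError(f"cells missing from label file: {missing[:5]}")
            extra = set(by_cell) - set(matrix.cell_ids)
            if extra:
                raise DataError(f"label file cells absent from matrix: {sorted(extra)[:5]}")
            labels = [by_cell[c] for c in matrix.cell_ids]
    else:
        raise DataError(f"{path}: expected 1 or 2 tab-separated columns, got {df.shape[1]}")
    lv = LabelVector(labels)
    if lv.n_types < min_types:
        raise DataError(
            f"{path}: found {lv.n_types} distinct label(s); at least {min_types} required"
        )
    return lv


def write_labels(y: LabelVector, cell_ids: list[str], path) -> None:
    """Write ``cell_id<TAB>label`` lines."""
    if len(cell_ids) != y.n_cells:
        raise DataError("cell id list and label vector length differ")
    with open(path, "w") as fh:
        for c, lab in zip(cell_ids, y.labels):
            fh.write(f"{c}\t{lab}\n")


def write_predictions(cell_ids: list[str], labels: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tpredicted_label\n")
        for c, lab in zip(cell_ids, labels):
            fh.write(f"{c}\t{lab}\n")
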