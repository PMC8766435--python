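"""Normalization and gene-space harmonization between train and test matrices."""
from __future__ import annotations

import logging

import numpy as np

from .containers import DataError, ExpressionMatrix

logger = logging.getLogger(__name__)

TARGET_SUM = 10_000.0


def normalize(X: ExpressionMatrix, method: str = "lognorm") -> ExpressionMatrix:
    """Library-size normalize each cell and log-transform.

    ``lognorm`` scales every cell (column) to a total of 10,000 and applies
    ``log(1 + x)``; ``none`` returns the values unchanged but flags them as
    normalized. A cell with zero total counts is an error: it carries no
    signal and would silently corrupt downstream scaling.
    """
    if method == "none":
        return ExpressionMatrix(X.values.copy(), list(X.gene_ids), list(X.cell_ids),
                                is_normalized=True)
    if method != "lognorm":
        raise ValueError(f"unknown normalization method {method!r}")
    lib = X.values.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        names = [X.cell_ids[i] for i in zero[:5]]
        raise DataError(f"{zero.size} cell(s) with zero library size, e.g. {names}")
    vals = np.log1p(X.values * (TARGET_SUM / lib)[None, :])
    return ExpressionMatrix(vals, list(X.gene_ids), list(X.cell_ids), is_normalized=True)


def intersect_genes(
    train: ExpressionMatrix, test: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their shared genes, rows sorted lexicographically.

    The two outputs carry identical gene lists in identical order, which every
    downstream feature-indexed step relies on.
    """
    common = sorted(set(train.gene_ids) & set(test.gene_ids))
    if not common:
        raise DataError("train and test matrices share no genes")
    tr_pos = {g: i for i, g in enumerate(train.gene_ids)}
    te_pos = {g: i for i, g in enumerate(test.gene_ids)}
    tr_idx = np.array([tr_pos[g] for g in common], dtype=int)
    te_idx = np.array([te_pos[g] for g in common], dtype=int)
    return train.subset_genes(tr_idx), test.subset_genes(te_idx)


def align_to_gene_order(
    X: ExpressionMatrix, gene_order: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Reorder ``X``'s rows to ``gene_order``, zero-filling missing genes.

    Returns ``(values, missing_mask)`` where ``values`` has shape
    ``(len(gene_order), n_cells)`` and ``missing_mask[i]`` is True when
    ``gene_order[i]`` is absent from ``X``. Raises if nothing overlaps.
    """
    pos = {g: i for i, g in enumerate(X.gene_ids)}
    out = np.zeros((len(gene_order), X.n_cells), dtype=np.float64)
    missing = np.zeros(len(gene_order), dtype=bool)
    n_found = 0
    for i, g in enumerate(gene_order):
        j = pos.get(g)
        if j is None:
            missing[i] = True
        else:
            out[i, :] = X.values[j, :]
            n_found += 1
    if n_found == 0:
        raise DataError("no overlap between the matrix genes and the model's gene order")
    if missing.any():
        logger.warning(
            "%d of %d model genes absent from the matrix; imputed as zeros",
            int(missing.sum()), len(gene_order),
        )
    return out, missing
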