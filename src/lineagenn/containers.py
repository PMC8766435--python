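"""In-memory containers for expression matrices and cell-type labels.

The expression matrix is always held genes x cells, mirroring the convention
of most scRNA-seq count files, with string gene and cell identifiers attached.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DataError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise DataError(f"duplicate {what} id: {dup!r}")


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with identifiers.

    Parameters
    ----------
    values
        Non-negative matrix of shape (n_genes, n_cells). Raw counts or
        normalized values, indicated by ``is_normalized``.
    gene_ids, cell_ids
        Unique string identifiers for rows and columns.
    is_normalized
        Whether ``values`` have been library-size normalized / log-transformed.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise DataError(f"expected a 2-D matrix, got shape {self.values.shape}")
        g, n = self.values.shape
        if g < 1 or n < 1:
            raise DataError("matrix must have at least one gene and one cell")
        if len(self.gene_ids) != g:
            raise DataError(f"{len(self.gene_ids)} gene ids for {g} rows")
        if len(self.cell_ids) != n:
            raise DataError(f"{len(self.cell_ids)} cell ids for {n} columns")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if np.any(self.values < 0):
            raise DataError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, row_idx: np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given gene rows (in order)."""
        row_idx = np.asarray(row_idx, dtype=int)
        return ExpressionMatrix(
            values=self.values[row_idx, :],
            gene_ids=[self.gene_ids[i] for i in row_idx],
            cell_ids=list(self.cell_ids),
            is_normalized=self.is_normalized,
        )

    def subset_cells(self, col_idx: np.ndarray) -> "ExpressionMatrix":
        col_idx = np.asarray(col_idx, dtype=int)
        return ExpressionMatrix(
            values=self.values[:, col_idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in col_idx],
            is_normalized=self.is_normalized,
        )


@dataclass
class LabelVector:
    """Per-cell categorical cell-type labels.

    ``label_set`` is the sorted list of distinct type names; it may be given
    explicitly (e.g. when a subset of cells misses a type) but every label
    must then belong to it.
    """

    labels: list[str]
    label_set: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) == 0:
            raise DataError("empty label vector")
        observed = sorted(set(self.labels))
        if self.label_set is None:
            self.label_set = observed
        else:
            self.label_set = [str(x) for x in self.label_set]
            missing = set(self.labels) - set(self.label_set)
            if missing:
                raise DataError(f"labels outside label_set: {sorted(missing)}")

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    @property
    def n_types(self) -> int:
        return len(self.label_set)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def indices_of(self, label: str) -> np.ndarray:
        arr = self.as_array()
        return np.flatnonzero(arr == label)

    def subset(self, idx: np.ndarray) -> "LabelVector":
        idx = np.asarray(idx, dtype=int)
        return LabelVector([self.labels[i] for i in idx], label_set=list(self.label_set))
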