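"""Per-type mean profiles, their Pearson correlation, and the mode decision.

The annotator dispatches on the correlation structure of the training data:
if any two cell types have mean-profile Pearson correlation at or above a
threshold tau (default 0.95), the lineage-tree hierarchical classifier is
used; otherwise a single flat multi-class network suffices.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DataError, ExpressionMatrix, LabelVector

DEFAULT_TAU = 0.95


@dataclass
class ProfileMatrix:
    """G x K matrix of per-type mean expression; column k averages type k's cells."""

    A: np.ndarray
    type_names: list[str]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        if self.A.ndim != 2 or self.A.shape[1] != len(self.type_names):
            raise DataError("profile matrix shape inconsistent with type names")
        if len(self.type_names) < 2:
            raise DataError("at least two cell types are required")


@dataclass
class CorrelationMatrix:
    """Symmetric K x K Pearson correlation of the profile columns."""

    P: np.ndarray
    type_names: list[str]

    def max_offdiag(self) -> float:
        K = self.P.shape[0]
        mask = ~np.eye(K, dtype=bool)
        return float(self.P[mask].max())


@dataclass
class StrategyDecision:
    mode: str  # "flat" | "hierarchical"
    tau: float
    max_offdiag: float


def mean_profiles(X0: ExpressionMatrix, y0: LabelVector) -> ProfileMatrix:
    """Average expression over the cells of each type: A[g, k] = mean_{c: y_c=k} X[g, c]."""
    if y0.n_cells != X0.n_cells:
        raise DataError(
            f"label vector length {y0.n_cells} != cell count {X0.n_cells}"
        )
    cols = []
    labels = y0.as_array()
    for k in y0.label_set:
        idx = np.flatnonzero(labels == k)
        if idx.size == 0:
            raise DataError(f"cell type {k!r} has no cells")
        cols.append(X0.values[:, idx].mean(axis=1))
    return ProfileMatrix(np.column_stack(cols), list(y0.label_set))


def correlation(prof: ProfileMatrix) -> CorrelationMatrix:
    """Pearson correlation matrix of the profile columns.

    A constant profile column has undefined correlations and is rejected:
    a type whose mean profile does not vary over genes carries no signal.
    """
    A = prof.A
    if A.shape[0] < 2:
        raise DataError("need at least two genes to correlate profiles")
    sd = A.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [prof.type_names[i] for i in flat]
        raise DataError(f"constant mean profile for type(s) {names}: correlation undefined")
    P = np.corrcoef(A, rowvar=False)
    P = np.clip(P, -1.0, 1.0)
    np.fill_diagonal(P, 1.0)
    return CorrelationMatrix(P, list(prof.type_names))


def select_strategy(P: CorrelationMatrix, tau: float = DEFAULT_TAU) -> StrategyDecision:
    """Hierarchical mode iff any off-diagonal correlation >= tau (inclusive)."""
    if not (0.0 < tau <= 1.0):
        raise ValueError(f"tau must be in (0, 1], got {tau}")
    m = P.max_offdiag()
    mode = "hierarchical" if m >= tau else "flat"
    return StrategyDecision(mode=mode, tau=tau, max_offdiag=m)
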