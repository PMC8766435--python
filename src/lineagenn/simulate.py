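"""Synthetic scRNA-seq count generator with controllable type correlation.

The generator emulates the two regimes that matter for the annotator's mode
decision: cell types sharing a ``group`` draw their mean profile from a
common base profile with a small multiplicative log-normal perturbation, so
their mean expression profiles are nearly collinear (high Pearson r);
types in distinct groups draw independent base profiles (low r).

Counts are negative-binomial around the per-type gene means, each type gets
a disjoint set of exclusive marker genes (expressed at ``marker_fold`` times
the median base gene mean in their own type and zeroed in all others, so
their expressing-cell sensitivity is 1 by construction when dropout is off),
and technical dropout is applied
as an independent Bernoulli zero mask. All randomness flows from the single
``rng_seed`` through fixed substreams, so the same seed reproduces the same
matrix bitwise, and raising only ``dropout_rate`` zeroes a superset of
entries.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import DataError, ExpressionMatrix, LabelVector

# Base-profile log-normal: median mean ~0.37 counts/gene with a wide spread,
# which with the default dispersion yields roughly 80-85% zeros before dropout.
PROFILE_LOG_MEAN = -1.0
PROFILE_LOG_SD = 1.6


@dataclass
class CellTypeSpec:
    """One simulated cell type; types sharing ``group`` are highly correlated."""

    name: str
    n_cells: int
    group: str | None = None  # None -> the type is its own group

    @property
    def group_name(self) -> str:
        return self.group if self.group is not None else f"__solo__{self.name}"


@dataclass
class SimConfig:
    n_genes: int = 2000
    types: list[CellTypeSpec] = field(default_factory=list)
    within_group_perturbation: float = 0.02
    n_markers_per_type: int = 12
    marker_fold: float = 5.0
    nb_dispersion: float = 0.3  # var = mu + dispersion * mu^2
    dropout_rate: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.types:
            raise DataError("at least one cell type must be specified")
        if self.n_markers_per_type < 0:
            raise DataError("n_markers_per_type must be >= 0")
        if self.n_markers_per_type * len(self.types) > self.n_genes:
            raise DataError("more marker genes requested than genes available")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise DataError("dropout_rate must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise DataError("nb_dispersion must be positive")
        names = [t.name for t in self.types]
        if len(set(names)) != len(names):
            raise DataError("cell type names must be unique")


@dataclass
class SimData:
    """Simulation output plus the ground truth used by tests."""

    X: ExpressionMatrix  # raw counts
    y: LabelVector
    marker_genes: dict[str, list[str]]
    type_means: np.ndarray  # G x K expected counts per type
    type_names: list[str]

    def manifest(self) -> dict:
        return {
            "type_names": self.type_names,
            "n_genes": self.X.n_genes,
            "n_cells": self.X.n_cells,
            "marker_genes": self.marker_genes,
        }


def simulate_full(cfg: SimConfig) -> SimData:
    """Generate raw counts, labels, and the planted ground truth."""
    ss = np.random.SeedSequence(cfg.rng_seed)
    profile_rng, marker_rng, count_rng, dropout_rng = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    G = cfg.n_genes
    K = len(cfg.types)
    groups = sorted({t.group_name for t in cfg.types})
    base = {
        g: np.exp(profile_rng.normal(PROFILE_LOG_MEAN, PROFILE_LOG_SD, size=G))
        for g in groups
    }
    # Per-type means: group base x small multiplicative log-normal perturbation.
    means = np.empty((G, K))
    for j, t in enumerate(cfg.types):
        pert = (
            np.exp(cfg.within_group_perturbation * profile_rng.normal(size=G))
            if cfg.within_group_perturbation > 0
            else 1.0
        )
        means[:, j] = base[t.group_name] * pert

    gene_ids = [f"g{i:05d}" for i in range(G)]
    marker_genes: dict[str, list[str]] = {t.name: [] for t in cfg.types}
    if cfg.n_markers_per_type > 0:
        chosen = marker_rng.choice(G, size=cfg.n_markers_per_type * K, replace=False)
        marker_level = cfg.marker_fold * float(np.exp(PROFILE_LOG_MEAN))
        for j, t in enumerate(cfg.types):
            rows = chosen[j * cfg.n_markers_per_type : (j + 1) * cfg.n_markers_per_type]
            means[rows, :] = 0.0  # exclusive: silent in every other type
            means[rows, j] = marker_level
            marker_genes[t.name] = sorted(gene_ids[r] for r in rows)

    theta = 1.0 / cfg.nb_dispersion
    blocks = []
    labels: list[str] = []
    for j, t in enumerate(cfg.types):
        mu = means[:, j][:, None]
        p = theta / (theta + np.where(mu > 0, mu, 1.0))
        counts = count_rng.negative_binomial(theta, p, size=(G, t.n_cells))
        counts[means[:, j] == 0, :] = 0
        blocks.append(counts)
        labels.extend([t.name] * t.n_cells)
    X = np.concatenate(blocks, axis=1).astype(np.float64)

    if cfg.dropout_rate >= 0:
        u = dropout_rng.uniform(size=X.shape)
        X[u < cfg.dropout_rate] = 0.0

    cell_ids = [f"cell{i:05d}" for i in range(X.shape[1])]
    return SimData(
        X=ExpressionMatrix(X, gene_ids, cell_ids, is_normalized=False),
        y=LabelVector(labels),
        marker_genes=marker_genes,
        type_means=means,
        type_names=[t.name for t in cfg.types],
    )


def simulate(cfg: SimConfig) -> tuple[ExpressionMatrix, LabelVector]:
    """Counts and labels only; see :func:`simulate_full` for the ground truth."""
    sim = simulate_full(cfg)
    return sim.X, sim.y


def split(
    X: ExpressionMatrix,
    y: LabelVector,
    train_fraction: float,
    test_size: int,
    seed: int,
) -> tuple[tuple[ExpressionMatrix, LabelVector], tuple[ExpressionMatrix, LabelVector]]:
    """Stratified disjoint train/test split.

    Per type, a ``train_fraction`` share of cells (at least one) is drawn for
    training; the test set of ``test_size`` cells is then drawn from the
    remainder with per-type counts proportional to the remaining pool.
    """
    if not (0.0 < train_fraction < 1.0):
        raise DataError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = y.as_array()
    train_idx: list[np.ndarray] = []
    rest: dict[str, np.ndarray] = {}
    for k in y.label_set:
        idx = rng.permutation(np.flatnonzero(labels == k))
        n_tr = max(1, int(np.floor(train_fraction * idx.size)))
        if n_tr >= idx.size:
            raise DataError(f"type {k!r}: no cells left for testing after the split")
        train_idx.append(idx[:n_tr])
        rest[k] = idx[n_tr:]
    pool_total = sum(v.size for v in rest.values())
    if test_size > pool_total:
        raise DataError(
            f"test_size {test_size} exceeds the {pool_total} cells left after training"
        )
    # largest-remainder allocation of test cells across types
    quotas = {k: test_size * v.size / pool_total for k, v in rest.items()}
    take = {k: int(np.floor(q)) for k, q in quotas.items()}
    leftovers = sorted(quotas, key=lambda k: (quotas[k] - take[k], k), reverse=True)
    while sum(take.values()) < test_size:
        progressed = False
        for k in leftovers:
            if sum(take.values()) == test_size:
                break
            if take[k] < rest[k].size:
                take[k] += 1
                progressed = True
        if not progressed:
            break
    test_idx = [rest[k][: take[k]] for k in y.label_set]

    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return (
        (X.subset_cells(tr), y.subset(tr)),
        (X.subset_cells(te), y.subset(te)),
    )
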