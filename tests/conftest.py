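from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from lineagenn import (
    CellTypeSpec,
    SimConfig,
    TrainConfig,
    accuracy,
    adjusted_rand_index,
    annotate,
    simulate,
    split,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_matrix(values, gene_ids=None, cell_ids=None, normalized=False):
    from lineagenn import ExpressionMatrix

    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return ExpressionMatrix(
        values,
        gene_ids or [f"g{i}" for i in range(g)],
        cell_ids or [f"c{i}" for i in range(n)],
        is_normalized=normalized,
    )


@pytest.fixture
def tiny_matrix():
    return make_matrix([[1.0, 0.0], [2.0, 3.0], [0.0, 5.0]])


def _run_fixture(cfg: SimConfig, train_fraction: float, test_size: int, seed: int):
    X, y = simulate(cfg)
    (Xtr, ytr), (Xte, yte) = split(X, y, train_fraction, test_size, seed=seed)
    pred, report = annotate(Xtr, ytr, Xte, cfg=TrainConfig(rng_seed=seed))
    return {
        "pred": pred,
        "truth": yte,
        "train_labels": ytr,
        "report": report,
        "accuracy": accuracy(pred, yte),
        "ari": adjusted_rand_index(pred, yte),
    }


@pytest.fixture(scope="session")
def easy_run():
    """Four well-separated types, 500 cells each: the flat-mode regime."""
    cfg = SimConfig(types=[CellTypeSpec(n, 500) for n in "ABCD"], rng_seed=11)
    return _run_fixture(cfg, train_fraction=0.6, test_size=800, seed=11)


@pytest.fixture(scope="session")
def hard_run():
    """Two highly correlated types plus two distinct ones; 1000 training
    cells per type after the split: the hierarchical-mode regime."""
    cfg = SimConfig(
        types=[
            CellTypeSpec("A", 1250, "g1"),
            CellTypeSpec("B", 1250, "g1"),
            CellTypeSpec("C", 1250),
            CellTypeSpec("D", 1250),
        ],
        rng_seed=12,
    )
    return _run_fixture(cfg, train_fraction=0.8, test_size=800, seed=12)
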