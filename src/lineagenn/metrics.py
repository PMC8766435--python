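"""Scoring predicted labels against truth: accurately assigned rate and ARI."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import sklearn.metrics

from .containers import DataError, LabelVector


def _as_lists(pred, truth) -> tuple[list[str], list[str]]:
    p = pred.labels if isinstance(pred, LabelVector) else [str(x) for x in pred]
    t = truth.labels if isinstance(truth, LabelVector) else [str(x) for x in truth]
    if len(p) != len(t):
        raise DataError(f"length mismatch: {len(p)} predictions vs {len(t)} truths")
    return p, t


def accuracy(pred, truth) -> float:
    """Accurately assigned rate: the fraction of cells with an exact label match."""
    p, t = _as_lists(pred, truth)
    return float(np.mean([a == b for a, b in zip(p, t)]))


def adjusted_rand_index(pred, truth) -> float:
    """Hubert–Arabie adjusted Rand index between the two partitions.

    Chance-corrected pair-counting agreement; invariant to renaming labels
    in either vector, hence usable against unsupervised clusterings too.
    """
    p, t = _as_lists(pred, truth)
    if len(p) < 2:
        raise DataError("ARI needs at least two cells")
    return float(sklearn.metrics.adjusted_rand_score(t, p))


def confusion_table(pred, truth) -> pd.DataFrame:
    """Count table, rows = true types, columns = predicted types."""
    p, t = _as_lists(pred, truth)
    return pd.crosstab(
        pd.Series(t, name="true"), pd.Series(p, name="predicted"), dropna=False
    )


@dataclass
class EvaluationReport:
    accuracy: float
    ari: float
    confusion: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "ari": self.ari,
            "confusion": {
                str(r): {str(c): int(v) for c, v in row.items()}
                for r, row in self.confusion.to_dict(orient="index").items()
            },
        }


def evaluate(pred, truth) -> EvaluationReport:
    return EvaluationReport(
        accuracy=accuracy(pred, truth),
        ari=adjusted_rand_index(pred, truth),
        confusion=confusion_table(pred, truth),
    )
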