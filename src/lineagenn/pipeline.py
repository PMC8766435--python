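"""End-to-end orchestration: normalize, intersect, dispatch, train, predict.

The flow mirrors the method's schematic: from the training data compute
per-type mean profiles and their Pearson correlation matrix; if any two
types correlate at or above tau, train the lineage-tree hierarchical
annotator, otherwise a single flat multi-class network. Prediction is
exhaustive: every test cell receives exactly one training-set label.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

from .containers import DataError, ExpressionMatrix, LabelVector
from .hierarchy import (
    DEFAULT_M,
    DEFAULT_NU1,
    DEFAULT_NU2,
    DEFAULT_SEN_THRESHOLD,
    HierarchicalAnnotator,
    build_lineage_tree,
    marker_sensitivity,
    predict_hierarchical,
    train_hierarchy,
)
from .network import DenseClassifier, NetworkSpec, TrainConfig, build_network, predict, train
from .preprocess import intersect_genes, normalize
from .strategy import DEFAULT_TAU, correlation, mean_profiles, select_strategy

logger = logging.getLogger(__name__)


@dataclass
class AnnotatorParams:
    """Method parameters with their standard defaults."""

    tau: float = DEFAULT_TAU
    model_size: str = "small"
    nu1: int = DEFAULT_NU1
    nu2: int = DEFAULT_NU2
    n_features: int = DEFAULT_M
    sen_threshold: float = DEFAULT_SEN_THRESHOLD
    force_mode: str = "auto"  # {auto, flat, hierarchical}
    normalize_method: str = "lognorm"

    def __post_init__(self) -> None:
        if self.force_mode not in ("auto", "flat", "hierarchical"):
            raise ValueError(f"invalid force_mode {self.force_mode!r}")


@dataclass
class FlatAnnotator:
    classifier: DenseClassifier
    mode: str = "flat"


def train_annotator(
    X0: ExpressionMatrix,
    y0: LabelVector,
    params: AnnotatorParams,
    cfg: TrainConfig,
):
    """Train on an already-normalized training matrix; returns (annotator, info).

    ``info`` records the mode decision (chosen vs forced) and the maximal
    off-diagonal profile correlation that drove it.
    """
    if not X0.is_normalized:
        raise DataError("training matrix must be normalized before training")
    if y0.n_types < 2:
        raise DataError("training needs at least two cell types")
    prof = mean_profiles(X0, y0)
    P = correlation(prof)
    decision = select_strategy(P, tau=params.tau)
    mode = decision.mode if params.force_mode == "auto" else params.force_mode
    info = {
        "mode": mode,
        "forced": params.force_mode != "auto",
        "max_offdiag_correlation": decision.max_offdiag,
        "tau": params.tau,
        "n_types": y0.n_types,
        "n_train_cells": X0.n_cells,
        "n_genes": X0.n_genes,
    }
    spec = NetworkSpec.from_name(params.model_size)
    if mode == "flat":
        clf = build_network(spec, X0.n_genes, y0.n_types, seed=cfg.rng_seed)
        train(clf, X0, y0, cfg)
        return FlatAnnotator(classifier=clf), info
    tree = build_lineage_tree(prof)
    sens = marker_sensitivity(X0, y0, sen_threshold=params.sen_threshold, nu1=params.nu1)
    ann = train_hierarchy(
        X0, y0, tree, spec, cfg, sens=sens,
        M=params.n_features, nu1=params.nu1, nu2=params.nu2,
    )
    info["newick"] = tree.to_newick()
    return ann, info


def predict_annotator(annotator, X1: ExpressionMatrix) -> tuple[LabelVector, dict]:
    """Apply a trained annotator to a normalized test matrix."""
    if not X1.is_normalized:
        raise DataError("test matrix must be normalized before prediction")
    if isinstance(annotator, FlatAnnotator):
        pred, _probs = predict(annotator.classifier, X1)
        return pred, {"n_preassigned": 0, "n_routed": X1.n_cells}
    if isinstance(annotator, HierarchicalAnnotator):
        pred, details = predict_hierarchical(annotator, X1, return_details=True)
        return pred, details
    raise TypeError(f"unknown annotator type {type(annotator)!r}")


def annotate(
    X0_raw: ExpressionMatrix,
    y0: LabelVector,
    X1_raw: ExpressionMatrix,
    params: AnnotatorParams | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[LabelVector, dict]:
    """Full train-and-predict flow on raw matrices.

    Returns the predicted labels for the test cells (aligned to
    ``X1_raw.cell_ids``) and a run report.
    """
    params = params or AnnotatorParams()
    cfg = cfg or TrainConfig()
    X0 = normalize(X0_raw, method=params.normalize_method)
    X1 = normalize(X1_raw, method=params.normalize_method)
    X0, X1 = intersect_genes(X0, X1)
    annotator, info = train_annotator(X0, y0, params, cfg)
    pred, details = predict_annotator(annotator, X1)
    counts: dict[str, int] = {}
    for lab in pred.labels:
        counts[lab] = counts.get(lab, 0) + 1
    report = {
        **info,
        **details,
        "n_test_cells": X1.n_cells,
        "predicted_type_counts": counts,
        "params": asdict(params),
        "train_config": asdict(cfg),
    }
    return pred, report
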