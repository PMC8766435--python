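"""Saving and loading trained annotators.

An annotator is written as a directory containing ``meta.json`` (schema
version, mode, parameters, gene/class orders, tree structure with per-node
features) and ``weights.npz`` (all weight/bias arrays, keyed by component).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .hierarchy import HierarchicalAnnotator, SensitivityTable, TreeNode
from .network import DenseClassifier, NetworkSpec, TrainConfig
from .pipeline import FlatAnnotator

SCHEMA_VERSION = 1


def _clf_meta(clf: DenseClassifier) -> dict:
    return {
        "spec": {"size_name": clf.spec.size_name, "hidden_widths": list(clf.spec.hidden_widths)},
        "gene_order": clf.gene_order,
        "class_order": clf.class_order,
        "n_layers": len(clf.weights),
        "loss_trace": clf.loss_trace,
    }


def _clf_arrays(clf: DenseClassifier, prefix: str, arrays: dict) -> None:
    for l, (W, b) in enumerate(zip(clf.weights, clf.biases)):
        arrays[f"{prefix}.W{l}"] = W
        arrays[f"{prefix}.b{l}"] = b


def _clf_from(meta: dict, prefix: str, arrays) -> DenseClassifier:
    spec = NetworkSpec(meta["spec"]["size_name"], tuple(meta["spec"]["hidden_widths"]))
    weights = [arrays[f"{prefix}.W{l}"] for l in range(meta["n_layers"])]
    biases = [arrays[f"{prefix}.b{l}"] for l in range(meta["n_layers"])]
    return DenseClassifier(
        spec=spec,
        weights=weights,
        biases=biases,
        gene_order=meta["gene_order"],
        class_order=meta["class_order"],
        loss_trace=list(meta.get("loss_trace", [])),
    )


def _tree_meta(node: TreeNode, counter: list[int], arrays: dict) -> dict:
    d: dict = {"leaf_names": list(node.leaf_names), "height": node.height}
    if not node.is_leaf:
        nid = counter[0]
        counter[0] += 1
        d["node_id"] = nid
        d["features"] = node.features
        if node.classifier is not None:
            d["classifier"] = _clf_meta(node.classifier)
            _clf_arrays(node.classifier, f"node{nid}", arrays)
        d["left"] = _tree_meta(node.left, counter, arrays)
        d["right"] = _tree_meta(node.right, counter, arrays)
    return d


def _tree_from(d: dict, arrays) -> TreeNode:
    node = TreeNode(leaf_names=tuple(d["leaf_names"]), height=d["height"])
    if "left" in d:
        node.left = _tree_from(d["left"], arrays)
        node.right = _tree_from(d["right"], arrays)
        node.features = d.get("features")
        if "classifier" in d:
            node.classifier = _clf_from(d["classifier"], f"node{d['node_id']}", arrays)
    return node


def save_annotator(annotator, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays: dict = {}
    if isinstance(annotator, FlatAnnotator):
        meta = {
            "schema_version": SCHEMA_VERSION,
            "mode": "flat",
            "classifier": _clf_meta(annotator.classifier),
        }
        _clf_arrays(annotator.classifier, "flat", arrays)
    elif isinstance(annotator, HierarchicalAnnotator):
        meta = {
            "schema_version": SCHEMA_VERSION,
            "mode": "hierarchical",
            "gene_ids": annotator.gene_ids,
            "type_names": annotator.type_names,
            "nu1": annotator.nu1,
            "nu2": annotator.nu2,
            "n_features": annotator.n_features,
            "spec": {
                "size_name": annotator.spec.size_name,
                "hidden_widths": list(annotator.spec.hidden_widths),
            },
            "cfg": vars(annotator.cfg),
            "sensitivity": {
                "gene_ids": annotator.sensitivity.gene_ids,
                "type_names": annotator.sensitivity.type_names,
                "threshold": annotator.sensitivity.threshold,
                "nu1": annotator.sensitivity.nu1,
                "marker_sets": annotator.sensitivity.marker_sets,
                "eligible_types": annotator.sensitivity.eligible_types,
            },
            "tree": _tree_meta(annotator.tree, [0], arrays),
        }
        arrays["sensitivity.sen"] = annotator.sensitivity.sen
    else:
        raise TypeError(f"cannot serialize {type(annotator)!r}")
    np.savez(path / "weights.npz", **arrays)
    (path / "meta.json").write_text(json.dumps(meta))


def load_annotator(path):
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema {meta.get('schema_version')!r}")
    arrays = np.load(path / "weights.npz")
    if meta["mode"] == "flat":
        return FlatAnnotator(classifier=_clf_from(meta["classifier"], "flat", arrays))
    sens_meta = meta["sensitivity"]
    sens = SensitivityTable(
        sen=arrays["sensitivity.sen"],
        gene_ids=sens_meta["gene_ids"],
        type_names=sens_meta["type_names"],
        threshold=sens_meta["threshold"],
        nu1=sens_meta["nu1"],
        marker_sets=sens_meta["marker_sets"],
        eligible_types=sens_meta["eligible_types"],
    )
    return HierarchicalAnnotator(
        tree=_tree_from(meta["tree"], arrays),
        sensitivity=sens,
        spec=NetworkSpec(meta["spec"]["size_name"], tuple(meta["spec"]["hidden_widths"])),
        cfg=TrainConfig(**meta["cfg"]),
        gene_ids=meta["gene_ids"],
        type_names=meta["type_names"],
        nu1=meta["nu1"],
        nu2=meta["nu2"],
        n_features=meta["n_features"],
    )
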