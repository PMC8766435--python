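"""Lineage-tree hierarchical annotation for highly correlated cell types.

Training proceeds in four steps:

1. Complete-linkage agglomerative clustering of the per-type mean profiles
   (Euclidean distance between profile columns) yields a binary lineage tree
   with one leaf per cell type.
2. A gene-by-type sensitivity table Sen[g, k] — the fraction of cells
   expressing gene g that belong to type k — identifies type-exclusive
   markers (Sen > 0.95). Types with more than nu1 such markers are eligible
   for direct marker-based assignment.
3. At each bifurcation, genes are ranked by moderated t between the pooled
   left- and right-branch cells and the top M become that node's features.
4. A binary sigmoid-head network is trained per bifurcation on its feature
   subset, using only cells whose type belongs to the node's leaf set.

Prediction first assigns test cells that express more than nu2 markers of
exactly one eligible type; every remaining cell is routed root-to-leaf
through the binary classifiers (right branch iff p >= 0.5), so assignment
is exhaustive: no cell is left unassigned or stuck at an internal node.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy

from .containers import DataError, ExpressionMatrix, LabelVector
from .network import DenseClassifier, NetworkSpec, TrainConfig, build_network, _fit_array
from .preprocess import align_to_gene_order
from .strategy import ProfileMatrix

logger = logging.getLogger(__name__)

DEFAULT_SEN_THRESHOLD = 0.95
DEFAULT_NU1 = 10
DEFAULT_NU2 = 3
DEFAULT_M = 1000


@dataclass
class TreeNode:
    """A node of the binary lineage tree; leaves carry a single type name."""

    leaf_names: tuple[str, ...]
    height: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    features: list[str] | None = None
    classifier: DenseClassifier | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def internal_nodes(self) -> list["TreeNode"]:
        """Pre-order list of internal nodes."""
        if self.is_leaf:
            return []
        out = [self]
        out.extend(self.left.internal_nodes())
        out.extend(self.right.internal_nodes())
        return out

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def to_newick(self) -> str:
        def rec(node: TreeNode, parent_height: float) -> str:
            length = parent_height - node.height
            if node.is_leaf:
                return f"{node.leaf_names[0]}:{length:g}"
            inner = f"({rec(node.left, node.height)},{rec(node.right, node.height)})"
            return f"{inner}:{length:g}"

        if self.is_leaf:
            return f"{self.leaf_names[0]};"
        return f"({rec(self.left, self.height)},{rec(self.right, self.height)});"


def build_lineage_tree(prof: ProfileMatrix) -> TreeNode:
    """Complete-linkage tree over the profile columns (Euclidean distance).

    Merge order follows the linkage algorithm's deterministic output; within
    each merge record the first-listed cluster becomes the left child.
    """
    K = prof.A.shape[1]
    if K < 2:
        raise DataError("a lineage tree needs at least two cell types")
    Z = scipy.cluster.hierarchy.linkage(prof.A.T, method="complete", metric="euclidean")
    nodes: list[TreeNode] = [
        TreeNode(leaf_names=(name,), height=0.0) for name in prof.type_names
    ]
    for i, j, dist, _size in Z:
        a, b = nodes[int(i)], nodes[int(j)]
        nodes.append(
            TreeNode(
                leaf_names=tuple(a.leaf_names) + tuple(b.leaf_names),
                height=float(dist),
                left=a,
                right=b,
            )
        )
    return nodes[-1]


@dataclass
class SensitivityTable:
    """Sen[g, k] = (# cells of type k expressing g) / (# cells expressing g)."""

    sen: np.ndarray
    gene_ids: list[str]
    type_names: list[str]
    threshold: float = DEFAULT_SEN_THRESHOLD
    nu1: int = DEFAULT_NU1
    marker_sets: dict[str, list[str]] = field(default_factory=dict)
    eligible_types: list[str] = field(default_factory=list)


def marker_sensitivity(
    X0: ExpressionMatrix,
    y0: LabelVector,
    sen_threshold: float = DEFAULT_SEN_THRESHOLD,
    nu1: int = DEFAULT_NU1,
) -> SensitivityTable:
    """Compute the sensitivity table and the per-type exclusive marker sets.

    Only positivity (X > 0) is used, so raw and log-normalized inputs give
    identical tables. Genes expressed in zero cells get Sen = 0 everywhere.
    """
    if nu1 < 0:
        raise ValueError("nu1 must be non-negative")
    expressed = X0.values > 0
    denom = expressed.sum(axis=1).astype(np.float64)
    labels = y0.as_array()
    cols = []
    for k in y0.label_set:
        num = expressed[:, labels == k].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cols.append(np.where(denom > 0, num / denom, 0.0))
    sen = np.column_stack(cols)
    marker_sets: dict[str, list[str]] = {}
    eligible = []
    for j, k in enumerate(y0.label_set):
        genes = [X0.gene_ids[g] for g in np.flatnonzero(sen[:, j] > sen_threshold)]
        marker_sets[k] = genes
        if len(genes) > nu1:
            eligible.append(k)
    return SensitivityTable(
        sen=sen,
        gene_ids=list(X0.gene_ids),
        type_names=list(y0.label_set),
        threshold=sen_threshold,
        nu1=nu1,
        marker_sets=marker_sets,
        eligible_types=eligible,
    )


def marker_preassign(
    X1: ExpressionMatrix,
    sens: SensitivityTable,
    nu1: int = DEFAULT_NU1,
    nu2: int = DEFAULT_NU2,
) -> list[str | None]:
    """Pre-assign test cells by type-exclusive markers.

    A cell gets type k iff k is eligible (more than nu1 markers) and the
    cell expresses strictly more than nu2 of k's markers and k is the only
    such type; otherwise the cell is deferred to the tree (``None``).
    Marker genes absent from the test matrix contribute nothing.
    """
    if nu1 < 0 or nu2 < 0:
        raise ValueError("nu1 and nu2 must be non-negative")
    eligible = [k for k in sens.type_names if len(sens.marker_sets.get(k, [])) > nu1]
    gene_pos = {g: i for i, g in enumerate(X1.gene_ids)}
    counts = np.zeros((X1.n_cells, len(eligible)), dtype=int)
    for j, k in enumerate(eligible):
        rows = [gene_pos[g] for g in sens.marker_sets[k] if g in gene_pos]
        if rows:
            counts[:, j] = (X1.values[rows, :] > 0).sum(axis=0)
    assigned: list[str | None] = [None] * X1.n_cells
    hits = counts > nu2
    for c in range(X1.n_cells):
        js = np.flatnonzero(hits[c])
        if js.size == 1:
            assigned[c] = eligible[js[0]]
    return assigned


def bifurcation_features(
    X0: ExpressionMatrix, y0: LabelVector, node: TreeNode, M: int = DEFAULT_M
) -> list[str]:
    """Top-``min(M, G)`` genes separating the node's left and right branches.

    Ranking is by absolute moderated t-statistic between the pooled branch
    cells, descending, with ties broken by gene id so the output is
    deterministic. A branch with fewer than two cells falls back to an
    unmoderated mean-difference ranking (with a warning).
    """
    from .diffexpr import mean_difference, moderated_t

    labels = y0.as_array()
    lmask = np.isin(labels, list(node.left.leaf_names))
    rmask = np.isin(labels, list(node.right.leaf_names))
    n1, n2 = int(lmask.sum()), int(rmask.sum())
    if n1 == 0 or n2 == 0:
        raise DataError(
            f"empty branch at node {node.leaf_names}: left={n1} right={n2} cells"
        )
    left_vals = X0.values[:, lmask]
    right_vals = X0.values[:, rmask]
    if n1 < 2 or n2 < 2:
        logger.warning(
            "branch with < 2 cells at node %s; using unmoderated mean-difference ranking",
            node.leaf_names,
        )
        stat = mean_difference(left_vals, right_vals)
    else:
        stat = moderated_t(left_vals, right_vals)
    score = np.abs(stat)
    score = np.where(np.isfinite(score), score, np.inf)
    gene_arr = np.asarray(X0.gene_ids, dtype=object)
    # sort by (-|t|, gene_id); lexsort keys are last-key-primary
    order = np.lexsort((gene_arr, -score))
    m = min(M, X0.n_genes)
    return [X0.gene_ids[i] for i in order[:m]]


def _node_seed(base_seed: int, node: TreeNode) -> int:
    tag = f"{base_seed}:node:" + "|".join(node.leaf_names)
    return zlib.crc32(tag.encode()) % (2**31)


@dataclass
class HierarchicalAnnotator:
    """Trained lineage-tree annotator: marker table plus per-node binary nets."""

    tree: TreeNode
    sensitivity: SensitivityTable
    spec: NetworkSpec
    cfg: TrainConfig
    gene_ids: list[str]
    type_names: list[str]
    nu1: int = DEFAULT_NU1
    nu2: int = DEFAULT_NU2
    n_features: int = DEFAULT_M

    mode: str = "hierarchical"


def train_hierarchy(
    X0: ExpressionMatrix,
    y0: LabelVector,
    tree: TreeNode,
    spec: NetworkSpec,
    cfg: TrainConfig,
    sens: SensitivityTable | None = None,
    M: int = DEFAULT_M,
    nu1: int = DEFAULT_NU1,
    nu2: int = DEFAULT_NU2,
) -> HierarchicalAnnotator:
    """Train one binary network per bifurcation of the tree.

    Each node trains only on cells whose true type lies in its leaf set,
    using that node's selected features; the target is 1 for the right
    branch. Node seeds are derived deterministically from the config seed
    and the node's leaf set.
    """
    if sens is None:
        sens = marker_sensitivity(X0, y0, nu1=nu1)
    labels = y0.as_array()
    gene_pos = {g: i for i, g in enumerate(X0.gene_ids)}
    for node in tree.internal_nodes():
        try:
            feats = bifurcation_features(X0, y0, node, M=M)
            rows = np.array([gene_pos[g] for g in feats], dtype=int)
            in_node = np.isin(labels, list(node.leaf_names))
            Xa = X0.values[np.ix_(rows, np.flatnonzero(in_node))].T
            targets = np.isin(labels[in_node], list(node.right.leaf_names)).astype(float)
            clf = build_network(spec, len(feats), 1, seed=_node_seed(cfg.rng_seed, node))
            node_cfg = TrainConfig(
                batch_size=cfg.batch_size,
                epochs=cfg.epochs,
                learning_rate=cfg.learning_rate,
                rms_decay=cfg.rms_decay,
                rms_eps=cfg.rms_eps,
                rng_seed=_node_seed(cfg.rng_seed + 1, node),
                validation_fraction=0.0,
            )
            _fit_array(clf, Xa, targets, node_cfg)
            clf.gene_order = feats
            node.features = feats
            node.classifier = clf
        except Exception as exc:
            raise DataError(
                f"training failed at tree node {node.leaf_names}: {exc}"
            ) from exc
    return HierarchicalAnnotator(
        tree=tree,
        sensitivity=sens,
        spec=spec,
        cfg=cfg,
        gene_ids=list(X0.gene_ids),
        type_names=list(y0.label_set),
        nu1=nu1,
        nu2=nu2,
        n_features=M,
    )


def predict_hierarchical(
    h: HierarchicalAnnotator,
    X1: ExpressionMatrix,
    nu1: int | None = None,
    nu2: int | None = None,
    return_details: bool = False,
):
    """Annotate every test cell: marker pre-assignment, then tree routing.

    Pre-assigned cells keep their marker label and never enter the tree.
    Deferred cells descend from the root; at each node the binary classifier
    sends a cell right iff its predicted right-branch probability is >= 0.5.
    Every cell ends at a leaf, so the output has no unassigned entries.
    """
    nu1 = h.nu1 if nu1 is None else nu1
    nu2 = h.nu2 if nu2 is None else nu2
    assigned = marker_preassign(X1, h.sensitivity, nu1=nu1, nu2=nu2)
    n_pre = sum(a is not None for a in assigned)

    vals, missing = align_to_gene_order(X1, h.gene_ids)
    gene_pos = {g: i for i, g in enumerate(h.gene_ids)}
    deferred = np.array([i for i, a in enumerate(assigned) if a is None], dtype=int)
    out: list[str | None] = list(assigned)

    def route(node: TreeNode, idx: np.ndarray) -> None:
        if idx.size == 0:
            return
        if node.is_leaf:
            for i in idx:
                out[i] = node.leaf_names[0]
            return
        if node.classifier is None or node.features is None:
            raise DataError(f"untrained node {node.leaf_names}")
        rows = np.array([gene_pos[g] for g in node.features], dtype=int)
        if missing[rows].all():
            raise DataError(
                f"none of node {node.leaf_names}'s features are present in the test matrix"
            )
        p = node.classifier.predict_proba_array(vals[np.ix_(rows, idx)].T)[:, 0]
        go_right = p >= 0.5
        route(node.right, idx[go_right])
        route(node.left, idx[~go_right])

    route(h.tree, deferred)
    result = LabelVector([str(a) for a in out], label_set=list(h.type_names))
    if return_details:
        return result, {"n_preassigned": n_pre, "n_routed": int(deferred.size)}
    return result
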