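from __future__ import annotations

import numpy as np
import pytest

from lineagenn import DataError, LabelVector, NetworkSpec, TrainConfig
from lineagenn.hierarchy import (
    SensitivityTable,
    build_lineage_tree,
    bifurcation_features,
    marker_preassign,
    marker_sensitivity,
    predict_hierarchical,
    train_hierarchy,
)
from lineagenn.strategy import ProfileMatrix

from conftest import make_matrix
from oracles import complete_linkage_merges, sensitivity_direct, welch_t_direct


class TestLineageTree:
    def test_two_types_single_bifurcation(self):
        prof = ProfileMatrix(np.array([[0.0, 1.0], [0.0, 2.0]]), ["a", "b"])
        tree = build_lineage_tree(prof)
        assert not tree.is_leaf
        assert tree.left.is_leaf and tree.right.is_leaf
        assert set(tree.leaf_names) == {"a", "b"}

    def test_tight_pairs_merge_first(self):
        # two pairs: {a,b} within 0.1, {c,d} within 0.1, pairs 10 apart
        A = np.array([[0.0, 0.1, 10.0, 10.1], [0.0, 0.0, 0.0, 0.0]])
        tree = build_lineage_tree(ProfileMatrix(A, ["a", "b", "c", "d"]))
        child_sets = {frozenset(tree.left.leaf_names), frozenset(tree.right.leaf_names)}
        assert child_sets == {frozenset({"a", "b"}), frozenset({"c", "d"})}

    @pytest.mark.parametrize("K", [2, 5, 8, 12])
    def test_leaf_and_internal_node_counts(self, K):
        rng = np.random.default_rng(K)
        prof = ProfileMatrix(rng.normal(size=(20, K)), [f"t{i}" for i in range(K)])
        tree = build_lineage_tree(prof)
        assert len(tree.leaves()) == K
        assert len(tree.internal_nodes()) == K - 1

    @pytest.mark.parametrize("K", [3, 4, 5, 6])
    def test_matches_brute_force_agglomerative_oracle(self, K):
        rng = np.random.default_rng(100 + K)
        for _ in range(5):
            A = rng.normal(size=(8, K))
            names = [f"t{i}" for i in range(K)]
            tree = build_lineage_tree(ProfileMatrix(A, names))
            expected = complete_linkage_merges(A.T, names)
            key = lambda t: (t[1], tuple(sorted(t[0])))
            ours = sorted(
                (
                    (frozenset(n.left.leaf_names) | frozenset(n.right.leaf_names), n.height)
                    for n in tree.internal_nodes()
                ),
                key=key,
            )
            theirs = sorted(((l | r, h) for l, r, h in expected), key=key)
            assert [m for m, _ in ours] == [m for m, _ in theirs]
            np.testing.assert_allclose(
                [h for _, h in ours], [h for _, h in theirs], rtol=1e-10
            )

    def test_newick_export_lists_all_leaves(self):
        rng = np.random.default_rng(2)
        names = [f"t{i}" for i in range(5)]
        tree = build_lineage_tree(ProfileMatrix(rng.normal(size=(10, 5)), names))
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for nm in names:
            assert nm in nwk

    def test_single_type_rejected(self):
        with pytest.raises(DataError):
            ProfileMatrix(np.ones((3, 1)), ["only"])


class TestSensitivity:
    def test_exclusive_gene_is_fully_sensitive(self):
        X = make_matrix([[1.0, 2.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0]])
        y = LabelVector(["k", "k", "j", "j"])
        sens = marker_sensitivity(X, y, nu1=0)
        k_col = sens.type_names.index("k")
        j_col = sens.type_names.index("j")
        assert sens.sen[0, k_col] == 1.0
        assert sens.sen[0, j_col] == 0.0

    def test_unexpressed_gene_zero_everywhere(self):
        X = make_matrix([[0.0, 0.0], [1.0, 1.0]])
        y = LabelVector(["a", "b"])
        sens = marker_sensitivity(X, y)
        np.testing.assert_array_equal(sens.sen[0], [0.0, 0.0])

    def test_partial_sensitivity_three_quarters(self):
        X = make_matrix([[2.0, 1.0, 3.0, 5.0]])
        y = LabelVector(["k", "k", "k", "j"])
        sens = marker_sensitivity(X, y)
        assert sens.sen[0, sens.type_names.index("k")] == pytest.approx(0.75)

    def test_column_sum_is_one_for_expressed_genes(self):
        rng = np.random.default_rng(0)
        X = make_matrix(rng.poisson(0.5, size=(50, 40)).astype(float))
        y = LabelVector(list(rng.choice(["a", "b", "c"], size=40)))
        sens = marker_sensitivity(X, y)
        expressed = (X.values > 0).any(axis=1)
        np.testing.assert_allclose(sens.sen[expressed].sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(sens.sen[~expressed].sum(axis=1), 0.0)

    def test_matches_cell_by_cell_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.poisson(0.8, size=(20, 30)).astype(float)
        labels = list(rng.choice(["a", "b"], size=30))
        X = make_matrix(vals)
        y = LabelVector(labels)
        sens = marker_sensitivity(X, y)
        for g in range(20):
            for j, k in enumerate(sens.type_names):
                assert sens.sen[g, j] == pytest.approx(
                    sensitivity_direct(vals, labels, g, k), abs=1e-12
                )

    def test_eligibility_requires_more_than_nu1_markers(self):
        # type k has exactly 11 exclusive genes, type j has 3
        vals = np.zeros((14, 4))
        vals[:11, :2] = 1.0
        vals[11:, 2:] = 1.0
        X = make_matrix(vals)
        y = LabelVector(["k", "k", "j", "j"])
        sens = marker_sensitivity(X, y, nu1=10)
        assert sens.eligible_types == ["k"]
        assert len(sens.marker_sets["k"]) == 11


def _sens_table(marker_sets, gene_ids, type_names, nu1=10):
    return SensitivityTable(
        sen=np.zeros((len(gene_ids), len(type_names))),
        gene_ids=gene_ids,
        type_names=type_names,
        nu1=nu1,
        marker_sets=marker_sets,
        eligible_types=[k for k, v in marker_sets.items() if len(v) > nu1],
    )


class TestMarkerPreassign:
    def setup_method(self):
        self.genes = [f"m{i}" for i in range(11)] + ["other"]
        self.sens = _sens_table(
            {"k": self.genes[:11], "j": []}, self.genes, ["j", "k"], nu1=10
        )

    def _cell(self, n_markers):
        vals = np.zeros((12, 1))
        vals[:n_markers, 0] = 1.0
        return make_matrix(vals, gene_ids=self.genes)

    def test_four_markers_assigns(self):
        assert marker_preassign(self._cell(4), self.sens) == ["k"]

    def test_exactly_three_markers_defers(self):
        assert marker_preassign(self._cell(3), self.sens) == [None]

    def test_ambiguous_cell_defers(self):
        genes = [f"a{i}" for i in range(11)] + [f"b{i}" for i in range(11)]
        sens = _sens_table({"x": genes[:11], "y": genes[11:]}, genes, ["x", "y"])
        vals = np.ones((22, 1))  # expresses all markers of both types
        X = make_matrix(vals, gene_ids=genes)
        assert marker_preassign(X, sens) == [None]

    def test_absent_markers_contribute_nothing(self):
        X = make_matrix(np.ones((1, 1)), gene_ids=["unrelated"])
        assert marker_preassign(X, self.sens) == [None]

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            marker_preassign(self._cell(4), self.sens, nu1=-1)


class TestBifurcationFeatures:
    def _node(self, left_names, right_names):
        from lineagenn.hierarchy import TreeNode

        return TreeNode(
            leaf_names=tuple(left_names) + tuple(right_names),
            left=TreeNode(leaf_names=tuple(left_names)),
            right=TreeNode(leaf_names=tuple(right_names)),
        )

    def test_planted_genes_all_recovered(self):
        rng = np.random.default_rng(3)
        G, n = 2000, 60
        vals = rng.normal(5, 1, size=(G, n))
        vals[:50, : n // 2] += 5.0  # 50 planted genes, 5-sigma shift
        vals = np.abs(vals)
        X = make_matrix(vals)
        y = LabelVector(["L"] * (n // 2) + ["R"] * (n // 2))
        feats = bifurcation_features(X, y, self._node(["L"], ["R"]), M=1000)
        planted = {f"g{i}" for i in range(50)}
        assert planted <= set(feats)
        # Welch-t oracle agrees that the planted genes rank highest
        w = np.abs(welch_t_direct(vals[:, : n // 2], vals[:, n // 2 :]))
        top_welch = set(np.argsort(-w)[:50])
        assert top_welch == set(range(50))

    def test_min_clamp_returns_all_genes(self):
        rng = np.random.default_rng(4)
        X = make_matrix(np.abs(rng.normal(1, 0.3, size=(200, 20))))
        y = LabelVector(["L"] * 10 + ["R"] * 10)
        feats = bifurcation_features(X, y, self._node(["L"], ["R"]), M=1000)
        assert len(feats) == 200
        assert len(set(feats)) == 200

    def test_deterministic_under_ties(self):
        X = make_matrix(np.ones((30, 10)) + np.eye(30, 10) * 0)  # identical groups
        y = LabelVector(["L"] * 5 + ["R"] * 5)
        f1 = bifurcation_features(X, y, self._node(["L"], ["R"]), M=10)
        f2 = bifurcation_features(X, y, self._node(["L"], ["R"]), M=10)
        assert f1 == f2
        assert f1 == sorted(f1)  # pure ties fall back to gene-id order

    def test_tiny_branch_falls_back_with_warning(self, caplog):
        import logging

        X = make_matrix(np.abs(np.random.default_rng(0).normal(1, 1, size=(20, 4))))
        y = LabelVector(["L", "R", "R", "R"])
        with caplog.at_level(logging.WARNING, logger="lineagenn.hierarchy"):
            feats = bifurcation_features(X, y, self._node(["L"], ["R"]), M=5)
        assert len(feats) == 5
        assert "mean-difference" in caplog.text

    def test_empty_branch_rejected(self):
        X = make_matrix(np.ones((5, 2)))
        y = LabelVector(["L", "L"], label_set=["L", "R"])
        with pytest.raises(DataError, match="empty branch"):
            bifurcation_features(X, y, self._node(["L"], ["R"]))


def _separable_dataset(K, n_per=40, seed=0):
    """K types, each with a block of exclusive strongly expressed genes."""
    rng = np.random.default_rng(seed)
    G = K * 30
    vals = np.abs(rng.normal(0.2, 0.1, size=(G, K * n_per)))
    labels = []
    for k in range(K):
        cols = slice(k * n_per, (k + 1) * n_per)
        vals[k * 30 : (k + 1) * 30, cols] += 5.0
        labels += [f"t{k}"] * n_per
    return make_matrix(vals, normalized=True), LabelVector(labels)


class TestTrainPredictHierarchy:
    def test_k4_tree_has_three_trained_nodes(self):
        X, y = _separable_dataset(4)
        from lineagenn.strategy import mean_profiles

        tree = build_lineage_tree(mean_profiles(X, y))
        ann = train_hierarchy(
            X, y, tree, NetworkSpec.from_name("small"),
            TrainConfig(epochs=5, batch_size=32, rng_seed=0), M=50,
        )
        nodes = ann.tree.internal_nodes()
        assert len(nodes) == 3
        assert all(n.classifier is not None and n.features for n in nodes)

    def test_separable_types_routed_correctly(self):
        X, y = _separable_dataset(2, seed=1)
        from lineagenn.strategy import mean_profiles

        tree = build_lineage_tree(mean_profiles(X, y))
        ann = train_hierarchy(
            X, y, tree, NetworkSpec.from_name("small"),
            TrainConfig(epochs=10, batch_size=16, rng_seed=1), M=30,
        )
        pred = predict_hierarchical(ann, X)
        assert pred.labels == y.labels

    def test_marker_preassignment_short_circuits_tree(self):
        X, y = _separable_dataset(2, seed=2)
        from lineagenn.strategy import mean_profiles

        tree = build_lineage_tree(mean_profiles(X, y))
        ann = train_hierarchy(
            X, y, tree, NetworkSpec.from_name("small"),
            TrainConfig(epochs=3, batch_size=16, rng_seed=2), M=30,
        )
        # force a sensitivity table that pre-assigns every cell to 't0'
        ann.sensitivity = _sens_table(
            {"t0": X.gene_ids[:11], "t1": []}, list(X.gene_ids), ["t0", "t1"]
        )
        pred = predict_hierarchical(ann, X)
        # the t0-markers are the first 30 genes: expressed in t0 cells only
        t0_cells = [i for i, lab in enumerate(y.labels) if lab == "t0"]
        assert all(pred.labels[i] == "t0" for i in t0_cells)

    def test_probability_half_routes_right(self):
        from lineagenn.hierarchy import HierarchicalAnnotator, TreeNode
        from lineagenn.network import build_network

        left = TreeNode(leaf_names=("l",))
        right = TreeNode(leaf_names=("r",))
        clf = build_network(NetworkSpec("micro", (2,)), 1, 1, seed=0)
        clf.weights = [np.zeros((1, 2)), np.zeros((2, 1))]
        clf.biases = [np.zeros(2), np.zeros(1)]  # sigmoid(0) = 0.5 exactly
        root = TreeNode(
            leaf_names=("l", "r"), left=left, right=right,
            features=["g0"], classifier=clf,
        )
        ann = HierarchicalAnnotator(
            tree=root,
            sensitivity=_sens_table({}, ["g0"], ["l", "r"]),
            spec=NetworkSpec("micro", (2,)),
            cfg=TrainConfig(),
            gene_ids=["g0"],
            type_names=["l", "r"],
        )
        X = make_matrix([[1.0]], gene_ids=["g0"], normalized=True)
        assert predict_hierarchical(ann, X).labels == ["r"]

    def test_output_exhaustive_and_within_training_labels(self):
        X, y = _separable_dataset(3, seed=3)
        from lineagenn.strategy import mean_profiles

        tree = build_lineage_tree(mean_profiles(X, y))
        ann = train_hierarchy(
            X, y, tree, NetworkSpec.from_name("small"),
            TrainConfig(epochs=4, batch_size=32, rng_seed=3), M=40,
        )
        pred = predict_hierarchical(ann, X)
        assert len(pred.labels) == X.n_cells
        assert set(pred.labels) <= set(y.label_set)

    def test_serialization_round_trip(self, tmp_path):
        from lineagenn.serialize import load_annotator, save_annotator
        from lineagenn.strategy import mean_profiles

        X, y = _separable_dataset(3, seed=4)
        tree = build_lineage_tree(mean_profiles(X, y))
        ann = train_hierarchy(
            X, y, tree, NetworkSpec.from_name("small"),
            TrainConfig(epochs=4, batch_size=32, rng_seed=4), M=40,
        )
        save_annotator(ann, tmp_path / "model")
        back = load_annotator(tmp_path / "model")
        p1 = predict_hierarchical(ann, X)
        p2 = predict_hierarchical(back, X)
        assert p1.labels == p2.labels
        for n1, n2 in zip(ann.tree.internal_nodes(), back.tree.internal_nodes()):
            assert n1.features == n2.features
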