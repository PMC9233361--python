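import dendropy
import numpy as np
import pandas as pd
import pytest

import specrqe as sq


class TestVectorToDissim:
    def test_identical_samples_give_zero_matrix(self):
        D = sq.vector_to_dissim([0.0, 0.0, 0.0])
        assert np.array_equal(D.values, np.zeros((3, 3)))

    def test_absolute_difference(self):
        D = sq.vector_to_dissim([100.0, 300.0], labels=["a", "b"])
        assert D.values[0, 1] == 200.0

    def test_matches_double_loop(self, rng):
        x = rng.uniform(0, 1000, 20)
        D = sq.vector_to_dissim(x)
        brute = np.array([[abs(xi - xj) for xj in x] for xi in x])
        assert np.allclose(D.values, brute)

    def test_nonfinite_entry_names_sample(self):
        with pytest.raises(ValueError, match="s1"):
            sq.vector_to_dissim([1.0, np.nan, 2.0], labels=["s0", "s1", "s2"])

    def test_constant_vector_accepted_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="specrqe"):
            D = sq.vector_to_dissim([5.0, 5.0, 5.0])
        assert np.all(D.values == 0)
        assert any("constant" in r.message for r in caplog.records)


def _climb_to_root(leaf):
    """(node, distance-from-leaf) pairs, leaf upward — an independent path oracle."""
    out, d, node = [], 0.0, leaf
    while node is not None:
        out.append((node, d))
        if node.edge.length is not None:
            d += node.edge.length
        node = node.parent_node
    return out


def _random_newick(labels, rng):
    if len(labels) == 1:
        return f"{labels[0]}:{rng.uniform(0.1, 2.0):.6f}"
    k = int(rng.integers(1, len(labels)))
    left = _random_newick(labels[:k], rng)
    right = _random_newick(labels[k:], rng)
    return f"({left},{right}):{rng.uniform(0.1, 2.0):.6f}"


class TestTreeToDissim:
    def test_same_tip_samples_have_zero_distance(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")
        st = sq.SampleTree(tree, {"s1": "A", "s2": "A", "s3": "C"})
        D = sq.tree_to_dissim(st, ["s1", "s2", "s3"])
        assert D.values[0, 1] == 0.0
        assert D.values[0, 2] > 0

    def test_caterpillar_path_counting(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,C:1);", schema="newick")
        st = sq.SampleTree(tree, {"a": "A", "b": "B", "c": "C"})
        D = sq.tree_to_dissim(st, ["a", "b", "c"])
        assert D.values[0, 1] == 2.0  # A-B
        assert D.values[0, 2] == 3.0  # A-C
        assert D.values[1, 2] == 3.0  # B-C

    def test_random_tree_matches_path_sum_oracle(self, rng):
        labels = [f"T{i}" for i in range(10)]
        nwk = "(" + _random_newick(labels[:5], rng) + "," + _random_newick(labels[5:], rng) + ");"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        st = sq.SampleTree(tree, {l.lower(): l for l in labels})
        samples = [l.lower() for l in labels]
        D = sq.tree_to_dissim(st, samples)
        leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
        for i in range(10):
            for j in range(i + 1, 10):
                anc_i = _climb_to_root(leaves[labels[i]])
                anc_j = dict(_climb_to_root(leaves[labels[j]]))
                mrca_dist = next(di + anc_j[nd] for nd, di in anc_i if nd in anc_j)
                assert D.values[i, j] == pytest.approx(mrca_dist, rel=1e-9)

    def test_unknown_tip_names_sample(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        with pytest.raises(KeyError, match="s2"):
            sq.SampleTree(tree, {"s1": "A", "s2": "Z"})


def _three_level_ontology():
    """2 / 5 / 22 categories coarse to fine, consistent hierarchy."""
    l2_parent = {"a": "H", "b": "H", "c": "F", "d": "F", "e": "F"}
    rows = []
    for t in range(22):
        l2 = "abcde"[t % 5]
        rows.append({"L1": l2_parent[l2], "L2": l2, "L3": f"t{t:02d}"})
    # two samples per finest type
    recs = {}
    for i, r in enumerate(rows * 2):
        recs[f"s{i:02d}"] = r
    return pd.DataFrame.from_dict(recs, orient="index")


class TestOntoToTree:
    def test_three_level_shape(self):
        st = sq.onto_to_tree(_three_level_ontology())
        leaves = list(st.tree.leaf_node_iter())
        assert len(leaves) == 22
        for leaf in leaves:
            depth = 0
            node = leaf
            while node.parent_node is not None:
                depth += 1
                node = node.parent_node
            assert depth == 3
        assert all(e.length == 1.0 for e in st.tree.preorder_edge_iter()
                   if e.length is not None)

    def test_single_level_is_star_tree(self):
        onto = pd.DataFrame({"L1": ["x", "y", "z", "x"]},
                            index=["s0", "s1", "s2", "s3"])
        D = sq.tree_to_dissim(sq.onto_to_tree(onto), ["s0", "s1", "s2", "s3"])
        off = D.values[np.triu_indices(4, k=1)]
        assert set(off.tolist()) == {0.0, 2.0}
        assert D.values[0, 3] == 0.0  # same category

    def test_same_finest_category_zero_distance(self):
        onto = _three_level_ontology()
        D = sq.tree_to_dissim(sq.onto_to_tree(onto), list(onto.index))
        # s00 and s22 share the same L3 type by construction
        assert D.values[0, 22] == 0.0

    def test_row_order_invariance(self, rng):
        onto = _three_level_ontology()
        D1 = sq.tree_to_dissim(sq.onto_to_tree(onto), list(onto.index))
        shuffled = onto.sample(frac=1.0, random_state=5)
        D2 = sq.tree_to_dissim(sq.onto_to_tree(shuffled), list(onto.index))
        assert np.array_equal(D1.values, D2.values)

    def test_inconsistent_hierarchy_names_label(self):
        onto = pd.DataFrame(
            {"L1": ["H", "F"], "L2": ["dup", "dup"]}, index=["s0", "s1"]
        )
        with pytest.raises(ValueError, match="dup"):
            sq.onto_to_tree(onto)


class TestTableToDissim:
    def test_identical_rows_zero(self):
        t = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [0.0, 1.0]],
                         index=["a", "b", "c"])
        D = sq.table_to_dissim(t, metric="braycurtis")
        assert D.values[0, 1] == 0.0

    def test_disjoint_composition_is_one(self):
        t = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        D = sq.table_to_dissim(t, metric="braycurtis")
        assert D.values[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("metric", ["braycurtis", "euclidean"])
    def test_matches_textbook_double_loop(self, rng, metric):
        X = rng.random((8, 5)) + 0.01
        t = pd.DataFrame(X, index=[f"s{i}" for i in range(8)])
        D = sq.table_to_dissim(t, metric=metric)
        for i in range(8):
            for j in range(8):
                if metric == "braycurtis":
                    expect = np.abs(X[i] - X[j]).sum() / (X[i] + X[j]).sum()
                else:
                    expect = np.sqrt(((X[i] - X[j]) ** 2).sum())
                assert D.values[i, j] == pytest.approx(expect, abs=1e-12)

    def test_all_zero_sample_rejected_by_name(self):
        t = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            sq.table_to_dissim(t, metric="braycurtis")


class TestValidateDissim:
    def test_shuffled_matrix_realigned(self, rng):
        x = rng.random(6)
        labels = [f"s{i}" for i in range(6)]
        D = np.abs(x[:, None] - x[None, :])
        perm = rng.permutation(6)
        got = sq.validate_dissim(D[np.ix_(perm, perm)],
                                 [labels[i] for i in perm], order=labels)
        assert got.labels == tuple(labels)
        assert np.allclose(got.values, D)

    def test_asymmetry_beyond_tolerance_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="asymmetric"):
            sq.validate_dissim(D, ["a", "b"])

    def test_negative_entry_rejected(self):
        D = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="negative"):
            sq.validate_dissim(D, ["a", "b"])

    def test_nonzero_diagonal_rejected(self):
        D = np.array([[0.5, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            sq.validate_dissim(D, ["a", "b"])

    def test_extra_samples_dropped_missing_raise(self, caplog):
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        with caplog.at_level("WARNING", logger="specrqe"):
            got = sq.validate_dissim(D, ["a", "b", "c"], order=["a", "c"])
        assert got.labels == ("a", "c")
        assert got.values[0, 1] == 2.0
        with pytest.raises(KeyError, match="z"):
            sq.validate_dissim(D, ["a", "b", "c"], order=["a", "z"])

    def test_builders_output_passes_validation(self, rng):
        x = rng.random(8)
        D = sq.vector_to_dissim(x)
        again = sq.validate_dissim(D.values, list(D.labels))
        assert np.array_equal(again.values, D.values)
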