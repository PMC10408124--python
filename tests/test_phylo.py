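"""Neighbor joining against topology oracles; nearest-neighbor concordance.

Two independent oracles: (1) skbio's own NJ implementation, compared by
Robinson-Foulds distance; (2) for small n, exhaustive enumeration of all
unrooted binary topologies with least-squares branch-length fits — the
generating topology of an additive matrix must be the unique optimum and
must be what NJ returns.
"""

import io as _io
import itertools

import numpy as np
import pytest
import skbio

from rbpmosaic import DistanceMatrix, distances_from_identity, label_concordance, nj_tree
from rbpmosaic.phylo import PhyloError


# ---------------------------------------------------------------------------
# random additive matrices from random unrooted binary trees
# ---------------------------------------------------------------------------

def random_topology(ids, rng):
    """Unrooted binary tree as {frozenset bipartition: branch id}, built by
    sequential leaf insertion; returns (edge list, splits)."""
    # represent the tree by its set of nontrivial splits over `ids`
    # built via recursive neighbor grouping: random sequential insertion
    tree = {"kind": "leaf", "name": ids[0]}
    tree = {"kind": "node", "children": [tree, {"kind": "leaf", "name": ids[1]},
                                         {"kind": "leaf", "name": ids[2]}]}

    def edges(node):
        out = []
        for i, ch in enumerate(node["children"] if node["kind"] == "node" else []):
            out.append((node, i))
            out.extend(edges(ch))
        return out

    for name in ids[3:]:
        parent, i = edges(tree)[rng.integers(0, len(edges(tree)))]
        old = parent["children"][i]
        parent["children"][i] = {
            "kind": "node",
            "children": [old, {"kind": "leaf", "name": name}],
        }
    return tree


def tree_splits(tree, all_ids):
    """Nontrivial bipartitions of an unrooted tree (canonical frozensets)."""
    full = frozenset(all_ids)
    splits = set()

    def leafset(node):
        if node["kind"] == "leaf":
            return frozenset([node["name"]])
        return frozenset().union(*(leafset(c) for c in node["children"]))

    def walk(node):
        for ch in node["children"] if node["kind"] == "node" else []:
            ls = leafset(ch)
            if 1 < len(ls) < len(full) - 1:
                splits.add(min(ls, full - ls, key=sorted))
            if ch["kind"] == "node":
                walk(ch)
    walk(tree)
    return splits


def additive_distances(tree, ids, rng, min_len=0.05, max_len=0.3):
    """Assign random branch lengths; return the leaf-to-leaf path matrix."""
    lengths = {}

    def assign(node):
        for ch in node["children"] if node["kind"] == "node" else []:
            lengths[id(ch)] = rng.uniform(min_len, max_len)
            assign(ch)
    assign(tree)

    paths = {}

    def walk(node, depth_map):
        if node["kind"] == "leaf":
            paths[node["name"]] = depth_map
            return
        for ch in node["children"]:
            walk(ch, {**{k: v for k, v in depth_map.items()},
                      id(ch): lengths[id(ch)]})

    # distances via shared-edge cancellation: d(a,b) = sum of lengths of
    # edges on exactly one of the two root paths
    walk(tree, {})
    n = len(ids)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pa, pb = paths[ids[i]], paths[ids[j]]
        d = sum(v for k, v in pa.items() if k not in pb)
        d += sum(v for k, v in pb.items() if k not in pa)
        mat[i, j] = mat[j, i] = d
    return mat


def newick_splits(newick, all_ids):
    tree = skbio.TreeNode.read(_io.StringIO(newick))
    full = frozenset(all_ids)
    splits = set()
    for node in tree.non_tips(include_self=False):
        ls = frozenset(t.name for t in node.tips())
        if 1 < len(ls) < len(full) - 1:
            splits.add(min(ls, full - ls, key=sorted))
    return splits


def enumerate_topologies(ids):
    """All unrooted binary topologies over ids (recursive edge insertion)."""
    if len(ids) == 3:
        yield {"kind": "node", "children": [
            {"kind": "leaf", "name": i} for i in ids]}
        return
    import copy

    def all_edges(node):
        out = []
        if node["kind"] == "node":
            for i, ch in enumerate(node["children"]):
                out.append((node, i))
                out.extend(all_edges(ch))
        return out

    for base in enumerate_topologies(ids[:-1]):
        for k in range(len(all_edges(base))):
            t = copy.deepcopy(base)
            parent, i = all_edges(t)[k]
            old = parent["children"][i]
            parent["children"][i] = {
                "kind": "node",
                "children": [old, {"kind": "leaf", "name": ids[-1]}],
            }
            yield t


def ls_fit_error(tree, ids, mat):
    """Least-squares branch-fit residual of a topology to a matrix."""
    edge_ids = []

    def collect(node):
        if node["kind"] == "node":
            for ch in node["children"]:
                edge_ids.append(id(ch))
                collect(ch)
    collect(tree)

    leaf_paths = {}

    def walk(node, path):
        if node["kind"] == "leaf":
            leaf_paths[node["name"]] = set(path)
            return
        for ch in node["children"]:
            walk(ch, path + [id(ch)])
    walk(tree, [])

    pairs = list(itertools.combinations(range(len(ids)), 2))
    design = np.zeros((len(pairs), len(edge_ids)))
    target = np.zeros(len(pairs))
    col = {e: k for k, e in enumerate(edge_ids)}
    for row, (i, j) in enumerate(pairs):
        sym_diff = leaf_paths[ids[i]] ^ leaf_paths[ids[j]]
        for e in sym_diff:
            design[row, col[e]] = 1.0
        target[row] = mat[i, j]
    coef, residuals, *_ = np.linalg.lstsq(design, target, rcond=None)
    return float(np.sum((design @ coef - target) ** 2))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestDistances:
    def test_identity_maps_linearly_to_distance(self):
        ids = ["a", "b", "c"]
        identity = np.array(
            [[100.0, 100.0, 30.0], [100.0, 100.0, 55.0], [30.0, 55.0, 100.0]]
        )
        dm = distances_from_identity(ids, identity)
        assert dm.data[0, 1] == 0.0
        assert dm.data[0, 2] == pytest.approx(0.70)
        assert dm.data[1, 2] == pytest.approx(0.45)

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0.0, 0.1], [0.2, 0.0]])
        with pytest.raises(PhyloError, match="symmetric"):
            DistanceMatrix(("a", "b"), bad)


class TestNeighborJoining:
    def test_three_taxon_ultrametric_pairs_the_close_taxa(self):
        mat = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        newick = nj_tree(DistanceMatrix(("A", "B", "C"), mat))
        tree = skbio.TreeNode.read(_io.StringIO(newick))
        a = tree.find("A")
        assert {t.name for t in a.parent.tips()} >= {"A", "B"}

    def test_two_taxa_give_a_single_edge(self):
        newick = nj_tree(DistanceMatrix(("A", "B"), np.array([[0.0, 0.4],
                                                              [0.4, 0.0]])))
        tree = skbio.TreeNode.read(_io.StringIO(newick))
        assert {t.name for t in tree.tips()} == {"A", "B"}

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_recovers_generating_topology_of_additive_matrices(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            ids = [f"t{k}" for k in range(n)]
            tree = random_topology(ids, rng)
            mat = additive_distances(tree, ids, rng)
            newick = nj_tree(DistanceMatrix(tuple(ids), mat))
            assert newick_splits(newick, ids) == tree_splits(tree, ids)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_generating_topology_is_the_least_squares_optimum(self, n):
        """Cross-validates the additive-matrix construction: exhaustive
        least-squares over all unrooted topologies singles out the
        generating one, and NJ agrees."""
        rng = np.random.default_rng(100 + n)
        ids = [f"t{k}" for k in range(n)]
        tree = random_topology(ids, rng)
        mat = additive_distances(tree, ids, rng)
        fits = sorted(
            (ls_fit_error(t, ids, mat), tree_splits(t, ids))
            for t in enumerate_topologies(ids)
        )
        assert fits[0][0] == pytest.approx(0.0, abs=1e-18)
        assert fits[0][1] == tree_splits(tree, ids)
        newick = nj_tree(DistanceMatrix(tuple(ids), mat))
        assert newick_splits(newick, ids) == fits[0][1]

    def test_agrees_with_skbio_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for n in (5, 8):
            ids = [f"t{k}" for k in range(n)]
            tree = random_topology(ids, rng)
            mat = additive_distances(tree, ids, rng)
            ours = nj_tree(DistanceMatrix(tuple(ids), mat))
            theirs = skbio.tree.nj(skbio.DistanceMatrix(mat, ids))
            got = newick_splits(ours, ids)
            ref = {
                min(ls, frozenset(ids) - ls, key=sorted)
                for ls in (
                    frozenset(t.name for t in node.tips())
                    for node in theirs.non_tips(include_self=False)
                )
                if 1 < len(ls) < n - 1
            }
            assert got == ref

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(5)
        ids = [f"t{k}" for k in range(6)]
        tree = random_topology(ids, rng)
        mat = additive_distances(tree, ids, rng)
        perm = rng.permutation(6)
        ids_p = [ids[k] for k in perm]
        mat_p = mat[np.ix_(perm, perm)]
        a = newick_splits(nj_tree(DistanceMatrix(tuple(ids), mat)), ids)
        b = newick_splits(nj_tree(DistanceMatrix(tuple(ids_p), mat_p)), ids)
        assert a == b


class TestLabelConcordance:
    def test_two_separated_blocks_score_one(self):
        mat = np.array(
            [
                [0.0, 0.1, 0.9, 0.9],
                [0.1, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.1],
                [0.9, 0.9, 0.1, 0.0],
            ]
        )
        dm = DistanceMatrix(("a", "b", "c", "d"), mat)
        labels = {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        assert label_concordance(dm, labels) == 1.0

    def test_equidistant_matrix_uses_lexicographic_tie_break(self):
        # everyone's nearest neighbor resolves to the lexicographically
        # smallest other taxon: 'a' for everyone except 'a' itself ('b')
        mat = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(("a", "b", "c", "d"), mat)
        labels = {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        # a->b same label; b->a same; c->a differs; d->a differs
        assert label_concordance(dm, labels) == pytest.approx(0.5)

    def test_singleton_labels_excluded_from_denominator(self):
        mat = np.array(
            [[0.0, 0.1, 0.5], [0.1, 0.0, 0.5], [0.5, 0.5, 0.0]]
        )
        dm = DistanceMatrix(("a", "b", "c"), mat)
        labels = {"a": "X", "b": "X", "c": "solo"}
        assert label_concordance(dm, labels) == 1.0

    def test_all_singletons_is_an_error(self):
        mat = np.array([[0.0, 0.2], [0.2, 0.0]])
        dm = DistanceMatrix(("a", "b"), mat)
        with pytest.raises(PhyloError, match="singleton"):
            label_concordance(dm, {"a": "X", "b": "Y"})

    def test_invariant_to_taxon_reordering_and_relabeling(self):
        rng = np.random.default_rng(11)
        n = 7
        ids = [f"t{k}" for k in range(n)]
        raw = rng.uniform(0.1, 1.0, (n, n))
        mat = (raw + raw.T) / 2
        np.fill_diagonal(mat, 0.0)
        labels = {t: ["u", "v"][k % 2] for k, t in enumerate(ids)}
        base = label_concordance(DistanceMatrix(tuple(ids), mat), labels)
        perm = rng.permutation(n)
        ids_p = [ids[k] for k in perm]
        mat_p = mat[np.ix_(perm, perm)]
        renamed = {t: "label_" + labels[t] for t in ids}
        assert label_concordance(
            DistanceMatrix(tuple(ids_p), mat_p), renamed
        ) == pytest.approx(base)
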