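"""Distance corrections, neighbor joining vs brute-force topology enumeration,
and Newick serialization."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from s1domains import phylo


# ---------------------------------------------------------------- oracles

def enumerate_unrooted_topologies(n_leaves):
    """All leaf-labeled unrooted binary topologies as edge lists.

    Leaves are 0..n-1, internal nodes n, n+1, ...; built by inserting each
    new leaf into every edge of every smaller topology (1, 3, 15, 105 trees
    for n = 3..6).
    """
    base = 1000  # internal node ids, disjoint from leaf ids
    trees = [[(0, base), (1, base), (2, base)]]
    next_internal = base + 1
    for leaf in range(3, n_leaves):
        new_trees = []
        for edges in trees:
            for idx, (u, v) in enumerate(edges):
                w = next_internal
                new = edges[:idx] + edges[idx + 1 :] + [(u, w), (w, v), (leaf, w)]
                new_trees.append(new)
        trees = new_trees
        next_internal += 1
    return trees


def topology_splits(edges, n_leaves):
    """Non-trivial bipartitions (as canonical frozensets of leaf ids)."""
    adjacency = {}
    for u, v in edges:
        adjacency.setdefault(u, set()).add(v)
        adjacency.setdefault(v, set()).add(u)
    splits = set()
    all_leaves = frozenset(range(n_leaves))
    for u, v in edges:
        # component containing u with edge (u, v) removed
        seen = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            for y in adjacency[x]:
                if (x, y) in ((u, v), (v, u)):
                    continue
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(w for w in seen if w < n_leaves)
        other = all_leaves - side
        if 2 <= len(side) <= n_leaves - 2:
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def fit_branch_lengths(edges, n_leaves, dmat):
    """Least-squares branch lengths for one topology; returns residual."""
    adjacency = {}
    for idx, (u, v) in enumerate(edges):
        adjacency.setdefault(u, []).append((v, idx))
        adjacency.setdefault(v, []).append((u, idx))

    def path_edges(a, b):
        stack = [(a, [])]
        seen = {a}
        while stack:
            x, path = stack.pop()
            if x == b:
                return path
            for y, idx in adjacency[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append((y, path + [idx]))
        raise AssertionError("disconnected topology")

    pairs = list(itertools.combinations(range(n_leaves), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        for idx in path_edges(a, b):
            A[r, idx] = 1.0
        y[r] = dmat[a, b]
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.linalg.norm(A @ x - y))


def random_additive_matrix(n, rng):
    """Distance matrix from a random binary tree with positive branch lengths."""
    topo = rng.choice(len(enumerate_unrooted_topologies(n)))
    edges = enumerate_unrooted_topologies(n)[topo]
    lengths = rng.uniform(0.1, 2.0, size=len(edges))
    adjacency = {}
    for idx, (u, v) in enumerate(edges):
        adjacency.setdefault(u, []).append((v, lengths[idx]))
        adjacency.setdefault(v, []).append((u, lengths[idx]))
    d = np.zeros((n, n))
    for a in range(n):
        stack = [(a, 0.0)]
        seen = {a}
        while stack:
            x, dist = stack.pop()
            if x < n:
                d[a, x] = dist
            for y, l in adjacency[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append((y, dist + l))
    return d, topology_splits(edges, n)


# ---------------------------------------------------------------- tests

class TestIdentityToDistance:
    def test_full_identity_is_zero(self):
        assert phylo.identity_to_distance(1.0, "p") == 0.0
        assert phylo.identity_to_distance(1.0, "kimura") == 0.0

    def test_p_distance(self):
        assert phylo.identity_to_distance(0.75, "p") == pytest.approx(0.25)

    def test_kimura_closed_form(self):
        expected = -math.log(1 - 0.25 - 0.2 * 0.25**2)
        assert phylo.identity_to_distance(0.75, "kimura") == pytest.approx(expected)

    def test_kimura_undefined_for_distant_pairs(self):
        with pytest.raises(ValueError, match="undefined"):
            phylo.identity_to_distance(0.05, "kimura")


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        dm = phylo.DistanceMatrix(["A", "B"], np.array([[0, 0.8], [0.8, 0]]))
        tree = phylo.neighbor_joining(dm)
        assert phylo.to_newick(tree) == "(A:0.4,B:0.4);"

    def test_three_taxa_closed_form(self):
        dm = phylo.DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        )
        assert phylo.to_newick(phylo.neighbor_joining(dm)) == "(A:1,B:1,C:3);"

    def test_four_taxon_additive_recovery(self):
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 3, 5], [3, 0, 4, 6], [3, 4, 0, 4], [5, 6, 4, 0]], dtype=float
        )
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels, d))
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        assert np.allclose(tree.path_length_matrix().d, d, atol=1e-9)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            phylo.DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], float))

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_recovery_vs_enumeration(self, n):
        """NJ finds the unique zero-residual topology among all enumerated ones,
        with exact branch lengths (path-length matrix equals the input)."""
        rng = np.random.default_rng(n)
        labels = [f"L{i}" for i in range(n)]
        for _ in range(5):
            d, true_splits = random_additive_matrix(n, rng)
            tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels, d))
            got_splits = {
                frozenset(int(lab[1:]) for lab in s) for s in tree.bipartitions()
            }
            canonical = {
                min(s, frozenset(range(n)) - s, key=lambda x: (len(x), sorted(x)))
                for s in got_splits
            }
            assert canonical == true_splits
            assert np.allclose(tree.path_length_matrix().d, d, atol=1e-9)
            # enumeration oracle: the generating topology is the only
            # additive fit among all topologies
            zero_residual = [
                topology_splits(edges, n)
                for edges in enumerate_unrooted_topologies(n)
                if fit_branch_lengths(edges, n, d) < 1e-8
            ]
            assert zero_residual == [true_splits]

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_label_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        d, _ = random_additive_matrix(n, rng)
        labels = [f"L{i}" for i in range(n)]
        tree1 = phylo.neighbor_joining(phylo.DistanceMatrix(labels, d))
        perm = rng.permutation(n)
        d2 = d[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        tree2 = phylo.neighbor_joining(phylo.DistanceMatrix(labels2, d2))
        assert phylo.to_newick(tree1) == phylo.to_newick(tree2)

    def test_negative_branch_clamped(self):
        # near-degenerate matrix that produces a negative NJ branch estimate
        d = np.array(
            [
                [0.0, 0.1, 0.4, 0.4],
                [0.1, 0.0, 0.4, 0.4],
                [0.4, 0.4, 0.0, 0.05],
                [0.4, 0.4, 0.05, 0.0],
            ]
        )
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(list("ABCD"), d))

        def lengths(node):
            out = []
            for child, l in node.children:
                out.append(l)
                out.extend(lengths(child))
            return out

        assert all(l >= 0 for l in lengths(tree.root))


class TestNewick:
    def test_round_trip_topology_and_lengths(self):
        rng = np.random.default_rng(3)
        d, _ = random_additive_matrix(6, rng)
        labels = [f"L{i}" for i in range(6)]
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels, d))
        newick = phylo.to_newick(tree)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == labels
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        ours = tree.path_length_matrix()
        for i, la in enumerate(labels):
            for j in range(i + 1, 6):
                assert pdm.distance(taxa[la], taxa[labels[j]]) == pytest.approx(
                    ours.d[i, j], abs=1e-4
                )

    def test_deterministic_child_order(self):
        dm = phylo.DistanceMatrix(
            ["C", "A", "B"], np.array([[0, 4, 4], [4, 0, 2], [4, 2, 0]], float)
        )
        assert phylo.to_newick(phylo.neighbor_joining(dm)) == "(A:1,B:1,C:3);"


class TestDistanceMatrixIO:
    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        d, _ = random_additive_matrix(4, rng)
        dm = phylo.DistanceMatrix([f"L{i}" for i in range(4)], d)
        p = tmp_path / "d.tsv"
        phylo.write_distance_tsv(dm, p)
        back = phylo.read_distance_tsv(p)
        assert back.labels == dm.labels
        assert np.allclose(back.d, dm.d)
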