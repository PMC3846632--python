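"""Distances, PCA, neighbor joining and minimum spanning networks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wildpopsig import (
    distance_matrix,
    expression_tree_input,
    minimum_spanning_network,
    neighbor_joining,
    pca,
)
from wildpopsig.structure import DistanceMatrix

from conftest import make_norm
from test_calling import make_ratio


def dm(values, labels):
    return DistanceMatrix(pd.DataFrame(values, index=labels, columns=labels))


class TestDistanceMatrix:
    def test_identical_vectors_distance_zero(self):
        r = make_ratio([[0.0, 0.0], [0.0, 0.0]])
        d = distance_matrix(r)
        np.testing.assert_allclose(d.values.values, 0.0)

    def test_three_four_five(self):
        r = make_ratio([[-1.5, 1.5], [-2.0, 2.0]])
        # strain difference vector (3, 4): distance 5
        d = distance_matrix(r)
        assert d.values.loc["s0", "s1"] == pytest.approx(5.0)

    def test_gene_order_irrelevant(self):
        vals = np.random.default_rng(0).normal(size=(10, 4))
        vals -= vals.mean(axis=1, keepdims=True)
        r = make_ratio(vals)
        d1 = distance_matrix(r).values
        perm = np.random.default_rng(1).permutation(10)
        r2 = make_ratio(vals[perm])
        d2 = distance_matrix(r2).values
        np.testing.assert_allclose(d1.values, d2.values)

    def test_empty_subset_rejected(self):
        r = make_ratio(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            distance_matrix(r, set())


class TestPCA:
    def test_rank_one_matrix(self):
        base = np.array([1.0, -1.0, 2.0, -2.0])
        vals = np.outer(np.array([1.0, 2.0, 3.0]), base)
        r = make_ratio(vals)
        _, varexp = pca(r)
        assert varexp[0] == pytest.approx(1.0)

    def test_duplicated_strains_identical_scores(self):
        vals = np.random.default_rng(2).normal(size=(8, 3))
        vals = np.column_stack([vals, vals[:, 0]])
        vals -= vals.mean(axis=1, keepdims=True)
        scores, _ = pca(make_ratio(vals))
        np.testing.assert_allclose(scores.iloc[0].values, scores.iloc[3].values, atol=1e-9)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(4, 5))  # 5 strains x 4 genes
        vals -= vals.mean(axis=1, keepdims=True)
        r = make_ratio(vals)
        scores, varexp = pca(r)
        x = vals.T - vals.T.mean(axis=0, keepdims=True)
        cov = x.T @ x
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(varexp[: len(evals)], evals / evals.sum(), atol=1e-8)
        proj = x @ evecs
        for j in range(3):
            np.testing.assert_allclose(
                np.abs(scores.values[:, j]), np.abs(proj[:, j]), atol=1e-8
            )

    def test_variance_explained_sums_to_one(self):
        vals = np.random.default_rng(4).normal(size=(12, 6))
        vals -= vals.mean(axis=1, keepdims=True)
        _, varexp = pca(make_ratio(vals))
        assert varexp.sum() == pytest.approx(1.0)


def random_additive_tree(n_taxa, rng):
    """Random binary tree with positive branch lengths; returns leaf
    distance matrix computed by independent path summation."""
    import networkx as nx

    g = nx.Graph()
    nodes = [f"t{i}" for i in range(n_taxa)]
    avail = list(nodes)
    nxt = 0
    while len(avail) > 2:
        a, b = avail.pop(rng.integers(len(avail))), avail.pop(rng.integers(len(avail) - 1))
        u = f"i{nxt}"
        nxt += 1
        g.add_edge(u, a, weight=rng.uniform(0.5, 3.0))
        g.add_edge(u, b, weight=rng.uniform(0.5, 3.0))
        avail.append(u)
    g.add_edge(avail[0], avail[1], weight=rng.uniform(0.5, 3.0))
    d = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(nodes):
        lengths = nx.single_source_dijkstra_path_length(g, a, weight="weight")
        for j, b in enumerate(nodes):
            d[i, j] = lengths[b]
    np.fill_diagonal(d, 0.0)
    return dm(d, nodes)


class TestNeighborJoining:
    def test_two_taxa(self):
        t = neighbor_joining(dm([[0.0, 3.0], [3.0, 0.0]], ["A", "B"]))
        assert t.path_length("A", "B") == pytest.approx(3.0)

    def test_three_taxa_closed_form(self):
        d = dm([[0, 5, 9], [5, 0, 10], [9, 10, 0]], ["A", "B", "C"])
        t = neighbor_joining(d)
        # a = (dAB + dAC - dBC)/2 = 2, b = 3, c = 7
        g = t.graph()
        center = [n for n in g.nodes if n.startswith("node")][0]
        assert g["A"][center]["weight"] == pytest.approx(2.0)
        assert g["B"][center]["weight"] == pytest.approx(3.0)
        assert g["C"][center]["weight"] == pytest.approx(7.0)

    def test_four_taxon_additive_matrix_recovered(self):
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], dtype=float
        )
        t = neighbor_joining(dm(d, labels))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert t.path_length(a, b) == pytest.approx(d[i, j], abs=1e-9)
        # the AB|CD split: removing the internal edge separates {A,B} from {C,D}
        g = t.graph()
        internal = [
            (u, v) for u, v, _ in t.edges if u.startswith("node") and v.startswith("node")
        ]
        assert internal
        import networkx as nx

        g.remove_edge(*internal[0])
        side = nx.node_connected_component(g, "A")
        assert {"A", "B"} <= side and not {"C", "D"} & side

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_additive_trees_reproduced_exactly(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        d = random_additive_tree(n_taxa, rng)
        t = neighbor_joining(d)
        for a, b in itertools.combinations(d.labels, 2):
            assert t.path_length(a, b) == pytest.approx(
                d.values.loc[a, b], abs=1e-9
            )

    def test_branch_lengths_nonnegative(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(6, 3))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        t = neighbor_joining(dm(d, [f"s{i}" for i in range(6)]))
        assert all(w >= 0 for _, _, w in t.edges)

    def test_newick_roundtrip_leaves(self):
        d = random_additive_tree(6, np.random.default_rng(8))
        nwk = neighbor_joining(d).to_newick()
        assert nwk.endswith(";")
        for leaf in d.labels:
            assert leaf in nwk

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(dm([[0.0]], ["A"]))


def msat_table(genotypes):
    rows = []
    for i, g in enumerate(genotypes):
        rows.append([f"st{i}", "G", "S"] + list(g))
    cols = ["strain_id", "group", "site"] + [f"locus_{j + 1}" for j in range(len(genotypes[0]))]
    return pd.DataFrame(rows, columns=cols)


def brute_force_mst_weight(dists):
    """Minimum total weight over all spanning trees by exhaustive search."""
    import networkx as nx

    n = len(dists)
    nodes = list(range(n))
    edges = [(i, j, dists[i][j]) for i in nodes for j in nodes if i < j]
    best = np.inf
    for subset in itertools.combinations(edges, n - 1):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_weighted_edges_from(subset)
        if nx.is_connected(g):
            best = min(best, sum(w for _, _, w in subset))
    return best


class TestMinimumSpanningNetwork:
    def test_two_close_one_far(self):
        # genotypes at pairwise distances 1, 1, 2: the two distance-1 edges
        # are the main tree
        t = msat_table([(0, 0), (0, 1), (1, 0)])
        net = minimum_spanning_network(t)
        main = net.edges[net.edges["kind"] == "main"]
        assert sorted(main["distance"]) == [1, 1]

    def test_triangle_of_equal_distances_has_alternative(self):
        t = msat_table([(0, 0), (0, 1), (1, 1)])
        # distances: 1, 1, 2 -> no tie; use a true equilateral set instead
        t = msat_table([(0, 0), (1, 0), (2, 0)])
        net = minimum_spanning_network(t)
        assert (net.edges["kind"] == "main").sum() == 2
        assert (net.edges["kind"] == "alternative").sum() == 1
        assert set(net.edges["distance"]) == {1}

    def test_multiplicity_counts_strains_sharing_genotype(self):
        t = msat_table([(0, 0), (0, 0), (1, 1)])
        net = minimum_spanning_network(t)
        assert sorted(net.nodes["multiplicity"]) == [1, 2]

    def test_identical_genotypes_single_node_no_edges(self):
        t = msat_table([(0, 0), (0, 0)])
        net = minimum_spanning_network(t)
        assert len(net.nodes) == 1 and net.edges.empty

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_main_tree_weight_matches_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        genos = [tuple(rng.integers(0, 3, size=6)) for _ in range(6)]
        genos = list(dict.fromkeys(genos))  # distinct
        t = msat_table(genos)
        net = minimum_spanning_network(t)
        dists = [[sum(a != b for a, b in zip(x, y)) for y in genos] for x in genos]
        assert net.main_tree_weight() == pytest.approx(brute_force_mst_weight(dists))

    def test_alternative_edges_tie_a_main_edge_on_their_path(self):
        rng = np.random.default_rng(5)
        genos = list(dict.fromkeys(tuple(rng.integers(0, 2, size=4)) for _ in range(6)))
        net = minimum_spanning_network(msat_table(genos))
        import networkx as nx

        tree = nx.Graph()
        main = net.edges[net.edges["kind"] == "main"]
        for _, e in main.iterrows():
            tree.add_edge(e["u"], e["v"], weight=e["distance"])
        for _, e in net.edges[net.edges["kind"] == "alternative"].iterrows():
            path = nx.shortest_path(tree, e["u"], e["v"])
            wmax = max(tree[a][b]["weight"] for a, b in zip(path, path[1:]))
            assert e["distance"] == wmax


class TestExpressionTreeInput:
    def _rna(self, probe_vals, strains, dna_only=None):
        n_arrays = len(strains)
        m = make_norm(probe_vals, strains=strains, branch="rna")
        return expression_tree_input(m, dna_only or set())

    def test_replicates_averaged(self):
        vals = np.array([[1.0, 3.0, 0.0, 0.0], [0.0, 0.0, 2.0, -2.0]])
        out = self._rna(vals, ["sA", "sA", "sB", "sB"])
        # strain A replicate pair (1, 3) -> 2; centered against B's 0
        assert out.values.loc["g0", "sA"] == pytest.approx(1.0)
        assert out.values.loc["g0", "sB"] == pytest.approx(-1.0)

    def test_probes_below_filter_error(self):
        vals = np.full((3, 4), 0.1)
        with pytest.raises(ValueError, match="no probes"):
            self._rna(vals, ["sA", "sA", "sB", "sB"])

    def test_dna_only_genes_removed(self):
        vals = np.array([[2.0, 2.0, -2.0, -2.0], [2.0, 2.0, -2.0, -2.0]])
        m = make_norm(vals, strains=["sA", "sA", "sB", "sB"], branch="rna")
        out = expression_tree_input(m, dna_only_genes={"g0"})
        assert "g0" not in out.values.index
        assert "g1" in out.values.index
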