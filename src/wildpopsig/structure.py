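"""Population structure: distances, PCA, neighbor-joining trees and
minimum spanning networks.

Strain relationships are reconstructed from the hybridization-ratio
matrix (Euclidean distances over the polymorphic genes, genome-wide or
per chromosome), from replicate-averaged expression ratios, and from
multilocus microsatellite genotypes (minimum spanning network with
equally minimal alternative connections).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .calling import RatioMatrix
from .normalize import NormalizedMatrix

__all__ = [
    "DistanceMatrix",
    "UnrootedTree",
    "MSNetwork",
    "distance_matrix",
    "pca",
    "neighbor_joining",
    "expression_tree_input",
    "minimum_spanning_network",
]


@dataclass
class DistanceMatrix:
    values: pd.DataFrame  # strains x strains, symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = self.values.values
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)


@dataclass
class UnrootedTree:
    """Unrooted tree as an edge list over leaves and internal nodes."""

    edges: list[tuple[str, str, float]]
    leaves: list[str]
    root: str  # arbitrary internal node used for Newick serialization

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=float(w))
        return g

    def path_length(self, a: str, b: str) -> float:
        return nx.shortest_path_length(self.graph(), a, b, weight="weight")

    def to_newick(self) -> str:
        g = self.graph()

        def build(node: str, parent: str | None) -> str:
            children = [n for n in g.neighbors(node) if n != parent]
            if not children:
                return node
            inner = ",".join(
                f"{build(c, node)}:{g[node][c]['weight']:.10g}" for c in children
            )
            label = node if node in self.leaves else ""
            return f"({inner}){label}"

        return build(self.root, None) + ";"


@dataclass
class MSNetwork:
    """Distinct multilocus genotypes linked by a minimum spanning tree plus
    equally minimal alternative connections."""

    nodes: pd.DataFrame               # index genotype_id; multiplicity, strains, loci
    edges: pd.DataFrame               # u, v, distance, kind in {main, alternative}

    def main_tree_weight(self) -> float:
        return float(self.edges.loc[self.edges["kind"] == "main", "distance"].sum())


def distance_matrix(r: RatioMatrix, gene_subset: set[str] | None = None) -> DistanceMatrix:
    """Euclidean distances between strain ratio vectors over ``gene_subset``."""
    if gene_subset is not None:
        genes = [g for g in r.values.index if g in gene_subset]
        if not genes:
            raise ValueError("gene subset is empty")
        vals = r.values.loc[genes]
    else:
        vals = r.values
    if vals.empty:
        raise ValueError("gene subset is empty")
    d = squareform(pdist(vals.values.T, metric="euclidean"))
    return DistanceMatrix(pd.DataFrame(d, index=vals.columns, columns=vals.columns))


def pca(
    r: RatioMatrix, gene_subset: set[str] | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA with strains as observations and genes as variables.

    Columns (genes) are centered, not scaled. Returns per-strain scores and
    the fraction of variance explained per component (sums to 1).
    """
    if gene_subset is not None:
        vals = r.values.loc[[g for g in r.values.index if g in gene_subset]]
    else:
        vals = r.values
    x = vals.values.T  # strains x genes
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 strains")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _vt = np.linalg.svd(xc, full_matrices=False)
    scores = u * s
    total = (s**2).sum()
    if total == 0:
        import warnings

        warnings.warn("constant matrix: all principal components have zero variance")
        var_explained = np.zeros_like(s)
    else:
        var_explained = s**2 / total
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=vals.columns, columns=cols), var_explained


def neighbor_joining(d: DistanceMatrix) -> UnrootedTree:
    """Saitou-Nei neighbor joining on the Q-criterion.

    Ties in Q are broken by the lexicographically lowest label pair.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch, so all reported lengths are nonnegative.
    """
    labels = list(d.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    dist = {a: {b: float(d.values.loc[a, b]) for b in labels} for a in labels}
    leaves = list(labels)
    edges: list[tuple[str, str, float]] = []
    active = list(labels)
    next_id = itertools.count(1)

    if n == 2:
        a, b = sorted(active)
        return UnrootedTree(edges=[(a, b, dist[a][b])], leaves=leaves, root=a)

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist[a][b] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (m - 2) * dist[a][b] - r[a] - r[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _q, a, b = best
        dab = dist[a][b]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        # clamp negatives, transferring the deficit to the sibling edge
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        u = f"node{next(next_id)}"
        dist[u] = {}
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist[a][c] + dist[b][c] - dab)
            dist[u][c] = duc
            dist[c][u] = duc
        edges.append((u, a, la))
        edges.append((u, b, lb))
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = sorted(active)
    la = 0.5 * (dist[a][b] + dist[a][c] - dist[b][c])
    lb = 0.5 * (dist[a][b] + dist[b][c] - dist[a][c])
    lc = 0.5 * (dist[a][c] + dist[b][c] - dist[a][b])
    u = f"node{next(next_id)}"
    for leaf, ln in ((a, la), (b, lb), (c, lc)):
        edges.append((u, leaf, max(ln, 0.0)))
    return UnrootedTree(edges=edges, leaves=leaves, root=u)


def expression_tree_input(
    rna: NormalizedMatrix,
    dna_only_genes: set[str] | None = None,
    probe_filter: float = 0.5,
) -> RatioMatrix:
    """Replicate-averaged per-genotype expression ratios for the RNA tree.

    Probe M-values are averaged per genotype, centered to the across-
    genotype mean, and only probes with a maximum absolute ratio greater
    than ``probe_filter`` are kept. Genes whose expression is driven solely
    by DNA polymorphisms (``dna_only_genes``) are removed. Surviving probes
    are averaged per gene.
    """
    dna_only_genes = dna_only_genes or set()
    strain_of = rna.arrays["strain"].reindex(rna.values.columns)
    per_strain = rna.values.T.groupby(strain_of.values).mean().T
    probe_ratio = per_strain.sub(per_strain.mean(axis=1), axis=0)
    keep = probe_ratio.abs().max(axis=1) > probe_filter
    if not keep.any():
        raise ValueError(f"no probes with maximum |ratio| > {probe_filter}")
    probe_ratio = probe_ratio.loc[keep]
    gene_of = rna.probes["gene_id"].reindex(probe_ratio.index)
    probe_ratio = probe_ratio.loc[~gene_of.isin(dna_only_genes)]
    gene_of = gene_of.loc[probe_ratio.index]
    gene_vals = probe_ratio.groupby(gene_of).mean()
    gene_vals = gene_vals.sub(gene_vals.mean(axis=1), axis=0)
    coords = pd.DataFrame(index=gene_vals.index)
    if {"gene_id", "chrom"} <= set(rna.probes.columns):
        per_gene = rna.probes.groupby("gene_id").agg(
            chrom=("chrom", "first"), start=("pos", "min"), end=("pos", "max")
        )
        coords = per_gene.reindex(gene_vals.index)
    return RatioMatrix(values=gene_vals, coords=coords)


def minimum_spanning_network(msats: pd.DataFrame) -> MSNetwork:
    """Minimum spanning network over distinct multilocus genotypes.

    Distance between genotypes is the number of differing loci. Main edges
    form a minimum spanning tree (Kruskal); every non-tree edge whose
    weight equals the maximum edge weight on the tree path between its
    endpoints is reported as an alternative connection.
    """
    locus_cols = [c for c in msats.columns if c.startswith("locus_")]
    if not locus_cols:
        raise ValueError("no locus_* columns in microsatellite table")
    geno = msats[locus_cols].apply(tuple, axis=1)
    node_rows = []
    geno_map: dict[tuple, str] = {}
    for g, members in msats.groupby(geno.values).groups.items():
        gid = f"mlg{len(geno_map) + 1}"
        geno_map[g] = gid
        strains = list(msats.loc[members, "strain_id"]) if "strain_id" in msats else list(members)
        node_rows.append((gid, len(members), ";".join(map(str, strains)), ";".join(map(str, g))))
    nodes = pd.DataFrame(
        node_rows, columns=["genotype_id", "multiplicity", "strains", "loci"]
    ).set_index("genotype_id")

    gids = list(geno_map.values())
    genos = {v: k for k, v in geno_map.items()}
    if len(gids) < 2:
        return MSNetwork(nodes=nodes, edges=pd.DataFrame(columns=["u", "v", "distance", "kind"]))

    g = nx.Graph()
    g.add_nodes_from(gids)
    for u, v in itertools.combinations(gids, 2):
        dist = sum(a != b for a, b in zip(genos[u], genos[v]))
        g.add_edge(u, v, weight=dist)
    mst_edges = {
        tuple(sorted((u, v))): d["weight"]
        for u, v, d in nx.minimum_spanning_edges(g, algorithm="kruskal", data=True)
    }
    tree = nx.Graph()
    for (u, v), w in mst_edges.items():
        tree.add_edge(u, v, weight=w)

    edge_rows = [(u, v, w, "main") for (u, v), w in sorted(mst_edges.items())]
    for u, v in itertools.combinations(gids, 2):
        key = tuple(sorted((u, v)))
        if key in mst_edges:
            continue
        w = g[u][v]["weight"]
        path = nx.shortest_path(tree, u, v)
        path_max = max(tree[a][b]["weight"] for a, b in zip(path, path[1:]))
        if w == path_max:
            edge_rows.append((key[0], key[1], w, "alternative"))
    edges = pd.DataFrame(edge_rows, columns=["u", "v", "distance", "kind"])
    return MSNetwork(nodes=nodes, edges=edges)
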