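"""Coexpression-network backbones from minimum spanning trees.

The complete coexpression graph puts an edge of length 1 - |r_ij| between
every pair of set members.  Its first minimum spanning tree T1 is the
cheapest acyclic connector of all genes; the second spanning structure is
the minimum spanning tree (or forest, when removing T1 disconnects the
remainder) of the graph with T1's edges deleted.  Their union, MST2, is a
sparse backbone of the full correlation structure: every node has degree at
least 2, highly cross-correlated genes sit near the center, and the gene
with the largest weight factor is the set's hub gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import CorrelationStructure, WeightSolution

__all__ = [
    "MST2Graph",
    "distance_graph",
    "minimum_spanning_tree",
    "mst2",
    "hub_gene",
    "centralities",
    "export_graph",
    "read_graph",
]


def distance_graph(C: CorrelationStructure, gene_ids: list[str] | None = None) -> nx.Graph:
    """Complete graph on the set members with distances 1 - |r_ij|."""
    p = C.p
    if p < 2:
        raise ValueError("need at least 2 genes to build a distance graph")
    names = gene_ids if gene_ids is not None else [str(i) for i in range(p)]
    if len(names) != p:
        raise ValueError(f"{len(names)} gene ids for {p} genes")
    G = nx.Graph()
    G.add_nodes_from(names)
    for i in range(p):
        for j in range(i + 1, p):
            G.add_edge(names[i], names[j], distance=float(1.0 - C.abs_corr[i, j]))
    return G


def _node_index(G: nx.Graph) -> dict:
    return {v: i for i, v in enumerate(G.nodes)}


def _kruskal_forest(G: nx.Graph, index: dict) -> list[tuple]:
    """Minimum spanning forest edges with a deterministic tie-break.

    Edges are processed in (distance, smaller node index, larger node index)
    order, so equal-length edges always resolve the same way.
    """
    edges = []
    for u, v, d in G.edges(data="distance"):
        i, j = sorted((index[u], index[v]))
        edges.append((d, i, j, u, v))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    uf = nx.utils.UnionFind(G.nodes)
    out = []
    for d, _, _, u, v in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            out.append((u, v, d))
    return out


def minimum_spanning_tree(G: nx.Graph) -> list[tuple]:
    """Edges (u, v, distance) of the first MST; errors if G is disconnected."""
    if not nx.is_connected(G):
        comps = [sorted(c) for c in nx.connected_components(G)]
        raise ValueError(f"graph is disconnected; components: {comps}")
    return _kruskal_forest(G, _node_index(G))


@dataclass
class MST2Graph:
    """Union of the first MST and the second spanning structure.

    ``graph`` carries edge attributes ``distance`` and ``tree`` (``first`` /
    ``second``) and, after :meth:`annotate`, per-node ``weight`` values.
    """

    graph: nx.Graph
    first_edges: list[tuple] = field(default_factory=list)
    second_edges: list[tuple] = field(default_factory=list)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def degrees(self) -> dict:
        return dict(self.graph.degree())

    def annotate(self, w: WeightSolution, gene_ids: list[str]) -> None:
        """Attach each gene's weight factor as a node attribute."""
        if len(gene_ids) != len(w.weights):
            raise ValueError("gene ids and weights differ in length")
        for g, wt in zip(gene_ids, w.weights):
            self.graph.nodes[g]["weight"] = float(wt)


def mst2(G: nx.Graph) -> MST2Graph:
    """First MST plus the minimum spanning structure of the reduced graph.

    The reduced graph is G with the first tree's edges removed; for small
    complete graphs it can be disconnected (e.g. a star-shaped first tree on
    four nodes), in which case the second structure is its minimum spanning
    forest.  Built from a complete graph on p >= 3 nodes, every node of the
    union has degree >= 2.
    """
    p = G.number_of_nodes()
    if p < 3:
        raise ValueError(f"MST2 needs at least 3 nodes, got {p}")
    if not nx.is_connected(G):
        comps = [sorted(c) for c in nx.connected_components(G)]
        raise ValueError(f"graph is disconnected; components: {comps}")
    index = _node_index(G)
    first = _kruskal_forest(G, index)
    reduced = G.copy()
    reduced.remove_edges_from([(u, v) for u, v, _ in first])
    second = _kruskal_forest(reduced, index)
    union = nx.Graph()
    union.add_nodes_from(G.nodes)
    for u, v, d in first:
        union.add_edge(u, v, distance=d, tree="first")
    for u, v, d in second:
        union.add_edge(u, v, distance=d, tree="second")
    return MST2Graph(graph=union, first_edges=first, second_edges=second)


def hub_gene(w: WeightSolution, gene_ids: list[str], return_tie: bool = False):
    """Gene with the largest weight factor; ties go to the earliest gene.

    A tie (within relative 1e-12 of the maximum) triggers a warning; with
    ``return_tie=True`` the tie flag is returned alongside the id.
    """
    wt = np.asarray(w.weights, dtype=float)
    if len(gene_ids) != wt.size:
        raise ValueError("gene ids and weights differ in length")
    if np.any(wt <= 0):
        raise ValueError("weights must be strictly positive")
    top = float(wt.max())
    tied = np.flatnonzero(wt >= top * (1.0 - 1e-12))
    hub = gene_ids[int(tied[0])]
    tie = tied.size > 1
    if tie:
        warnings.warn(
            f"hub weight tie among {[gene_ids[int(i)] for i in tied]}; keeping {hub!r}"
        )
    return (hub, tie) if return_tie else hub


def centralities(g: MST2Graph) -> dict:
    """Per-node degree and (unweighted shortest-path) betweenness on MST2."""
    deg = dict(g.graph.degree())
    btw = nx.betweenness_centrality(g.graph, normalized=True)
    return {v: {"degree": deg[v], "betweenness": btw[v]} for v in g.graph.nodes}


# -- export / import --------------------------------------------------------

_FORMATS = ("graphml", "tsv")


def export_graph(g: MST2Graph, path, format: str = "graphml") -> None:
    """Write an MST2 graph as GraphML or an edge-list TSV.

    GraphML keeps node annotations (weights) and edge attributes; the TSV
    keeps the edge structure (source, target, distance, tree provenance).
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown graph format {format!r}; choose from {_FORMATS}")
    if format == "graphml":
        nx.write_graphml(g.graph, path)
        return
    with open(path, "w") as fh:
        fh.write("source\ttarget\tdistance\ttree\n")
        for u, v, data in g.graph.edges(data=True):
            fh.write(f"{u}\t{v}\t{data['distance']:.17g}\t{data['tree']}\n")


def read_graph(path, format: str = "graphml") -> MST2Graph:
    """Read a graph written by :func:`export_graph`."""
    if format not in _FORMATS:
        raise ValueError(f"unknown graph format {format!r}; choose from {_FORMATS}")
    if format == "graphml":
        graph = nx.read_graphml(path)
        graph = nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    else:
        graph = nx.Graph()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["source", "target", "distance", "tree"]:
                raise ValueError(f"unexpected edge-list header: {header}")
            for lineno, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 4:
                    raise ValueError(f"line {lineno}: expected 4 columns, got {len(parts)}")
                u, v, d, tree = parts
                graph.add_edge(u, v, distance=float(d), tree=tree)
    first = [(u, v, d["distance"]) for u, v, d in graph.edges(data=True) if d["tree"] == "first"]
    second = [(u, v, d["distance"]) for u, v, d in graph.edges(data=True) if d["tree"] == "second"]
    return MST2Graph(graph=graph, first_edges=first, second_edges=second)
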