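"""Biological-network features.

Degree, normalized betweenness centrality, transcription-factor
in/out-degree and the disease-relevance distance, on top of networkx
graphs.  Whole-graph betweenness is delegated to igraph's C
implementation (exact, same definition) because genome-scale networks
make the pure-Python computation the pipeline bottleneck; unit tests
check it against brute-force shortest-path enumeration.

Conventions: shortest paths are unweighted (BFS); pairs with no
connecting path are skipped in the betweenness sum; a self-loop does
not count as an interaction partner but does set the self-interaction
flag.
"""

from __future__ import annotations

import math
from typing import Iterable

import networkx as nx

from .errors import InvalidInputError, UndefinedScoreError, UnknownNodeError

UNREACHABLE = math.inf


def read_edgelist_tsv(path, directed: bool = False) -> nx.Graph | nx.DiGraph:
    """Read a two-column edge-list TSV ('#' starts a comment line)."""
    g = nx.DiGraph() if directed else nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InvalidInputError(f"malformed edge line: {line!r}")
            g.add_edge(parts[0], parts[1])
    return g


def write_edgelist_tsv(path, g: nx.Graph) -> None:
    with open(path, "w") as fh:
        fh.write(f"# directed={int(g.is_directed())}\n")
        for u, v in g.edges():
            fh.write(f"{u}\t{v}\n")


def _require_node(g: nx.Graph, node) -> None:
    if node not in g:
        raise UnknownNodeError(f"node {node!r} not in network")


def degree(g: nx.Graph, node) -> int:
    """Number of distinct interaction partners (self-loops excluded)."""
    _require_node(g, node)
    return len(set(g.neighbors(node)) - {node})


def degree_map(g: nx.Graph) -> dict:
    return {n: len(set(g.neighbors(n)) - {n}) for n in g}


def self_interacting(g: nx.Graph, node) -> bool:
    """True iff the node carries a self-loop (protein interacts with itself)."""
    _require_node(g, node)
    return g.has_edge(node, node)


def betweenness_map(g: nx.Graph) -> dict:
    """Normalized betweenness centrality of every node.

    B(n) = 2 * sum over unordered pairs s != n != t of
    sigma_st(n)/sigma_st, divided by (N-1)(N-2), with sigma the number
    of unweighted shortest paths.  Disconnected pairs (sigma_st = 0)
    are skipped.  Computed via igraph for speed; self-loops do not
    affect shortest paths and are dropped before the computation.
    """
    import igraph as ig

    if g.number_of_nodes() < 3:
        raise UndefinedScoreError("betweenness needs at least 3 nodes")
    nodes = list(g.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges() if u != v]
    h = ig.Graph(n=len(nodes), edges=edges, directed=False)
    raw = h.betweenness()
    n = len(nodes)
    norm = 2.0 / ((n - 1) * (n - 2))
    return {node: raw[i] * norm for node, i in index.items()}


def betweenness(g: nx.Graph, node) -> float:
    _require_node(g, node)
    if g.is_directed():
        raise InvalidInputError("betweenness is defined here for undirected networks")
    return betweenness_map(g)[node]


def tf_degrees(g: nx.DiGraph, node) -> tuple[int, int]:
    """(indegree, outdegree) in the directed TF -> target network.

    The indegree of a gene is the number of transcription factors
    regulating it; the outdegree of a TF is the number of genes it
    regulates.
    """
    _require_node(g, node)
    return int(g.in_degree(node)), int(g.out_degree(node))


def disease_distance(g: nx.Graph, protein, disease_genes: Iterable) -> float:
    """Minimum shortest-path length from the protein to any known
    disease gene; 0 if the protein is itself one; ``UNREACHABLE``
    (math.inf) if no path exists."""
    genes = set(disease_genes)
    if not genes:
        raise InvalidInputError("empty disease gene set")
    if protein in genes:
        return 0
    _require_node(g, protein)
    sources = [x for x in genes if x in g]
    if not sources:
        return UNREACHABLE
    # multi-source shortest paths from the disease genes (unit edge weights)
    dist = nx.multi_source_dijkstra_path_length(g, sources)
    d = dist.get(protein, UNREACHABLE)
    return int(d) if d is not UNREACHABLE else UNREACHABLE
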