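"""Median-joining haplotype network construction and export.

The network starts from the epsilon-relaxed minimum spanning network (the
union of all minimum spanning trees when epsilon = 0) over observed
haplotypes, then iteratively inserts quasi-median ("median vector")
sequences for connected triplets whenever they shorten the network, and
prunes median vectors that end up poorly connected.  All tie-breaking is
lexicographic on the haplotype strings so the output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .seqstats import HaplotypeTable

__all__ = [
    "HaploNetwork",
    "distance_matrix",
    "minimum_spanning_network",
    "median_joining",
    "write_gml",
    "write_edge_tsv",
]

_NUC = set("ACGT01")  # binary encodings are accepted alongside nucleotides


@dataclass
class HaploNetwork:
    """Graph over observed haplotypes plus inferred median vectors."""

    graph: nx.Graph
    observed: list[str]
    medians: list[str] = field(default_factory=list)
    epsilon: int = 0
    frequencies: dict[str, int] = field(default_factory=dict)
    population_composition: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def total_cost(self) -> int:
        return int(sum(w for _, _, w in self.graph.edges.data("weight")))


def _check_haplotypes(haps: list[str]) -> None:
    if len(haps) < 2:
        raise ValueError("need at least 2 haplotypes")
    lengths = {len(h) for h in haps}
    if len(lengths) != 1:
        raise ValueError("haplotype length mismatch")
    bad = set("".join(haps)) - _NUC
    if bad:
        raise ValueError(f"invalid characters in haplotypes: {sorted(bad)}")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def distance_matrix(table: HaplotypeTable | list[str]) -> np.ndarray:
    """Symmetric integer Hamming distance matrix over haplotypes."""
    haps = table.haplotypes if isinstance(table, HaplotypeTable) else list(table)
    _check_haplotypes(haps)
    k = len(haps)
    d = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = _hamming(haps[i], haps[j])
    return d


def _minimax_distances(haps: list[str], d: np.ndarray) -> np.ndarray:
    """Bottleneck (minimax-path) distance between all node pairs, from an MST."""
    k = len(haps)
    g = nx.Graph()
    g.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            g.add_edge(i, j, weight=int(d[i, j]))
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    minimax = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        # max edge weight along MST path from i to every other node (DFS)
        stack = [(i, 0)]
        seen = {i}
        while stack:
            u, mx = stack.pop()
            for v in mst.neighbors(u):
                if v not in seen:
                    seen.add(v)
                    w = max(mx, mst.edges[u, v]["weight"])
                    minimax[i, v] = w
                    stack.append((v, w))
    return minimax


def _epsilon_msn_graph(haps: list[str], epsilon: int) -> nx.Graph:
    """Edges (u, v) with d(u, v) <= bottleneck(u, v) + epsilon.

    At epsilon = 0 this is exactly the union of all minimum spanning trees
    (an edge is in some MST iff its weight equals the bottleneck distance
    between its endpoints).
    """
    d = distance_matrix(haps)
    minimax = _minimax_distances(haps, d)
    g = nx.Graph()
    for h in haps:
        g.add_node(h)
    k = len(haps)
    for i in range(k):
        for j in range(i + 1, k):
            if d[i, j] == 0:
                continue
            if d[i, j] <= minimax[i, j] + epsilon:
                g.add_edge(haps[i], haps[j], weight=int(d[i, j]))
    return g


def minimum_spanning_network(table: HaplotypeTable | list[str],
                             epsilon: int = 0) -> HaploNetwork:
    """Union-of-MSTs network (epsilon-relaxed when epsilon > 0)."""
    haps = table.haplotypes if isinstance(table, HaplotypeTable) else list(table)
    _check_haplotypes(haps)
    g = _epsilon_msn_graph(haps, epsilon)
    net = HaploNetwork(g, observed=list(haps), epsilon=epsilon)
    _attach_metadata(net, table)
    return net


def _quasi_median(u: str, v: str, w: str) -> str:
    """Per-site majority consensus; 3-way ties take the lexicographically
    first of the three states."""
    out = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(min(a, b, c))
    return "".join(out)


def _mst_cost(nodes: list[str]) -> int:
    d = distance_matrix(nodes)
    g = nx.Graph()
    k = len(nodes)
    for i in range(k):
        for j in range(i + 1, k):
            g.add_edge(i, j, weight=int(d[i, j]))
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    return int(sum(w for _, _, w in mst.edges.data("weight")))


def median_joining(table: HaplotypeTable | list[str],
                   epsilon: int = 0,
                   max_iter: int = 100) -> HaploNetwork:
    """Median-joining network (Bandelt-style iteration).

    Each round builds the epsilon-relaxed MSN over the current node set,
    collects quasi-medians of mutually connected triplets, and greedily adds
    the candidate that most reduces the cost of a minimum spanning tree over
    the node set (lexicographic tie-break).  Median vectors that fall to
    degree <= 1 are pruned.  Iterates to a fixed point; the spanning cost is
    non-increasing throughout.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    observed = table.haplotypes if isinstance(table, HaplotypeTable) else list(table)
    _check_haplotypes(observed)
    observed = list(dict.fromkeys(observed))
    nodes = list(observed)
    obs_set = set(observed)
    cost = _mst_cost(nodes)
    for _ in range(max_iter):
        g = _epsilon_msn_graph(nodes, epsilon)
        candidates = set()
        for u, v, w in combinations(sorted(nodes), 3):
            if g.has_edge(u, v) and g.has_edge(u, w) and g.has_edge(v, w):
                q = _quasi_median(u, v, w)
                if q not in nodes:
                    candidates.add(q)
        best_q, best_cost = None, cost
        for q in sorted(candidates):
            c = _mst_cost(nodes + [q])
            if c < best_cost or (c == best_cost and best_q is not None and q < best_q):
                best_q, best_cost = q, c
        if best_q is None:
            # prune weakly connected medians, then stop if nothing changes
            g = _epsilon_msn_graph(nodes, epsilon)
            drop = [h for h in nodes
                    if h not in obs_set and g.degree(h) <= 1]
            if not drop:
                break
            nodes = [h for h in nodes if h not in drop]
            cost = _mst_cost(nodes)
            continue
        assert best_cost <= cost, "network cost must not increase"
        nodes.append(best_q)
        cost = best_cost
    g = _epsilon_msn_graph(nodes, epsilon)
    # final prune of dangling medians
    changed = True
    while changed:
        changed = False
        drop = [h for h in g.nodes if h not in obs_set and g.degree(h) <= 1]
        if drop:
            nodes = [h for h in nodes if h not in drop]
            g = _epsilon_msn_graph(nodes, epsilon)
            changed = True
    medians = [h for h in nodes if h not in obs_set]
    net = HaploNetwork(g, observed=observed, medians=medians, epsilon=epsilon)
    _attach_metadata(net, table)
    return net


def _attach_metadata(net: HaploNetwork, table) -> None:
    if not isinstance(table, HaplotypeTable):
        return
    freq = {h: int(c) for h, c in zip(table.haplotypes, table.counts)}
    comp = dict(zip(table.haplotypes, table.population_composition()))
    net.frequencies = freq
    net.population_composition = comp
    for node in net.graph.nodes:
        net.graph.nodes[node]["frequency"] = freq.get(node, 0)
        net.graph.nodes[node]["median_vector"] = node not in freq
        for pop, c in comp.get(node, {}).items():
            net.graph.nodes[node][f"pop_{pop}"] = c


def write_gml(net: HaploNetwork, path) -> None:
    nx.write_gml(net.graph, str(path))


def write_edge_tsv(net: HaploNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tweight\tnode1_type\tnode2_type\n")
        obs = set(net.observed)
        for u, v, w in sorted(net.graph.edges.data("weight")):
            tu = "observed" if u in obs else "median"
            tv = "observed" if v in obs else "median"
            fh.write(f"{u}\t{v}\t{w}\t{tu}\t{tv}\n")
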