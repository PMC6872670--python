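"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's own code paths: betweenness and
closeness enumerate shortest paths explicitly, information centrality
re-derives the (L + J) inverse with an independent formulation, subgraph
centrality uses the matrix exponential, eigenvector centrality uses power
iteration, and Fisher's exact test enumerates the full hypergeometric
family.  They are only feasible on tiny inputs, which is the point.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
from scipy.linalg import expm


def oracle_degree(graph: nx.Graph) -> dict:
    return {v: float(graph.degree(v)) for v in graph}


def _all_shortest_paths(graph):
    """(source, target) -> list of all shortest paths (as node tuples)."""
    out = {}
    for s in graph:
        for t in graph:
            if s == t:
                continue
            try:
                out[(s, t)] = [tuple(p) for p in nx.all_shortest_paths(graph, s, t)]
            except nx.NetworkXNoPath:
                out[(s, t)] = []
    return out


def oracle_betweenness(graph: nx.Graph) -> dict:
    n = graph.number_of_nodes()
    paths = _all_shortest_paths(graph)
    acc = {v: 0.0 for v in graph}
    nodes = list(graph)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            plist = paths[(s, t)]
            if not plist:
                continue
            for v in graph:
                if v in (s, t):
                    continue
                through = sum(1 for p in plist if v in p)
                acc[v] += through / len(plist)
    if n < 3:
        return {v: 0.0 for v in graph}
    scale = (n - 1) * (n - 2) / 2.0
    return {v: acc[v] / scale for v in graph}


def oracle_closeness(graph: nx.Graph) -> dict:
    out = {}
    for v in graph:
        lengths = nx.single_source_shortest_path_length(graph, v)
        reachable = len(lengths) - 1
        total = sum(lengths.values())
        out[v] = reachable / total if total > 0 else 0.0
    return out


def oracle_eigenvector(graph: nx.Graph, iterations: int = 200000) -> dict:
    """Power iteration per connected component, unit-max normalised."""
    out = {v: 0.0 for v in graph}
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        if len(comp) < 2:
            continue
        # iterate on A + I so bipartite spectra (+/- lambda) still converge
        a = nx.to_numpy_array(graph, nodelist=comp) + np.eye(len(comp))
        x = np.ones(len(comp))
        x /= np.linalg.norm(x)
        for _ in range(iterations):
            new = a @ x
            lam = x @ new  # Rayleigh quotient
            norm = np.linalg.norm(new)
            if norm == 0:
                break
            new = new / norm
            if np.linalg.norm(a @ new - lam * new) < 1e-11 * max(lam, 1.0):
                x = new
                break
            x = new
        x = np.abs(x)
        out.update(dict(zip(comp, x / x.max())))
    return out


def oracle_information(graph: nx.Graph) -> dict:
    out = {v: 0.0 for v in graph}
    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        n_c = len(comp)
        if n_c < 2:
            continue
        a = nx.to_numpy_array(graph, nodelist=comp)
        lap = np.diag(a.sum(axis=1)) - a
        c = np.linalg.inv(lap + np.ones((n_c, n_c)))
        for i, v in enumerate(comp):
            denom = sum(c[i, i] + c[j, j] - 2 * c[i, j] for j in range(n_c))
            out[v] = n_c / denom
    return out


def oracle_subgraph(graph: nx.Graph) -> dict:
    nodes = sorted(graph)
    a = nx.to_numpy_array(graph, nodelist=nodes)
    return dict(zip(nodes, np.diag(expm(a))))


def oracle_nc(graph: nx.Graph) -> dict:
    out = {}
    for v in graph:
        total = 0.0
        for u in graph.neighbors(v):
            z = len(set(graph.neighbors(v)) & set(graph.neighbors(u)))
            denom = min(graph.degree(v) - 1, graph.degree(u) - 1)
            if denom > 0:
                total += z / denom
        out[v] = total
    return out


def oracle_lac(graph: nx.Graph) -> dict:
    out = {}
    for v in graph:
        nbrs = list(graph.neighbors(v))
        if not nbrs:
            out[v] = 0.0
            continue
        sub = graph.subgraph(nbrs)
        out[v] = sum(sub.degree(u) for u in nbrs) / len(nbrs)
    return out


ORACLES = {
    "degree": oracle_degree,
    "betweenness": oracle_betweenness,
    "closeness": oracle_closeness,
    "eigenvector": oracle_eigenvector,
    "information": oracle_information,
    "subgraph": oracle_subgraph,
    "nc": oracle_nc,
    "lac": oracle_lac,
}


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full enumeration of the margin-fixed family,
    summing probabilities <= the observed table's (probability-mass rule)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_p(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = table_p(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = table_p(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def oracle_fisher_greater(a: int, b: int, c: int, d: int) -> float:
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    total = 0.0
    for x in range(a, min(r1, c1) + 1):
        total += math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
    return min(total, 1.0)


def oracle_wang_chain(depth_a: int, depth_b: int, weight: float = 0.8) -> float:
    """Wang similarity of two terms on a single is_a chain (root at depth 0).

    Term at depth d has ancestors at depths d, d-1, ..., 0 with S-values
    w^0, w^1, ..., w^d.  Shared ancestors are the chain up to min depth.
    """
    def sv(depth):
        return [weight**i for i in range(depth + 1)]

    sa, sb = sv(depth_a), sv(depth_b)
    shared = min(depth_a, depth_b) + 1
    # S-value of the ancestor at depth k, seen from a term at depth d, is w^(d-k)
    num = sum(weight ** (depth_a - k) + weight ** (depth_b - k) for k in range(shared))
    return num / (sum(sa) + sum(sb))


def random_graph(rng: np.random.Generator, n: int, p: float) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                graph.add_edge(i, j)
    return graph
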