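"""PPI network topology: centrality measures, redundancy pruning, hub calls.

Eight node-centrality measures are implemented over an undirected simple
graph: degree, betweenness (Brandes, normalised), closeness
(component-restricted), eigenvector (per component, unit-max normalised),
information (Stephenson-Zelen, via the inverse of Laplacian + all-ones),
subgraph (diagonal of the adjacency matrix exponential), the
edge-clustering-coefficient sum (``nc``), and local average connectivity
(``lac``).  Betweenness and the all-pairs distance matrix are delegated to
igraph's C implementations; everything else is dense/sparse linear algebra
on a fixed node ordering, so results are deterministic.
"""

from __future__ import annotations

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse import csgraph

from ._util import log, nearest_rank_percentile

MEASURES = (
    "degree",
    "betweenness",
    "closeness",
    "eigenvector",
    "information",
    "subgraph",
    "nc",
    "lac",
)

#: The redundancy-pruned subset retained for the cohort comparisons.
SEED_MEASURES = ("betweenness", "eigenvector", "closeness", "information")

HUB_PERCENTILE = 0.90

#: Above this node count, subgraph centrality falls back to a truncated
#: power series (k <= 20) instead of a full eigendecomposition.
SUBGRAPH_EIG_MAX_NODES = 5000


class _GraphData:
    """Shared precomputation: node order, adjacency, degrees, components."""

    def __init__(self, graph: nx.Graph):
        if graph.number_of_nodes() == 0:
            raise ValueError("empty graph")
        if any(graph.has_edge(v, v) for v in graph):
            raise ValueError("self-loops are not allowed in a simple PPI graph")
        self.nodes = sorted(graph.nodes)
        self.index = {v: i for i, v in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.adj = nx.to_scipy_sparse_array(graph, nodelist=self.nodes, format="csr", dtype=float)
        self.degrees = np.asarray(self.adj.sum(axis=1)).ravel()
        n_comp, labels = csgraph.connected_components(self.adj, directed=False)
        self.comp_labels = labels
        self.components = [np.flatnonzero(labels == c) for c in range(n_comp)]
        edges = [(self.index[a], self.index[b]) for a, b in graph.edges]
        self.igraph = ig.Graph(n=self.n, edges=edges, directed=False)

    def wrap(self, values: np.ndarray) -> dict:
        return dict(zip(self.nodes, np.asarray(values, dtype=float)))


def compute_centrality(graph: nx.Graph, measure: str) -> dict:
    """One centrality measure as a node -> value map."""
    if measure not in MEASURES:
        raise ValueError(f"unknown centrality measure {measure!r}")
    data = _GraphData(graph)
    return data.wrap(_MEASURE_FUNCS[measure](data))


def compute_all_centralities(graph: nx.Graph, measures=MEASURES) -> pd.DataFrame:
    """All requested measures in one pass, sharing the graph precomputation."""
    data = _GraphData(graph)
    cols = {}
    for measure in measures:
        if measure not in MEASURES:
            raise ValueError(f"unknown centrality measure {measure!r}")
        cols[measure] = _MEASURE_FUNCS[measure](data)
    df = pd.DataFrame(cols, index=pd.Index(data.nodes, name="protein_id"))
    if not np.isfinite(df.to_numpy()).all():
        raise AssertionError("non-finite centrality value")
    return df


def _degree(data: _GraphData) -> np.ndarray:
    return data.degrees


def _betweenness(data: _GraphData) -> np.ndarray:
    raw = np.array(data.igraph.betweenness(directed=False), dtype=float)
    if data.n < 3:
        return np.zeros(data.n)
    return raw / ((data.n - 1) * (data.n - 2) / 2.0)


def _distance_matrix(data: _GraphData) -> np.ndarray:
    return np.array(data.igraph.distances(), dtype=float)


def _closeness(data: _GraphData) -> np.ndarray:
    dist = _distance_matrix(data)
    out = np.zeros(data.n)
    for comp in data.components:
        if comp.size < 2:
            continue  # isolated nodes keep closeness 0
        sub = dist[np.ix_(comp, comp)]
        out[comp] = (comp.size - 1) / sub.sum(axis=1)
    return out


def _eigenvector(data: _GraphData, norm: str = "max") -> np.ndarray:
    """Principal adjacency eigenvector, computed independently per component.

    Each component's vector is normalised to unit maximum (configurable to
    unit L2); single-node components get 0, as eigenvector centrality is
    undefined without edges.
    """
    out = np.zeros(data.n)
    for comp in data.components:
        if comp.size < 2:
            continue
        sub = data.adj[comp][:, comp].toarray()
        eigvals, eigvecs = np.linalg.eigh(sub)
        vec = np.abs(eigvecs[:, -1])
        scale = vec.max() if norm == "max" else np.linalg.norm(vec)
        out[comp] = vec / scale if scale > 0 else 0.0
    return out


def _information(data: _GraphData) -> np.ndarray:
    """Stephenson-Zelen information centrality per component.

    With C = (L + J)^-1 on a component of size n_c (L the Laplacian, J the
    all-ones matrix), node i scores n_c / sum_j (C_ii + C_jj - 2 C_ij).
    """
    out = np.zeros(data.n)
    for comp in data.components:
        n_c = comp.size
        if n_c < 2:
            continue
        sub = data.adj[comp][:, comp].toarray()
        lap = np.diag(sub.sum(axis=1)) - sub
        c_mat = np.linalg.inv(lap + np.ones((n_c, n_c)))
        diag = np.diag(c_mat)
        denom = n_c * diag + diag.sum() - 2.0 * c_mat.sum(axis=1)
        out[comp] = n_c / denom
    return out


def _subgraph(data: _GraphData) -> np.ndarray:
    """Subgraph centrality sum_k (A^k)_ii / k! via symmetric eigendecomposition;
    truncated power series (k <= 20) above the dense-size threshold."""
    if data.n > SUBGRAPH_EIG_MAX_NODES:
        out = np.ones(data.n)  # k = 0 term
        term = sp.identity(data.n, format="csr")
        fact = 1.0
        for k in range(1, 21):
            term = term @ data.adj
            fact *= k
            out += term.diagonal() / fact
        return out
    out = np.zeros(data.n)
    for comp in data.components:
        if comp.size == 1:
            out[comp] = 1.0
            continue
        sub = data.adj[comp][:, comp].toarray()
        eigvals, eigvecs = np.linalg.eigh(sub)
        out[comp] = (eigvecs**2) @ np.exp(eigvals)
    return out


def _edge_triangles(data: _GraphData) -> sp.csr_matrix:
    """z_ij = number of triangles on edge (i, j), as a sparse matrix on edges."""
    a = data.adj.tocsr()
    common = (a @ a).multiply(a)  # common-neighbour counts restricted to edges
    return common.tocsr()


def _nc(data: _GraphData) -> np.ndarray:
    """Edge-clustering-coefficient sum: sum over incident edges of
    z_ij / min(d_i - 1, d_j - 1), term 0 when the denominator is 0."""
    common = sp.coo_array(_edge_triangles(data))
    denom = np.minimum(data.degrees[common.row], data.degrees[common.col]) - 1.0
    contrib = np.where(denom > 0, common.data / np.where(denom > 0, denom, 1.0), 0.0)
    out = np.zeros(data.n)
    np.add.at(out, common.row, contrib)
    return out


def _lac(data: _GraphData) -> np.ndarray:
    """Local average connectivity: mean, over the neighbours of i, of their
    degree within the subgraph induced by N(i); 0 for isolated nodes."""
    common = _edge_triangles(data)
    sums = np.asarray(common.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(data.degrees > 0, sums / data.degrees, 0.0)
    return out


_MEASURE_FUNCS = {
    "degree": _degree,
    "betweenness": _betweenness,
    "closeness": _closeness,
    "eigenvector": _eigenvector,
    "information": _information,
    "subgraph": _subgraph,
    "nc": _nc,
    "lac": _lac,
}


def select_orthogonal(
    measure_values: pd.DataFrame,
    low: float = 0.6,
    high: float = 0.8,
    seeds=SEED_MEASURES,
) -> dict:
    """Verify (or greedily re-select) a low-redundancy centrality subset.

    The seed subset must have pairwise Spearman |rho| < ``low`` while every
    removed measure correlates with |rho| > ``high`` to at least one kept
    measure.  When the verification fails on the given data, measures are
    re-selected greedily in a fixed priority order (seeds first), keeping a
    measure iff it stays below ``low`` against everything already kept.
    """
    df = measure_values.copy()
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        log.warning("select_orthogonal: excluding constant measures %s", constant)
        df = df.drop(columns=constant)
    if df.shape[1] < 2:
        raise ValueError("need at least two non-constant measures")
    corr = df.corr(method="spearman")
    seeds = [s for s in seeds if s in df.columns]
    removed = [c for c in df.columns if c not in seeds]
    seed_ok = all(
        abs(corr.loc[a, b]) < low for i, a in enumerate(seeds) for b in seeds[i + 1 :]
    )
    coverage = {
        m: float(max((abs(corr.loc[m, s]) for s in seeds), default=0.0)) for m in removed
    }
    removed_ok = all(v > high for v in coverage.values())
    verified = seed_ok and removed_ok
    if verified:
        kept = list(seeds)
    else:
        priority = list(seeds) + [m for m in df.columns if m not in seeds]
        kept = []
        for m in priority:
            if all(abs(corr.loc[m, k]) < low for k in kept):
                kept.append(m)
        coverage = {
            m: float(max((abs(corr.loc[m, k]) for k in kept), default=0.0))
            for m in df.columns
            if m not in kept
        }
    return {
        "kept": kept,
        "correlations": corr,
        "verified": verified,
        "seed_pairwise_ok": seed_ok,
        "uncovered_removed": sorted(m for m, v in coverage.items() if v <= high),
        "excluded_constant": constant,
    }


def annotate_hubs(graph: nx.Graph, q: float = HUB_PERCENTILE) -> tuple:
    """Hub = node whose degree meets the nearest-rank q-percentile cutoff.

    Hubness is a property of the complete interactome: the cutoff is always
    computed on the full input graph, never per cohort.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degrees = dict(graph.degree())
    values = np.array(list(degrees.values()))
    cutoff = nearest_rank_percentile(values, q)
    hubs = {v for v, d in degrees.items() if d >= cutoff}
    if values.min() == values.max():
        log.warning("annotate_hubs: degenerate degree distribution, every node is a hub")
    return hubs, int(cutoff)
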