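"""GO over-representation and Wang-measure semantic similarity.

Enrichment compares a protein set against a reference proteome per
namespace: annotations are ancestor-closed over the DAG, each term gets a
one-sided Fisher p-value, Benjamini-Hochberg FDR is applied within the
namespace, and a term counts as associated with the set when it occurs at
least 10 times, its fold ratio exceeds 2, and its q-value is below 0.05.

Set-level similarity between cohorts uses the Wang term measure (weighted
S-value contributions of shared ancestors) combined by best-match average
(BMA), computed per namespace and averaged across MF, BP, and CC.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._util import log
from .stats import fisher_exact

NAMESPACES = ("MF", "BP", "CC")

MIN_COUNT = 10
MIN_FOLD = 2.0
MAX_FDR = 0.05

#: Cohort pairs whose enriched-term sets are compared.
SIMILARITY_PAIRS = [("D", "Nd"), ("D", "Nn"), ("D", "N"), ("Nn", "Nd")]


@dataclasses.dataclass
class EnrichmentResult:
    term_id: str
    namespace: str
    count_in_set: int
    count_in_reference: int
    fold_ratio: float
    p_value: float
    q_value: float
    passes: bool


def ancestor_close(annotations: pd.DataFrame, dag) -> dict:
    """protein -> set of annotated terms plus all their DAG ancestors."""
    closed = {}
    for pid, grp in annotations.groupby("protein_id"):
        terms = set()
        for term in grp["term_id"]:
            terms |= dag.ancestors(term)
        closed[pid] = terms
    return closed


def enrich(
    set_proteins,
    reference_proteins,
    annotations: pd.DataFrame,
    dag,
    close_ancestors: bool = True,
    min_count: int = MIN_COUNT,
    min_fold: float = MIN_FOLD,
    max_fdr: float = MAX_FDR,
) -> list:
    """Per-namespace over-representation of ``set_proteins`` vs the reference.

    The 2x2 table for a term with k_S hits among |S| set proteins and k_R
    hits among |R| reference proteins is [[k_S, |S|-k_S],
    [k_R-k_S, (|R|-|S|)-(k_R-k_S)]] with a one-sided (greater) Fisher test;
    fold ratio is (k_S/|S|) / (k_R/|R|).
    """
    set_proteins = set(set_proteins)
    reference_proteins = set(reference_proteins)
    if not set_proteins:
        raise ValueError("empty protein set for enrichment")
    if not set_proteins <= reference_proteins:
        raise ValueError("protein set must be a subset of the reference")
    if close_ancestors:
        per_protein = ancestor_close(annotations, dag)
    else:
        per_protein = {
            pid: set(grp["term_id"]) for pid, grp in annotations.groupby("protein_id")
        }
    n_set = len(set_proteins)
    n_ref = len(reference_proteins)
    counts_set: dict = {}
    counts_ref: dict = {}
    for pid in reference_proteins:
        for term in per_protein.get(pid, ()):
            counts_ref[term] = counts_ref.get(term, 0) + 1
            if pid in set_proteins:
                counts_set[term] = counts_set.get(term, 0) + 1
    results = []
    for ns in NAMESPACES:
        terms = sorted(t for t in counts_ref if dag.namespace(t) == ns)
        if not terms:
            continue
        raw_p = []
        for term in terms:
            k_s = counts_set.get(term, 0)
            k_r = counts_ref[term]
            _, p = fisher_exact(
                k_s, n_set - k_s, k_r - k_s, (n_ref - n_set) - (k_r - k_s),
                alternative="greater",
            )
            raw_p.append(p)
        q_values = multipletests(raw_p, method="fdr_bh")[1]
        for term, p, q in zip(terms, raw_p, q_values):
            k_s = counts_set.get(term, 0)
            k_r = counts_ref[term]
            fold = (k_s / n_set) / (k_r / n_ref) if k_r else 0.0
            results.append(
                EnrichmentResult(
                    term_id=term,
                    namespace=ns,
                    count_in_set=k_s,
                    count_in_reference=k_r,
                    fold_ratio=float(fold),
                    p_value=float(p),
                    q_value=float(q),
                    passes=bool(k_s >= min_count and fold > min_fold and q < max_fdr),
                )
            )
    return results


def enrichment_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


# ---------------------------------------------------------------------------
# Wang semantic similarity


def _s_values(term: str, dag) -> dict:
    """Wang S-values: downward max-propagation over the term's ancestor closure.

    S(term) = 1; for an ancestor t, S(t) = max over children t' of t within
    the closure of w_e(t' -> t) * S(t').
    """
    closure = dag.ancestors(term)
    sub = dag.graph.subgraph(closure)
    s: dict = {}
    # edges run child -> parent, so a topological order visits the query term
    # first and every ancestor after all of its in-closure children
    for t in nx.topological_sort(sub):
        if t == term:
            s[t] = 1.0
        else:
            s[t] = max(w * s[c] for c, w in dag.children_in(t, closure))
    return s


def wang_term_similarity(a: str, b: str, dag) -> float:
    """Wang similarity of two terms in the same namespace, in [0, 1]."""
    if a not in dag or b not in dag:
        raise ValueError(f"unknown term in pair ({a!r}, {b!r})")
    if dag.namespace(a) != dag.namespace(b):
        raise ValueError(f"cross-namespace term pair ({a!r}, {b!r})")
    s_a = _s_values(a, dag)
    s_b = _s_values(b, dag)
    shared = set(s_a) & set(s_b)
    if not shared:
        return 0.0
    num = sum(s_a[t] + s_b[t] for t in shared)
    return num / (sum(s_a.values()) + sum(s_b.values()))


def set_similarity_bma(terms1, terms2, dag) -> float:
    """Best-match-average similarity between two term sets (same namespace)."""
    terms1, terms2 = sorted(set(terms1)), sorted(set(terms2))
    if not terms1 or not terms2:
        raise ValueError("empty term set in BMA similarity")
    sims = {
        (a, b): wang_term_similarity(a, b, dag) for a in terms1 for b in terms2
    }
    row_best = sum(max(sims[(a, b)] for b in terms2) for a in terms1)
    col_best = sum(max(sims[(a, b)] for a in terms1) for b in terms2)
    return (row_best + col_best) / (len(terms1) + len(terms2))


def enriched_term_sets(
    cohorts: dict,
    reference_proteins,
    annotations: pd.DataFrame,
    dag,
    close_ancestors: bool = True,
    min_count: int = MIN_COUNT,
) -> dict:
    """cohort -> namespace -> set of terms passing the enrichment filters."""
    out = {}
    for name, members in cohorts.items():
        results = enrich(members, reference_proteins, annotations, dag,
                         close_ancestors=close_ancestors, min_count=min_count)
        per_ns = {ns: set() for ns in NAMESPACES}
        for r in results:
            if r.passes:
                per_ns[r.namespace].add(r.term_id)
        out[name] = per_ns
    return out


def cohort_similarity(
    partition,
    annotations: pd.DataFrame,
    dag,
    reference_proteins,
    pairs=None,
    cohorts=("D", "N", "Nd", "Nn"),
    use_all_annotated: bool = False,
) -> pd.DataFrame:
    """Per-namespace BMA similarity of cohort term sets, plus the mean.

    By default the compared sets are the over-represented (passing) terms;
    ``use_all_annotated`` switches to each cohort's full ancestor-closed
    annotation sets instead.  Cells without terms on either side are absent
    and the mean is taken over the available namespaces.
    """
    pairs = SIMILARITY_PAIRS if pairs is None else pairs
    if use_all_annotated:
        closed = ancestor_close(annotations, dag)
        term_sets = {}
        for name in cohorts:
            per_ns = {ns: set() for ns in NAMESPACES}
            for pid in partition[name]:
                for term in closed.get(pid, ()):
                    per_ns[dag.namespace(term)].add(term)
            term_sets[name] = per_ns
    else:
        term_sets = enriched_term_sets(
            {name: partition[name] for name in cohorts}, reference_proteins, annotations, dag
        )
    rows = []
    for a, b in pairs:
        row = {"pair": f"{a}-{b}"}
        values = []
        for ns in NAMESPACES:
            t1, t2 = term_sets[a][ns], term_sets[b][ns]
            if not t1 or not t2:
                log.warning("cohort_similarity: no enriched %s terms for %s-%s", ns, a, b)
                row[ns] = np.nan
                continue
            row[ns] = set_similarity_bma(t1, t2, dag)
            values.append(row[ns])
        row["mean"] = float(np.mean(values)) if values else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("pair")
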