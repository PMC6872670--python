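"""Domain types and file I/O for the druggability corpus.

A corpus bundles everything the comparative analysis consumes: protein
records (sequence, isoforms, domain intervals, per-residue score tracks),
PSSMs, compound-protein interactions, protein-disease associations, a
protein-protein interaction network, and a GO-style ontology DAG with
protein annotations.  All on-disk formats are plain text: FASTA, TSV with a
header row and '#' comments, the PSI-BLAST ASCII PSSM dialect, and an OBO
subset (or typed edge-list TSV) for the DAG.

Domain intervals are 1-based inclusive in files and converted to 0-based
half-open tuples internally; that conversion happens here and nowhere else.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
import os
import re
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from Bio import SeqIO

from ._util import log

#: Canonical amino-acid alphabet (alphabetical); PSSM columns follow it.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Column order of the PSI-BLAST ASCII PSSM dialect.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"
_PSIBLAST_TO_CANON = [PSIBLAST_ORDER.index(a) for a in AMINO_ACIDS]

#: Default semantic contribution factors per DAG edge type (Wang measure).
DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}

TRACK_NAMES = ("disorder", "rsa", "binding")

TABLE_SCHEMAS = {
    "interactions": ["compound_id", "structure", "protein_id", "drug_status"],
    "diseases": ["protein_id", "disease_id", "disease_class"],
    "annotations": ["protein_id", "term_id"],
    "tracks": ["protein_id", "position", "score"],
    "isoforms": ["protein_id", "isoform_count"],
    "domains": ["protein_id", "start", "end"],
    "identity": ["protein_a", "protein_b", "identity"],
}

DRUG_STATUSES = ("approved", "experimental", "other")


class CorpusError(ValueError):
    """Raised when an input file violates a corpus invariant."""


@dataclasses.dataclass
class ProteinRecord:
    """One protein: identifier, sequence, isoforms, domains, residue tracks.

    ``domains`` holds 0-based half-open intervals.  ``tracks`` maps a track
    name ('disorder', 'rsa', 'binding') to a per-residue vector in [0, 1]
    whose length equals the sequence length.  Every expressed protein is its
    own isoform, so ``isoform_count`` is at least 1.
    """

    protein_id: str
    sequence: str
    isoform_count: int = 1
    domains: list = dataclasses.field(default_factory=list)
    tracks: dict = dataclasses.field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if not self.protein_id:
            raise CorpusError("empty protein id")
        if self.length == 0:
            raise CorpusError(f"{self.protein_id}: empty sequence")
        if self.isoform_count < 1:
            raise CorpusError(f"{self.protein_id}: isoform_count must be >= 1")
        for start, end in self.domains:
            if not (0 <= start < end <= self.length):
                raise CorpusError(
                    f"{self.protein_id}: domain ({start}, {end}) outside sequence "
                    f"of length {self.length}"
                )
        for name, vec in self.tracks.items():
            vec = np.asarray(vec)
            if vec.shape != (self.length,):
                raise CorpusError(
                    f"{self.protein_id}: track '{name}' has {vec.size} values "
                    f"for a protein of length {self.length}"
                )
            if np.any(vec < 0) or np.any(vec > 1):
                raise CorpusError(f"{self.protein_id}: track '{name}' outside [0, 1]")


@dataclasses.dataclass
class Pssm:
    """Per-position amino-acid probabilities plus a background distribution.

    Rows sum to one (after pseudocount renormalisation) and are strictly
    positive, which the relative-entropy conservation score requires.
    """

    protein_id: str
    probs: np.ndarray  # (L, 20), canonical alphabet order
    background: np.ndarray  # (20,)

    def validate(self) -> None:
        if self.probs.ndim != 2 or self.probs.shape[1] != 20:
            raise CorpusError(f"{self.protein_id}: PSSM must be L x 20")
        if np.any(self.probs <= 0) or np.any(self.background <= 0):
            raise CorpusError(f"{self.protein_id}: PSSM has non-positive entries")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise CorpusError(f"{self.protein_id}: PSSM rows do not sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise CorpusError(f"{self.protein_id}: background does not sum to 1")


class GoDag:
    """Acyclic ontology over typed child->parent edges with semantic weights.

    Terms carry a namespace in {MF, BP, CC}; each edge is typed ``is_a`` or
    ``part_of`` and carries a contribution weight in (0, 1) used by the Wang
    similarity measure.
    """

    def __init__(self, graph: nx.DiGraph):
        self.graph = graph
        self._ancestor_cache: dict = {}

    @property
    def terms(self):
        return list(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term]["namespace"]

    def parents(self, term: str):
        """(parent, weight) pairs for the term's outgoing typed edges."""
        return [(p, self.graph.edges[term, p]["weight"]) for p in self.graph.successors(term)]

    def children_in(self, term: str, closure: set):
        """(child, weight) pairs restricted to a term closure."""
        return [
            (c, self.graph.edges[c, term]["weight"])
            for c in self.graph.predecessors(term)
            if c in closure
        ]

    def ancestors(self, term: str) -> frozenset:
        """The term itself plus every DAG ancestor (transitive parents)."""
        if term not in self._ancestor_cache:
            if term not in self.graph:
                raise CorpusError(f"unknown ontology term {term!r}")
            self._ancestor_cache[term] = frozenset(nx.descendants(self.graph, term)) | {term}
        return self._ancestor_cache[term]

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise CorpusError(f"ontology contains a cycle: {cycle}")
        for _, _, data in self.graph.edges(data=True):
            if not 0 < data["weight"] < 1:
                raise CorpusError("ontology edge weight outside (0, 1)")
        for term, data in self.graph.nodes(data=True):
            if data.get("namespace") not in {"MF", "BP", "CC"}:
                raise CorpusError(f"term {term} lacks a valid namespace")


@dataclasses.dataclass
class Corpus:
    """Everything one analysis run consumes, already validated."""

    proteome: dict  # protein_id -> ProteinRecord
    pssms: dict  # protein_id -> Pssm
    interactions: pd.DataFrame
    diseases: pd.DataFrame
    ppi: nx.Graph
    dag: GoDag | None = None
    annotations: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list:
    """Read a FASTA file into (protein_id, sequence) pairs.

    IDs are the first whitespace-delimited header token; sequences are
    uppercased and non-canonical letters are mapped to X with a warning.
    Empty files and duplicate IDs are hard errors.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise CorpusError(f"duplicate FASTA id {pid!r}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        cleaned = re.sub(f"[^{AMINO_ACIDS}X]", "X", seq)
        if cleaned != seq:
            log.warning("fasta %s: non-canonical letters mapped to X", pid)
        if not cleaned:
            raise CorpusError(f"FASTA record {pid!r} has an empty sequence")
        records.append((pid, cleaned))
    if not records:
        raise CorpusError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable, path) -> None:
    with open(path, "w") as fh:
        for pid, seq in records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PSSM


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20)


def read_pssm(
    path,
    pseudocount: float = 1e-4,
    background: np.ndarray | None = None,
    expected_length: int | None = None,
    protein_id: str | None = None,
) -> Pssm:
    """Read a PSSM from either the PSI-BLAST ASCII dialect or a plain TSV.

    For the ASCII dialect the weighted-observed-percentage columns (not the
    log-odds) are taken and divided by 100.  A pseudocount is added and each
    row renormalised so all probabilities are strictly positive.
    """
    with open(path) as fh:
        text = fh.read()
    if "position-specific scoring matrix" in text or "Last position-specific" in text:
        probs = _parse_psiblast_ascii(text)
    else:
        rows = np.loadtxt(_stdio.StringIO(text), ndmin=2)
        if rows.shape[1] != 20:
            raise CorpusError(f"{path}: PSSM TSV must have 20 columns, got {rows.shape[1]}")
        probs = rows
    if np.any(probs < 0):
        raise CorpusError(f"{path}: negative PSSM entries")
    if expected_length is not None and probs.shape[0] != expected_length:
        raise CorpusError(
            f"{path}: PSSM has {probs.shape[0]} rows but the sequence has "
            f"{expected_length} residues"
        )
    probs = probs + pseudocount
    row_sums = probs.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise CorpusError(f"{path}: PSSM row with zero total probability")
    probs = probs / row_sums
    bg = uniform_background() if background is None else np.asarray(background, dtype=float)
    pssm = Pssm(protein_id or os.path.splitext(os.path.basename(str(path)))[0], probs, bg)
    pssm.validate()
    return pssm


def _parse_psiblast_ascii(text: str) -> np.ndarray:
    rows = []
    for line in text.splitlines():
        parts = line.split()
        # data rows: index, residue, 20 log-odds, 20 percentages, info, weight
        if len(parts) >= 42 and parts[0].isdigit():
            perc = np.array([float(x) for x in parts[22:42]])
            rows.append(perc[_PSIBLAST_TO_CANON] / 100.0)
    if not rows:
        raise CorpusError("no data rows found in PSI-BLAST ASCII PSSM")
    return np.vstack(rows)


def write_pssm_ascii(protein_id: str, sequence: str, percentages: np.ndarray, path) -> None:
    """Write the PSI-BLAST ASCII dialect (`-out_ascii_pssm` layout).

    ``percentages`` is (L, 20) in canonical alphabet order, summing to ~100
    per row.  Log-odds columns are emitted as zeros; only the
    weighted-observed-percentage block is meaningful downstream.
    """
    canon_to_psi = [AMINO_ACIDS.index(a) for a in PSIBLAST_ORDER]
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed, weighted ")
        fh.write("observed percentages rounded down, information per position, ")
        fh.write("and relative weight of gapless real matches to pseudocounts\n")
        fh.write(" " * 11 + "  ".join(PSIBLAST_ORDER) + "   " + "  ".join(PSIBLAST_ORDER) + "\n")
        for i, (aa, row) in enumerate(zip(sequence, percentages), start=1):
            psi_row = row[canon_to_psi]
            lod = " ".join(["0"] * 20)
            perc = " ".join(f"{v:.0f}" for v in psi_row)
            fh.write(f"{i:5d} {aa}  {lod}  {perc}  0.00 0.00\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a TSV table, enforce its schema, and drop duplicate rows."""
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = TABLE_SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CorpusError(f"{path}: missing required column(s) {missing}")
    df = df[required]
    before = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    if before - len(df):
        log.info("%s: dropped %d duplicate rows", path, before - len(df))
    for col in ("position", "isoform_count", "start", "end"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    for col in ("score", "identity"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    if schema == "interactions":
        bad = set(df["drug_status"]) - set(DRUG_STATUSES)
        if bad:
            raise CorpusError(f"{path}: unknown drug_status values {sorted(bad)}")
        if (df["protein_id"] == "").any():
            raise CorpusError(f"{path}: empty protein_id in interactions")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def attach_tracks(proteome: Mapping, track_df: pd.DataFrame, name: str) -> None:
    """Attach a per-residue score track (long TSV form) to protein records.

    Positions are 1-based in the file.  A vector whose length disagrees with
    the protein length is a hard error; proteins absent from the file simply
    lack the track (markers will be marked absent, not zero).
    """
    for pid, grp in track_df.groupby("protein_id"):
        if pid not in proteome:
            log.warning("track %s: unknown protein %s (ignored)", name, pid)
            continue
        rec = proteome[pid]
        grp = grp.sort_values("position")
        if len(grp) != rec.length or grp["position"].iloc[0] != 1:
            raise CorpusError(
                f"track '{name}' for {pid}: {len(grp)} values for a protein of "
                f"length {rec.length}"
            )
        vec = grp["score"].to_numpy(dtype=float)
        if np.any(vec < 0) or np.any(vec > 1):
            raise CorpusError(f"track '{name}' for {pid}: scores outside [0, 1]")
        rec.tracks[name] = vec


def tracks_to_table(proteome: Mapping, name: str) -> pd.DataFrame:
    rows = []
    for pid, rec in proteome.items():
        if name in rec.tracks:
            vec = rec.tracks[name]
            rows.append(
                pd.DataFrame(
                    {"protein_id": pid, "position": np.arange(1, len(vec) + 1), "score": vec}
                )
            )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=TABLE_SCHEMAS["tracks"]
    )


def attach_domains(proteome: Mapping, domain_df: pd.DataFrame) -> None:
    """Attach 1-based inclusive domain intervals, converting to 0-based half-open."""
    for _, row in domain_df.iterrows():
        pid = row["protein_id"]
        if pid not in proteome:
            log.warning("domains: unknown protein %s (ignored)", pid)
            continue
        rec = proteome[pid]
        start, end = int(row["start"]), int(row["end"])
        if not (1 <= start <= end <= rec.length):
            raise CorpusError(
                f"domain [{start}, {end}] outside protein {pid} (length {rec.length})"
            )
        rec.domains.append((start - 1, end))


def attach_isoforms(proteome: Mapping, isoform_df: pd.DataFrame) -> None:
    """Attach isoform counts; proteins absent from the table keep count 1."""
    for _, row in isoform_df.iterrows():
        pid = row["protein_id"]
        if pid in proteome:
            proteome[pid].isoform_count = max(1, int(row["isoform_count"]))


def validate_cross_references(proteome: Mapping, *tables: pd.DataFrame) -> list:
    """Flag (do not drop) table rows referencing unknown proteins."""
    report = []
    for df in tables:
        if df is None or "protein_id" not in df.columns:
            continue
        unknown = sorted(set(df["protein_id"]) - set(proteome))
        if unknown:
            report.append(f"{len(unknown)} protein ids not in proteome: {unknown[:5]}...")
            log.warning("cross-reference: %s", report[-1])
    return report


# ---------------------------------------------------------------------------
# PPI edge list


def read_ppi(path) -> nx.Graph:
    """Read an undirected PPI edge list (two ID columns, '#' comments).

    Self-loops and parallel edges are dropped with a warning so the graph is
    simple.
    """
    graph = nx.Graph()
    dropped = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise CorpusError(f"{path}: malformed edge line {line!r}")
            a, b = parts[0], parts[1]
            if a == b or graph.has_edge(a, b):
                dropped += 1
                continue
            graph.add_edge(a, b)
    if dropped:
        log.warning("%s: dropped %d self-loop/duplicate edges", path, dropped)
    return graph


def write_ppi(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Ontology


def read_go(
    dag_path,
    annotation_path=None,
    edge_weights: Mapping | None = None,
):
    """Read an ontology DAG (OBO subset or typed edge-list TSV) + annotations.

    Returns (GoDag, AnnotationTable or None).  Annotations referring to terms
    absent from the DAG are dropped with a warning.  Cycles are hard errors.
    """
    weights = dict(DEFAULT_EDGE_WEIGHTS)
    if edge_weights:
        weights.update(edge_weights)
    with open(dag_path) as fh:
        head = fh.read(4096)
    if "[Term]" in head or "format-version" in head:
        dag = _dag_from_obo(dag_path, weights)
    else:
        dag = _dag_from_edgelist(dag_path, weights)
    dag.validate()
    annotations = None
    if annotation_path is not None:
        annotations = read_table(annotation_path, "annotations")
        known = annotations["term_id"].isin(set(dag.graph.nodes))
        if (~known).any():
            log.warning(
                "annotations: dropped %d rows with terms absent from the DAG", (~known).sum()
            )
            annotations = annotations[known].reset_index(drop=True)
    return dag, annotations


_OBO_NAMESPACES = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
    "MF": "MF",
    "BP": "BP",
    "CC": "CC",
}


def _dag_from_obo(path, weights) -> GoDag:
    multigraph = obonet.read_obo(str(path))
    graph = nx.DiGraph()
    for term, data in multigraph.nodes(data=True):
        ns = _OBO_NAMESPACES.get(data.get("namespace", ""), None)
        if ns is None:
            raise CorpusError(f"term {term} has unsupported namespace {data.get('namespace')!r}")
        graph.add_node(term, namespace=ns)
    for child, parent, rel in multigraph.edges(keys=True):
        if rel not in weights:
            log.warning("ontology: ignoring edge type %r", rel)
            continue
        _add_dag_edge(graph, child, parent, rel, weights[rel])
    return GoDag(graph)


def _dag_from_edgelist(path, weights) -> GoDag:
    graph = nx.DiGraph()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("child", "parent", "relation", "child_namespace"):
        if col not in df.columns and col != "child_namespace":
            raise CorpusError(f"{path}: missing required column {col!r}")
    ns_col = "namespace" if "namespace" in df.columns else None
    for _, row in df.iterrows():
        rel = row["relation"]
        if rel not in weights:
            raise CorpusError(f"{path}: unknown relation {rel!r}")
        ns = _OBO_NAMESPACES.get(row[ns_col], None) if ns_col else None
        for term in (row["child"], row["parent"]):
            if term not in graph:
                graph.add_node(term, namespace=ns or "MF")
            elif ns:
                graph.nodes[term]["namespace"] = graph.nodes[term].get("namespace", ns)
        _add_dag_edge(graph, row["child"], row["parent"], rel, weights[rel])
    return GoDag(graph)


def _add_dag_edge(graph, child, parent, rel, weight):
    if child == parent:
        raise CorpusError(f"ontology self-edge on {child} (cycle)")
    graph.add_edge(child, parent, relation=rel, weight=weight)


def write_go_edgelist(dag: GoDag, path) -> None:
    with open(path, "w") as fh:
        fh.write("child\tparent\trelation\tnamespace\n")
        for child, parent, data in sorted(dag.graph.edges(data=True)):
            fh.write(f"{child}\t{parent}\t{data['relation']}\t{dag.namespace(child)}\n")
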