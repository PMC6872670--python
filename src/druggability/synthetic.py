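"""Synthetic corpus generator with planted, configurable group effects.

The generator emulates the statistical structure of the real data sources
the analysis was designed for — heavy-tailed drug-interaction counts,
scale-free-ish PPI degree distributions, length-dependent intrinsic
disorder, overdispersed disease-association counts with a three-regime
mixture (zero-inflated / background / high-mean), and DAG-structured
functional annotations — without requiring any download.

Proteins carry a hidden group intent (``target``, ``nd`` for the
high-disease possibly druggable regime, ``nn`` for the disease-free regime,
``background``), and each marker's group mean is the configured base plus a
planted location offset.  The manifest records every intent, the planted
means, the expected cohort-level median orderings with their minimum
significance tier, the expected signs of the relative-difference summary,
and the analytic plateau onset of the disease curve, so parameter-recovery
tests have an explicit ground truth.  ``null_mode`` zeroes every planted
effect while keeping the cohort-defining disease structure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import log, substream
from . import corpus as cio
from .cohorts import DiseaseCurve, select_k

GROUPS = ("target", "nd", "nn", "background")

#: Markers whose group means are planted directly (track aggregates are
#: realised per residue; counts are Poisson means).
TRACK_MARKERS = ("disorder", "conservation", "surface", "binding")


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions for one synthetic corpus."""

    seed: int = 0
    n_targets: int = 500
    n_nontargets: int = 500

    # sequence length: log-normal, clamped
    length_mu: float = 5.93  # exp() ~ 375 residues
    length_sigma: float = 0.55
    length_min: int = 60
    length_max: int = 1800

    # drug-interaction counts over targets: truncated discrete power law
    interaction_exponent: float = 1.6
    interaction_max: int = 443
    n_compounds: int = 2000
    compound_popularity_exponent: float = 1.1
    duplicate_structure_pairs: int = 30
    status_probs: tuple = (0.70, 0.25, 0.05)  # approved / experimental / other

    # disease-association mixture (three regimes)
    target_assoc_prob: float = 0.94
    target_disease_mean: float = 14.0
    target_disease_dispersion: float = 3.0
    nd_fraction: float = 0.15
    nd_disease_mean: float = 25.0
    nd_disease_dispersion: float = 0.8
    nn_fraction: float = 0.40
    background_disease_mean: float = 2.5
    background_disease_dispersion: float = 5.0
    n_diseases: int = 400
    n_disease_classes: int = 12

    # planted marker effects: base mean, offset for targets, offset for the
    # high-disease (nd) group; everything else sits at the base
    base_disorder: float = 0.30
    base_conservation: float = 0.28
    base_surface: float = 0.55
    base_binding: float = 0.12
    base_isoform_mean: float = 0.8  # extra isoforms beyond the mandatory one
    base_domain_mean: float = 1.0
    target_shift_disorder: float = -0.15
    target_shift_conservation: float = -0.13
    target_shift_surface: float = -0.10
    target_shift_binding: float = -0.05
    target_shift_isoform: float = 1.7
    target_shift_domain: float = 1.2
    nd_shift_disorder: float = 0.0
    nd_shift_conservation: float = -0.08
    nd_shift_surface: float = -0.07
    nd_shift_binding: float = 0.02
    nd_shift_isoform: float = 1.2
    nd_shift_domain: float = 1.4
    protein_jitter_sd: float = 0.05

    # PPI model: preferential attachment with group-biased attachment odds
    # and group-specific numbers of edges brought by each new node
    network_m: int = 3
    target_m: int = 5
    nd_m: int = 10
    nn_m: int = 2
    target_bias: float = 3.0
    nd_bias: float = 8.0
    nn_bias: float = 0.4

    # ontology model
    terms_per_namespace: int = 40
    annotation_mean: float = 2.5
    planted_annotation_rate: float = 0.35
    background_annotation_rate: float = 0.01

    # identity-expansion fixture
    near_duplicate_pairs: int = 4
    near_duplicate_mutation_rate: float = 0.05

    null_mode: bool = False

    def __post_init__(self):
        if self.null_mode:
            for f in dataclasses.fields(self):
                if f.name.startswith(("target_shift_", "nd_shift_")):
                    setattr(self, f.name, 0.0)
            self.target_bias = 1.0
            self.nd_bias = 1.0
            self.nn_bias = 1.0
            self.target_m = self.nd_m = self.nn_m = self.network_m
            self.planted_annotation_rate = self.background_annotation_rate
        if min(self.n_targets, self.n_nontargets) <= 0:
            raise ValueError("cohort sizes must be positive")
        if not 0 <= self.nd_fraction + self.nn_fraction <= 1:
            raise ValueError("nd_fraction + nn_fraction must lie in [0, 1]")
        if self.base_domain_mean * 160 > self.length_max:
            raise ValueError("domain model infeasible for the length clamp")

    def group_means(self) -> dict:
        base = {
            "disorder": self.base_disorder,
            "conservation": self.base_conservation,
            "surface": self.base_surface,
            "binding": self.base_binding,
            "isoform": self.base_isoform_mean,
            "domain": self.base_domain_mean,
        }
        means = {g: dict(base) for g in GROUPS}
        for marker in base:
            means["target"][marker] = base[marker] + getattr(self, f"target_shift_{marker}")
            means["nd"][marker] = base[marker] + getattr(self, f"nd_shift_{marker}")
        return means


# ---------------------------------------------------------------------------
# building blocks


def _truncated_power_law(rng, exponent: float, maximum: int, size: int) -> np.ndarray:
    values = np.arange(1, maximum + 1, dtype=float)
    probs = values**-exponent
    probs /= probs.sum()
    return rng.choice(np.arange(1, maximum + 1), size=size, p=probs)


def _nbinom(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _nbinom_sf(k: np.ndarray, mean: float, dispersion: float) -> np.ndarray:
    """P(X >= k) for the same parameterisation as :func:`_nbinom`."""
    p = dispersion / (dispersion + mean)
    return sps.nbinom.sf(np.asarray(k) - 1, dispersion, p)


def _segmented_track(rng, length: int, content: float, mean_segment: float = 12.0):
    """Per-residue scores in segments so thresholded runs form regions.

    Each segment adopts the high-score regime with probability ``content``;
    scores inside a segment are beta noise around the regime mean, so the
    aggregate above-cutoff fraction tracks the planted content.
    """
    scores = np.empty(length)
    pos = 0
    while pos < length:
        seg = min(1 + rng.geometric(1.0 / mean_segment), length - pos)
        if rng.random() < content:
            scores[pos : pos + seg] = rng.beta(8, 2, seg)
        else:
            scores[pos : pos + seg] = rng.beta(2, 8, seg)
        pos += seg
    return scores


def _rsa_track(rng, length: int, content: float) -> np.ndarray:
    """Bimodal relative solvent accessibility: exposed vs buried residues."""
    exposed = rng.random(length) < content
    out = np.where(exposed, rng.beta(3, 3, length), rng.beta(1, 12, length))
    return out


def _pssm_probs(rng, sequence: str, cons_fraction: float) -> np.ndarray:
    """Dirichlet rows: concentrated on the observed residue at conserved
    positions, near-background elsewhere."""
    length = len(sequence)
    conserved = rng.random(length) < cons_fraction
    alphas = np.full((length, 20), 8.0)
    idx = np.array([cio.AMINO_ACIDS.find(a) for a in sequence])
    idx[idx < 0] = 0  # X residues treated as alanine columns
    rows = np.flatnonzero(conserved)
    alphas[rows, :] = 0.25
    alphas[rows, idx[rows]] = 18.0
    draws = rng.gamma(alphas)
    return draws / draws.sum(axis=1, keepdims=True)


def _biased_preferential_attachment(rng, ids, bias, m_per_node) -> nx.Graph:
    """Barabasi-Albert-style growth where attachment odds are multiplied by a
    per-node bias and each arriving node brings its own number of edges,
    letting configured groups accrue centrality."""
    order = rng.permutation(len(ids))
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    weights = np.zeros(len(ids))
    active: list = []
    for rank, node_pos in enumerate(order):
        node = ids[node_pos]
        if rank == 0:
            weights[node_pos] = bias[node_pos]
            active.append(node_pos)
            continue
        k = min(m_per_node[node_pos], rank)
        probs = weights[active] / weights[active].sum()
        chosen = rng.choice(len(active), size=k, replace=False, p=probs)
        for c in chosen:
            peer_pos = active[c]
            graph.add_edge(node, ids[peer_pos])
            weights[peer_pos] += bias[peer_pos]
        weights[node_pos] = bias[node_pos] * (k + 1)
        active.append(node_pos)
    return graph


# ---------------------------------------------------------------------------
# generator


def generate_corpus(config: SyntheticConfig, out_dir=None):
    """Generate a complete corpus; optionally write it to ``out_dir``.

    Returns (Corpus, manifest dict).  Output is byte-identical for identical
    configs: every stage draws from its own named substream of the seed and
    all files are written in sorted order with fixed float formatting.
    """
    seed = config.seed
    means = config.group_means()

    # -- identities and group intents ------------------------------------
    rng = substream(seed, "groups")
    target_ids = [f"T{i:05d}" for i in range(config.n_targets)]
    nontarget_ids = [f"P{i:05d}" for i in range(config.n_nontargets)]
    n_nd = int(round(config.nd_fraction * config.n_nontargets))
    n_nn = int(round(config.nn_fraction * config.n_nontargets))
    intents = np.array(
        ["nd"] * n_nd + ["nn"] * n_nn + ["background"] * (config.n_nontargets - n_nd - n_nn)
    )
    rng.shuffle(intents)
    groups = {pid: "target" for pid in target_ids}
    groups.update(dict(zip(nontarget_ids, intents)))
    all_ids = target_ids + nontarget_ids

    # -- lengths and sequences -------------------------------------------
    rng = substream(seed, "sequences")
    lengths = np.clip(
        np.round(rng.lognormal(config.length_mu, config.length_sigma, len(all_ids))),
        config.length_min,
        config.length_max,
    ).astype(int)
    length_of = dict(zip(all_ids, lengths))
    aa = np.array(list(cio.AMINO_ACIDS))
    sequences = {
        pid: "".join(aa[rng.integers(0, 20, length_of[pid])]) for pid in all_ids
    }
    # planted near-duplicates: background non-targets copying a target, for
    # the identity-expansion stage
    near_pairs = []
    background_ids = [p for p in nontarget_ids if groups[p] == "background"]
    for i in range(min(config.near_duplicate_pairs, len(background_ids), len(target_ids))):
        donor, clone = target_ids[i], background_ids[i]
        seq = np.array(list(sequences[donor]))
        n_mut = int(round(config.near_duplicate_mutation_rate * seq.size))
        sites = rng.choice(seq.size, size=n_mut, replace=False)
        seq[sites] = aa[rng.integers(0, 20, n_mut)]
        sequences[clone] = "".join(seq)
        length_of[clone] = seq.size
        near_pairs.append((clone, donor))

    # -- per-protein marker targets and tracks ---------------------------
    rng = substream(seed, "tracks")
    proteome = {}
    for pid in all_ids:
        g = groups[pid]
        length = length_of[pid]
        # longer chains tend to carry more disorder
        length_term = 0.05 * np.log(length / 375.0)
        contents = {}
        for marker in TRACK_MARKERS:
            base = means[g][marker] + (length_term if marker == "disorder" else 0.0)
            contents[marker] = float(
                np.clip(base + rng.normal(0.0, config.protein_jitter_sd), 0.02, 0.95)
            )
        rec = cio.ProteinRecord(
            protein_id=pid,
            sequence=sequences[pid],
            isoform_count=1 + int(rng.poisson(max(means[g]["isoform"], 0.0))),
        )
        rec.tracks["disorder"] = _segmented_track(rng, length, contents["disorder"])
        rec.tracks["binding"] = _segmented_track(rng, length, contents["binding"])
        rec.tracks["rsa"] = _rsa_track(rng, length, contents["surface"])
        n_domains = int(rng.poisson(max(means[g]["domain"], 0.0)))
        pos = 0
        for _ in range(n_domains):
            size = int(rng.integers(40, 121))
            gap = int(rng.integers(5, 40))
            start = pos + gap
            if start + size > length:
                break
            rec.domains.append((start, start + size))
            pos = start + size
        rec._cons_content = contents["conservation"]  # consumed by the PSSM stage
        proteome[pid] = rec

    rng = substream(seed, "pssms")
    pssms = {
        pid: cio.Pssm(pid, _pssm_probs(rng, rec.sequence, rec._cons_content),
                      cio.uniform_background())
        for pid, rec in proteome.items()
    }
    for rec in proteome.values():
        del rec._cons_content

    # -- drug-protein interactions ---------------------------------------
    rng = substream(seed, "interactions")
    statuses = rng.choice(
        ["approved", "experimental", "other"], size=config.n_compounds, p=config.status_probs
    )
    structures = [f"S{i:05d}" for i in range(config.n_compounds)]
    for i in range(config.duplicate_structure_pairs):
        structures[2 * i + 1] = structures[2 * i]  # distinct CIDs, same structure
    pop = np.arange(1, config.n_compounds + 1) ** -config.compound_popularity_exponent
    pop /= pop.sum()
    counts = _truncated_power_law(
        rng, config.interaction_exponent, config.interaction_max, config.n_targets
    )
    rows = []
    for pid, count in zip(target_ids, counts):
        chosen = rng.choice(config.n_compounds, size=min(count, config.n_compounds),
                            replace=False, p=pop)
        for c in sorted(chosen):
            rows.append((f"C{c:05d}", structures[c], pid, statuses[c]))
    interactions = pd.DataFrame(
        rows, columns=["compound_id", "structure", "protein_id", "drug_status"]
    )

    # -- disease associations ---------------------------------------------
    rng = substream(seed, "diseases")
    disease_counts = {}
    for pid in all_ids:
        g = groups[pid]
        if g == "target":
            if rng.random() < config.target_assoc_prob:
                c = 1 + int(_nbinom(rng, config.target_disease_mean,
                                    config.target_disease_dispersion, 1)[0])
            else:
                c = 0
        elif g == "nd":
            c = 1 + int(_nbinom(rng, config.nd_disease_mean,
                                config.nd_disease_dispersion, 1)[0])
        elif g == "nn":
            c = 0
        else:
            c = 1 + int(_nbinom(rng, config.background_disease_mean,
                                config.background_disease_dispersion, 1)[0])
        disease_counts[pid] = min(c, config.n_diseases)
    disease_pop = np.arange(1, config.n_diseases + 1) ** -1.1
    disease_pop /= disease_pop.sum()
    classes = [f"class_{i % config.n_disease_classes:02d}" for i in range(config.n_diseases)]
    drows = []
    for pid in all_ids:
        c = disease_counts[pid]
        if c == 0:
            continue
        chosen = rng.choice(config.n_diseases, size=c, replace=False, p=disease_pop)
        for d in sorted(chosen):
            drows.append((pid, f"M{d:05d}", classes[d]))
    diseases = pd.DataFrame(drows, columns=["protein_id", "disease_id", "disease_class"])

    # -- PPI network -------------------------------------------------------
    rng = substream(seed, "network")
    bias_of = {"target": config.target_bias, "nd": config.nd_bias,
               "nn": config.nn_bias, "background": 1.0}
    m_of = {"target": config.target_m, "nd": config.nd_m,
            "nn": config.nn_m, "background": config.network_m}
    bias = np.array([bias_of[groups[p]] for p in all_ids])
    m_per_node = np.array([m_of[groups[p]] for p in all_ids])
    ppi = _biased_preferential_attachment(rng, all_ids, bias, m_per_node)

    # -- ontology and annotations -----------------------------------------
    rng = substream(seed, "ontology")
    dag, planted_terms = _generate_dag(rng, config)
    annotations = _generate_annotations(rng, config, dag, planted_terms, groups, all_ids)

    corpus = cio.Corpus(
        proteome=proteome,
        pssms=pssms,
        interactions=interactions,
        diseases=diseases,
        ppi=ppi,
        dag=dag,
        annotations=annotations,
    )
    manifest = build_manifest(config, groups, near_pairs, planted_terms)
    if out_dir is not None:
        write_corpus(corpus, manifest, out_dir)
    return corpus, manifest


def _generate_dag(rng, config: SyntheticConfig):
    graph = nx.DiGraph()
    ns_names = {"MF": "MF", "BP": "BP", "CC": "CC"}
    for ns in ns_names:
        terms = [f"{ns}:{i:04d}" for i in range(config.terms_per_namespace)]
        for i, term in enumerate(terms):
            graph.add_node(term, namespace=ns)
            if i == 0:
                continue
            n_parents = 1 if (i < 3 or rng.random() < 0.6) else 2
            parents = rng.choice(i, size=min(n_parents, i), replace=False)
            for p in sorted(parents):
                rel = "is_a" if rng.random() < 0.8 else "part_of"
                graph.add_edge(term, terms[p], relation=rel,
                               weight=cio.DEFAULT_EDGE_WEIGHTS[rel])
    last = config.terms_per_namespace
    # planted term sets: late indices are leaves by construction
    planted = {
        "MF": {"target": [f"MF:{last-2:04d}", f"MF:{last-1:04d}"],
               "nd": [f"MF:{last-2:04d}", f"MF:{last-1:04d}"]},
        "BP": {"target": [f"BP:{last-4:04d}", f"BP:{last-3:04d}"],
               "nd": [f"BP:{last-2:04d}", f"BP:{last-1:04d}"]},
        "CC": {"target": [f"CC:{last-3:04d}", f"CC:{last-2:04d}"],
               "nd": [f"CC:{last-2:04d}", f"CC:{last-1:04d}"]},
    }
    return cio.GoDag(graph), planted


def _generate_annotations(rng, config, dag, planted, groups, all_ids) -> pd.DataFrame:
    planted_terms = {
        t for ns in planted for owner in planted[ns] for t in planted[ns][owner]
    }
    terms_by_ns = {
        ns: sorted(t for t in dag.terms
                   if dag.namespace(t) == ns and t not in planted_terms)
        for ns in ("MF", "BP", "CC")
    }
    rows = []
    for pid in all_ids:
        g = groups[pid]
        chosen = set()
        for ns, terms in terms_by_ns.items():
            k = rng.poisson(config.annotation_mean)
            if k:
                # base annotations never touch the planted terms, so planted
                # background rates stay at the configured level
                chosen.update(rng.choice(terms[1:], size=min(k, len(terms) - 1),
                                         replace=False))
            for owner in ("target", "nd"):
                rate = (config.planted_annotation_rate if g == owner
                        else config.background_annotation_rate)
                for term in planted[ns][owner]:
                    if rng.random() < rate:
                        chosen.add(term)
        for term in sorted(chosen):
            rows.append((pid, term))
    return pd.DataFrame(rows, columns=["protein_id", "term_id"])


# ---------------------------------------------------------------------------
# ground truth


def expected_disease_curve(config: SyntheticConfig, max_k: int = 80) -> DiseaseCurve:
    """The analytic (infinite-sample) disease curve implied by the config."""
    ks = np.arange(1, max_k + 1)
    n_t = config.n_targets
    n_non = config.n_nontargets
    n_nd = round(config.nd_fraction * n_non)
    n_bg = n_non - n_nd - round(config.nn_fraction * n_non)
    t = n_t * config.target_assoc_prob * _nbinom_sf(
        ks - 1, config.target_disease_mean, config.target_disease_dispersion
    )
    nd = n_nd * _nbinom_sf(ks - 1, config.nd_disease_mean, config.nd_disease_dispersion)
    bg = n_bg * _nbinom_sf(ks - 1, config.background_disease_mean,
                           config.background_disease_dispersion)
    pool = t + nd + bg
    keep = pool > 0
    return DiseaseCurve(ks[keep], pool[keep], (t / pool)[keep])


def expected_plateau_k(config: SyntheticConfig, plateau_fraction: float = 0.98,
                       support_floor: int = 20) -> int:
    """Plateau onset of the analytic curve under the same selection rule the
    pipeline applies to sampled data."""
    return select_k(expected_disease_curve(config), plateau_fraction, support_floor)


def build_manifest(config, groups, near_pairs, planted_terms) -> dict:
    means = config.group_means()
    orderings = []
    signs: dict = {}
    if not config.null_mode:
        marker_col = {
            "disorder": "disorder_content",
            "conservation": "cons_fraction",
            "surface": "surface_fraction",
            "binding": "binding_content",
        }
        cohort_group = {"D": "target", "Nd": "nd", "Nn": "nn"}
        for marker, col in marker_col.items():
            for hi, lo in (("D", "Nd"), ("D", "Nn"), ("Nd", "Nn")):
                diff = means[cohort_group[hi]][marker] - means[cohort_group[lo]][marker]
                if abs(diff) >= 0.04:  # only claim clearly separated medians
                    pair = (hi, lo) if diff > 0 else (lo, hi)
                    orderings.append([col, pair[0], pair[1], "p<0.05", "median"])
            # N mixes nd/nn/background; claim N vs D when every non-target
            # group sits on the same side of the target mean
            diffs = [means[g][marker] - means["target"][marker]
                     for g in ("nd", "nn", "background")]
            if min(diffs) >= 0.04:
                orderings.append([col, "N", "D", "p<0.05", "median"])
            elif max(diffs) <= -0.04:
                orderings.append([col, "D", "N", "p<0.05", "median"])
            signs[col] = {}
            for cohort, g in (("Nd", "nd"), ("Nn", "nn")):
                diff = means[g][marker] - means["target"][marker]
                if abs(diff) >= 0.04:
                    signs[col][cohort] = 1 if diff > 0 else -1
            if min(diffs) >= 0.04:
                signs[col]["N"] = 1
            elif max(diffs) <= -0.04:
                signs[col]["N"] = -1
        # discrete count markers: medians tie under Poisson discreteness, so
        # the planted direction is claimed on the mean
        for col in ("isoform_count", "domain_count"):
            orderings += [[col, "D", "Nn", "p<0.05", "mean"],
                          [col, "Nd", "Nn", "p<0.05", "mean"]]
        orderings += [["domain_coverage", "D", "Nn", "p<0.05", "median"],
                      ["domain_coverage", "Nd", "Nn", "p<0.05", "mean"]]
        for col in ("betweenness", "eigenvector", "closeness", "information"):
            orderings += [
                [col, "D", "Nn", "p<0.05", "median"],
                [col, "Nd", "Nn", "p<0.05", "median"],
                [col, "Nd", "D", "p<0.05", "median"],
            ]
    try:
        plateau_k = expected_plateau_k(config)
    except ValueError:
        plateau_k = None  # corpus too small for the support floor
    return {
        "config": dataclasses.asdict(config),
        "groups": groups,
        "group_means": means,
        "expected_orderings": orderings,
        "expected_signs": signs,
        "expected_plateau_k": plateau_k,
        "near_duplicate_pairs": near_pairs,
        "planted_terms": planted_terms,
    }


# ---------------------------------------------------------------------------
# on-disk form


def write_corpus(corpus: cio.Corpus, manifest: dict, out_dir) -> None:
    """Write every corpus component as plain text, deterministically."""
    os.makedirs(out_dir, exist_ok=True)
    pssm_dir = os.path.join(out_dir, "pssm")
    os.makedirs(pssm_dir, exist_ok=True)
    ids = sorted(corpus.proteome)
    cio.write_fasta([(p, corpus.proteome[p].sequence) for p in ids],
                    os.path.join(out_dir, "proteome.fasta"))
    iso = pd.DataFrame(
        {"protein_id": ids, "isoform_count": [corpus.proteome[p].isoform_count for p in ids]}
    )
    cio.write_table(iso, os.path.join(out_dir, "isoforms.tsv"))
    drows = [
        (p, start + 1, end)
        for p in ids
        for start, end in corpus.proteome[p].domains
    ]
    cio.write_table(pd.DataFrame(drows, columns=["protein_id", "start", "end"]),
                    os.path.join(out_dir, "domains.tsv"))
    for name in cio.TRACK_NAMES:
        df = cio.tracks_to_table(corpus.proteome, name)
        df["score"] = df["score"].map(lambda v: f"{v:.4f}")
        cio.write_table(df, os.path.join(out_dir, f"track_{name}.tsv"))
    for pid in ids:
        pssm = corpus.pssms[pid]
        cio.write_pssm_ascii(pid, corpus.proteome[pid].sequence, pssm.probs * 100.0,
                             os.path.join(pssm_dir, f"{pid}.pssm"))
    cio.write_table(corpus.interactions, os.path.join(out_dir, "interactions.tsv"))
    cio.write_table(corpus.diseases, os.path.join(out_dir, "diseases.tsv"))
    cio.write_ppi(corpus.ppi, os.path.join(out_dir, "ppi.tsv"))
    _write_obo(corpus.dag, os.path.join(out_dir, "ontology.obo"))
    cio.write_table(corpus.annotations, os.path.join(out_dir, "annotations.tsv"))
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


_OBO_NS_LONG = {"MF": "molecular_function", "BP": "biological_process",
                "CC": "cellular_component"}


def _write_obo(dag: cio.GoDag, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.graph.nodes):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: synthetic term {term}\n")
            fh.write(f"namespace: {_OBO_NS_LONG[dag.namespace(term)]}\n")
            for parent, data in sorted(
                (p, dag.graph.edges[term, p]) for p in dag.graph.successors(term)
            ):
                if data["relation"] == "is_a":
                    fh.write(f"is_a: {parent} ! parent\n")
                else:
                    fh.write(f"relationship: part_of {parent} ! parent\n")


def read_corpus(in_dir) -> tuple:
    """Read a corpus previously written by :func:`write_corpus`."""
    fasta = cio.read_fasta(os.path.join(in_dir, "proteome.fasta"))
    proteome = {pid: cio.ProteinRecord(pid, seq) for pid, seq in fasta}
    cio.attach_isoforms(proteome, cio.read_table(os.path.join(in_dir, "isoforms.tsv"),
                                                 "isoforms"))
    cio.attach_domains(proteome, cio.read_table(os.path.join(in_dir, "domains.tsv"),
                                                "domains"))
    for name in cio.TRACK_NAMES:
        cio.attach_tracks(
            proteome, cio.read_table(os.path.join(in_dir, f"track_{name}.tsv"), "tracks"),
            name,
        )
    pssm_dir = os.path.join(in_dir, "pssm")
    pssms = {}
    for fname in sorted(os.listdir(pssm_dir)):
        pid = os.path.splitext(fname)[0]
        pssms[pid] = cio.read_pssm(
            os.path.join(pssm_dir, fname),
            expected_length=proteome[pid].length if pid in proteome else None,
            protein_id=pid,
        )
    interactions = cio.read_table(os.path.join(in_dir, "interactions.tsv"), "interactions")
    diseases = cio.read_table(os.path.join(in_dir, "diseases.tsv"), "diseases")
    ppi = cio.read_ppi(os.path.join(in_dir, "ppi.tsv"))
    dag, annotations = cio.read_go(os.path.join(in_dir, "ontology.obo"),
                                   os.path.join(in_dir, "annotations.tsv"))
    manifest_path = os.path.join(in_dir, "manifest.json")
    manifest = None
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    corpus = cio.Corpus(proteome, pssms, interactions, diseases, ppi, dag, annotations)
    for rec in corpus.proteome.values():
        rec.validate()
    return corpus, manifest


def corpus_digest(in_dir) -> dict:
    """SHA-256 of every file in a written corpus (determinism checks)."""
    out = {}
    for root, _, files in os.walk(in_dir):
        for fname in sorted(files):
            path = os.path.join(root, fname)
            rel = os.path.relpath(path, in_dir)
            with open(path, "rb") as fh:
                out[rel] = hashlib.sha256(fh.read()).hexdigest()
    return out


# ---------------------------------------------------------------------------
# worked fixture


def generate_worked_fixture():
    """A fixed, seedless miniature corpus whose every value is hand-checkable.

    Eleven proteins: a 4-leaf star (A1 centre), a triangle (B1-B3), one edge
    (C1-C2), and an isolated node (D1).  A3 duplicates A1's sequence to
    exercise identity expansion; A1 carries a background-uniform PSSM (zero
    relative entropy) and B1 a point-mass PSSM (relative entropy near ln 20).
    The companion expected-values file in the test suite was produced by the
    independent brute-force oracles, not by the pipeline.
    """
    seqs = {
        "A1": "ACDEFGHIKL",
        "A2": "MNPQRSTVWY",
        "A3": "ACDEFGHIKL",
        "A4": "LKIHGFEDCA",
        "A5": "AAAAACCCCC",
        "B1": "DDDDDEEEEE",
        "B2": "FFFFFGGGGG",
        "B3": "HHHHHIIIII",
        "C1": "KKKKKLLLLLMM",
        "C2": "NNNNNPPPPP",
        "D1": "QQQQQRRRRR",
    }
    lo, hi = 0.1, 0.9
    disorder = {
        "A1": [lo, lo, lo, hi, hi, hi, hi, lo, lo, lo],
        "A2": [hi] * 10,
        "A3": [lo] * 10,
        "A4": [lo, hi, hi, lo, lo, lo, hi, hi, hi, hi],
        "A5": [lo] * 10,
        "B1": [hi, hi, lo, lo, lo, lo, lo, lo, hi, hi],
        "B2": [lo] * 10,
        "B3": [hi] * 10,
        "C1": [lo] * 12,
        "C2": [hi, lo, hi, lo, hi, lo, hi, lo, hi, lo],
        "D1": [lo] * 10,
    }
    rsa = {
        "A1": [0.10, 0.15, 0.20, 0.90, 0.05, 0.30, 0.40, 0.14, 0.16, 0.80],
        "A2": [0.50] * 10,
        "A3": [0.05] * 10,
        "A4": [0.90] * 10,
        "A5": [0.10] * 10,
        "B1": [0.20] * 10,
        "B2": [0.05, 0.05, 0.05, 0.05, 0.05, 0.90, 0.90, 0.90, 0.90, 0.90],
        "B3": [0.30] * 10,
        "C1": [0.15] * 12,
        "C2": [0.10, 0.20] * 5,
        "D1": [0.05] * 10,
    }
    binding = {
        "A1": [0.49, 0.50, 0.51, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        "A2": [0.9] * 10,
        "A3": [0.0] * 10,
        "A4": [0.6] * 5 + [0.4] * 5,
        "A5": [0.0] * 10,
        "B1": [0.0] * 10,
        "B2": [0.7] * 10,
        "B3": [0.0] * 10,
        "C1": [0.0] * 12,
        "C2": [0.9, 0.1] * 5,
        "D1": [0.0] * 10,
    }
    domains = {
        "A1": [(0, 5), (4, 10)],  # overlapping pair covering the whole chain
        "A2": [(0, 10)],
        "A4": [(2, 6)],
        "C1": [(0, 4), (8, 12)],
    }
    isoforms = {"A1": 4, "A2": 3, "B1": 2, "B2": 3, "A4": 1, "C1": 2}
    proteome = {}
    for pid, seq in seqs.items():
        rec = cio.ProteinRecord(
            protein_id=pid,
            sequence=seq,
            isoform_count=isoforms.get(pid, 1),
            domains=list(domains.get(pid, [])),
        )
        rec.tracks["disorder"] = np.array(disorder[pid])
        rec.tracks["rsa"] = np.array(rsa[pid])
        rec.tracks["binding"] = np.array(binding[pid])
        rec.validate()
        proteome[pid] = rec

    eps = 1e-4
    uniform = np.full((10, 20), 0.05)
    onehot = np.zeros((10, 20))
    for i, a in enumerate(seqs["B1"]):
        onehot[i, cio.AMINO_ACIDS.index(a)] = 1.0
    onehot = (onehot + eps) / (1.0 + 20 * eps)
    pssms = {
        "A1": cio.Pssm("A1", uniform.copy(), cio.uniform_background()),
        "B1": cio.Pssm("B1", onehot, cio.uniform_background()),
    }
    for p in pssms.values():
        p.validate()

    interactions = pd.DataFrame(
        [
            ("c1", "s1", "A1", "approved"),
            ("c2", "s1", "A1", "approved"),  # same structure as c1: merged
            ("c3", "s2", "A1", "experimental"),
            ("c3", "s2", "A2", "experimental"),
            ("c5", "s5", "A1", "approved"),
            ("c5", "s5", "B1", "approved"),
            ("c6", "s6", "A1", "approved"),
            ("c6", "s6", "B1", "approved"),
            ("c6", "s6", "B2", "approved"),
            ("c7", "s7", "B2", "approved"),
            ("c8", "s8", "B2", "experimental"),
            ("c9", "s9", "B3", "other"),  # filtered out: B3 is not a target
        ],
        columns=["compound_id", "structure", "protein_id", "drug_status"],
    )
    disease_counts = {
        "A1": 5, "A2": 3, "B1": 14, "B2": 1,
        "A4": 20, "A5": 2, "C1": 15, "D1": 1,
    }
    drows = []
    disease_no = 0
    for pid in sorted(disease_counts):
        for _ in range(disease_counts[pid]):
            drows.append((pid, f"M{disease_no:03d}",
                          "class_a" if disease_no % 2 == 0 else "class_b"))
            disease_no += 1
    diseases = pd.DataFrame(drows, columns=["protein_id", "disease_id", "disease_class"])

    ppi = nx.Graph()
    ppi.add_nodes_from(seqs)
    ppi.add_edges_from(
        [("A1", "A2"), ("A1", "A3"), ("A1", "A4"), ("A1", "A5"),
         ("B1", "B2"), ("B2", "B3"), ("B1", "B3"), ("C1", "C2")]
    )

    dag_graph = nx.DiGraph()
    for term, ns in [("MF:R", "MF"), ("MF:A", "MF"), ("MF:B", "MF"),
                     ("BP:R", "BP"), ("BP:X", "BP"), ("BP:Y", "BP"),
                     ("CC:R", "CC"), ("CC:M", "CC")]:
        dag_graph.add_node(term, namespace=ns)
    for child, parent, rel in [("MF:A", "MF:R", "is_a"), ("MF:B", "MF:R", "is_a"),
                               ("BP:X", "BP:R", "is_a"), ("BP:Y", "BP:R", "part_of"),
                               ("CC:M", "CC:R", "is_a")]:
        dag_graph.add_edge(child, parent, relation=rel,
                           weight=cio.DEFAULT_EDGE_WEIGHTS[rel])
    dag = cio.GoDag(dag_graph)
    dag.validate()
    annotations = pd.DataFrame(
        [("A1", "MF:A"), ("A2", "MF:A"), ("B1", "MF:A"), ("B2", "MF:A"),
         ("A4", "MF:B"), ("C1", "MF:B"),
         ("A1", "BP:X"), ("A4", "BP:X"), ("C2", "BP:Y"),
         ("B1", "CC:M"), ("C1", "CC:M")],
        columns=["protein_id", "term_id"],
    )
    return cio.Corpus(proteome, pssms, interactions, diseases, ppi, dag, annotations)


# ---------------------------------------------------------------------------
# recovery evaluation against the manifest ground truth


def evaluate_recovery(markers, partition, comparisons, reldiff, manifest) -> dict:
    """Score a pipeline run against the generator's planted ground truth.

    Checks every expected ordering (direction of the planted statistic plus
    significance at the claimed tier) and every expected sign of the
    relative-difference summary.  Returns the failure lists plus pass flags.
    """
    by_pair = {(r.marker, r.pair): r for r in comparisons}
    members = {name: [p for p in sorted(ids) if p in markers.index]
               for name, ids in partition.cohorts.items()}
    tier_alpha = {"p<0.05": 0.05, "p<0.0001": 1e-4}
    ordering_failures = []
    for marker, hi, lo, tier, statistic in manifest["expected_orderings"]:
        r = by_pair.get((marker, (hi, lo))) or by_pair.get((marker, (lo, hi)))
        if r is None:
            ordering_failures.append((marker, hi, lo, "comparison missing"))
            continue
        agg = np.nanmean if statistic == "mean" else np.nanmedian
        v_hi = agg(markers.loc[members[hi], marker].to_numpy(dtype=float))
        v_lo = agg(markers.loc[members[lo], marker].to_numpy(dtype=float))
        if not (v_hi > v_lo and r.p_value < tier_alpha[tier]):
            ordering_failures.append(
                (marker, hi, lo, f"{statistic} {v_hi:.4g} vs {v_lo:.4g}, p={r.p_value:.3g}")
            )
    sign_failures = []
    for marker, per_cohort in manifest["expected_signs"].items():
        for cohort, sign in per_cohort.items():
            value = reldiff.loc[cohort, marker] if marker in reldiff.columns else np.nan
            if not (np.isfinite(value) and np.sign(value) == sign):
                sign_failures.append((marker, cohort, float(value)))
    return {
        "ordering_failures": ordering_failures,
        "sign_failures": sign_failures,
        "orderings_ok": not ordering_failures,
        "signs_ok": not sign_failures,
    }
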