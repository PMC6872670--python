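"""Construction of the seven protein cohorts.

The analysis contrasts drug targets (D), an identity-expanded target set
(D+), the most and least promiscuous target quartiles (Dh, Dl), a
size-matched non-target control set (N), and the disease-defined split of N
into possibly druggable (Nd, many disease associations) and non-druggable
(Nn, no disease associations) proteins.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from ._util import log, nearest_rank_percentile, substream

COHORT_NAMES = ("D", "Dplus", "Dh", "Dl", "N", "Nd", "Nn")


@dataclasses.dataclass
class CohortPartition:
    """Assignment of protein IDs to the seven cohorts plus the parameters used."""

    cohorts: dict  # name -> set of protein ids
    params: dict = dataclasses.field(default_factory=dict)

    def __getitem__(self, name: str) -> set:
        return self.cohorts[name]

    def validate(self) -> None:
        c = self.cohorts
        assert c["Dh"] <= c["D"] and c["Dl"] <= c["D"]
        # heavily tied count distributions may overlap the quartiles; that is
        # flagged as degenerate rather than fatal
        assert not (c["Dh"] & c["Dl"]) or self.params.get("quartiles_degenerate")
        assert c["D"] <= c["Dplus"]
        assert not (c["N"] & c["D"])
        assert c["Nd"] <= c["N"] and c["Nn"] <= c["N"]
        assert not (c["Nd"] & c["Nn"])

    def to_frame(self) -> pd.DataFrame:
        proteins = sorted(set().union(*self.cohorts.values()))
        data = {"protein_id": proteins}
        for name in COHORT_NAMES:
            members = self.cohorts[name]
            data[name] = [int(p in members) for p in proteins]
        return pd.DataFrame(data)


@dataclasses.dataclass
class DiseaseCurve:
    """For each minimal disease count K: pool size and drug-target fraction.

    ``f(K)`` is the fraction of drug targets among proteins associated with
    at least K diseases; the pool size ``n_proteins(K)`` is non-increasing.
    """

    k: np.ndarray
    n_proteins: np.ndarray
    f: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.k, "n_proteins": self.n_proteins, "f": self.f})


# ---------------------------------------------------------------------------


def merge_interactions(raw: pd.DataFrame) -> pd.DataFrame:
    """Merge compounds with identical structures and keep only drugs.

    Compounds sharing a canonical structure string collapse onto the
    lowest-sorting compound id; rows whose drug_status is neither approved
    nor experimental are removed; duplicate (compound, protein) pairs are
    collapsed.
    """
    df = raw[raw["drug_status"].isin(["approved", "experimental"])].copy()
    if df.empty:
        log.warning("merge_interactions: no approved/experimental interactions remain")
        return df.assign(compound_id=df.get("compound_id"))
    canonical = df.groupby("structure")["compound_id"].min()
    df["compound_id"] = df["structure"].map(canonical)
    df = df.drop_duplicates(subset=["compound_id", "protein_id"]).reset_index(drop=True)
    return df


def build_target_sets(interactions: pd.DataFrame, proteome) -> tuple:
    """Targets = proteome members with >= 1 merged interaction; count distinct drugs."""
    known = interactions["protein_id"].isin(set(proteome))
    if (~known).any():
        log.warning(
            "build_target_sets: dropped %d interactions to proteins outside the proteome",
            (~known).sum(),
        )
    kept = interactions[known]
    counts = kept.groupby("protein_id")["compound_id"].nunique().to_dict()
    return set(counts), counts


_DEFAULT_ALIGNER = None


def _aligner():
    global _DEFAULT_ALIGNER
    if _DEFAULT_ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        _DEFAULT_ALIGNER = aligner
    return _DEFAULT_ALIGNER


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Local-alignment sequence identity: identical columns / alignment length.

    Affine-gap Smith-Waterman with BLOSUM62 scores (gap open 11, extend 1);
    a desk-scale stand-in for BLAST-style identity.
    """
    if not seq_a or not seq_b:
        return 0.0
    try:
        alignment = _aligner().align(seq_a, seq_b)[0]
    except (IndexError, ValueError):
        return 0.0
    counts = alignment.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    if aln_len == 0:
        return 0.0
    return counts.identities / aln_len


def _kmer_set(seq: str, k: int = 5) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def expand_by_identity(
    targets: set,
    proteome,
    cutoff: float = 0.90,
    identity_table: pd.DataFrame | None = None,
    min_kmer_overlap: float = 0.2,
) -> set:
    """D+ = D plus non-targets sharing >= cutoff sequence identity with a target.

    A precomputed pairwise-identity table (protein_a, protein_b, identity)
    may be supplied for fidelity with an external aligner; otherwise the
    built-in local aligner is used.  Like BLAST's word seeding, candidate
    pairs must share a minimum 5-mer overlap (and compatible lengths) before
    the quadratic alignment is attempted; this also keeps short high-identity
    local matches between unrelated sequences from counting as homology.
    """
    if not 0 < cutoff <= 1:
        raise ValueError(f"identity cutoff must be in (0, 1], got {cutoff}")
    dplus = set(targets)
    non_targets = [p for p in proteome if p not in targets]
    if identity_table is not None:
        pairs = {}
        for _, row in identity_table.iterrows():
            a, b = row["protein_a"], row["protein_b"]
            ident = float(row["identity"])
            pairs[(a, b)] = max(pairs.get((a, b), 0.0), ident)
            pairs[(b, a)] = max(pairs.get((b, a), 0.0), ident)
        for p in non_targets:
            if any(pairs.get((p, t), 0.0) >= cutoff for t in targets):
                dplus.add(p)
        return dplus
    kmers = {p: _kmer_set(proteome[p].sequence) for p in proteome}
    target_list = sorted(targets)
    for p in non_targets:
        seq_p = proteome[p].sequence
        for t in target_list:
            len_ratio = min(len(seq_p), proteome[t].length) / max(len(seq_p),
                                                                  proteome[t].length)
            if len_ratio < cutoff - 0.05:
                continue
            shared = len(kmers[p] & kmers[t])
            denom = min(len(kmers[p]), len(kmers[t])) or 1
            if shared / denom < min_kmer_overlap:
                continue
            if pairwise_identity(seq_p, proteome[t].sequence) >= cutoff:
                dplus.add(p)
                break
    return dplus


def split_promiscuity(targets: set, counts: dict) -> tuple:
    """Split D into the top (Dh) and bottom (Dl) quartiles of drug counts.

    Nearest-rank 75th/25th percentiles with inclusive ties on both sides;
    fully degenerate count distributions yield Dh = Dl = D with a warning.
    """
    if len(targets) < 4:
        raise ValueError("quartile split undefined for fewer than 4 targets")
    values = [counts[p] for p in targets]
    if any(v < 1 for v in values):
        raise ValueError("every target must have at least one interaction")
    p75 = nearest_rank_percentile(values, 0.75)
    p25 = nearest_rank_percentile(values, 0.25)
    dh = {p for p in targets if counts[p] >= p75}
    dl = {p for p in targets if counts[p] <= p25}
    degenerate = bool(dh & dl)
    if degenerate:
        log.warning("split_promiscuity: degenerate quartiles (heavy ties), Dh and Dl overlap")
    return dh, dl, {"P75": p75, "P25": p25, "degenerate": degenerate}


def sample_size_matched(
    targets: set,
    non_targets: set,
    proteome,
    tolerance: float = 0.10,
    seed: int = 0,
    max_tolerance: float = 0.30,
    step: float = 0.05,
) -> tuple:
    """Draw one length-matched non-target per target, without replacement.

    Targets are processed in seeded random order; for each, a candidate with
    |len_c - len_t| <= tolerance * len_t is drawn uniformly from the unused
    pool.  When none exists the tolerance is widened in +step increments up
    to max_tolerance; a target that still cannot be matched is skipped and
    reported, preserving the matching guarantee over forcing bad matches.
    """
    if not non_targets:
        raise ValueError("empty non-target candidate pool")
    if targets & non_targets:
        raise ValueError("non-target pool must be disjoint from targets")
    rng = substream(seed, "size_matching")
    order = sorted(targets)
    rng.shuffle(order)
    cand = sorted(non_targets)
    cand_len = np.array([proteome[c].length for c in cand], dtype=float)
    used = np.zeros(len(cand), dtype=bool)
    matched, skipped, widened = {}, [], []
    for t in order:
        lt = proteome[t].length
        tol = tolerance
        choice = None
        while tol <= max_tolerance + 1e-9:
            ok = (~used) & (np.abs(cand_len - lt) <= tol * lt)
            idx = np.flatnonzero(ok)
            if idx.size:
                choice = int(rng.choice(idx))
                break
            tol = round(tol + step, 10)
        if choice is None:
            skipped.append(t)
            continue
        if tol > tolerance + 1e-9:
            widened.append((t, tol))
            log.info("size matching: tolerance widened to %.2f for %s", tol, t)
        used[choice] = True
        matched[t] = (cand[choice], tol)
    if skipped:
        log.warning("size matching: %d targets skipped (no candidate within %.2f)",
                    len(skipped), max_tolerance)
    selected = {c for c, _ in matched.values()}
    return selected, {"pairs": matched, "skipped": skipped, "widened": widened}


def disease_curve(targets: set, proteome, diseases: pd.DataFrame) -> DiseaseCurve:
    """Drug-target fraction among proteins with >= K disease associations."""
    if diseases is None or diseases.empty:
        raise ValueError("no disease association data")
    counts = diseases[diseases["protein_id"].isin(set(proteome))]
    counts = counts.groupby("protein_id")["disease_id"].nunique()
    if counts.empty:
        raise ValueError("no disease associations map to the proteome")
    max_k = int(counts.max())
    ks, ns, fs = [], [], []
    is_target = counts.index.isin(targets)
    vals = counts.to_numpy()
    for k in range(1, max_k + 1):
        pool = vals >= k
        n = int(pool.sum())
        if n == 0:
            break
        ks.append(k)
        ns.append(n)
        fs.append(float((pool & is_target).sum()) / n)
    return DiseaseCurve(np.array(ks), np.array(ns), np.array(fs))


def select_k(
    curve: DiseaseCurve,
    plateau_fraction: float = 0.98,
    support_floor: int = 20,
    override: int | None = None,
) -> int:
    """Choose the minimal-disease-count threshold K* from the f(K) curve.

    K* is the smallest K whose target fraction reaches ``plateau_fraction``
    of the curve's maximum, among K with at least ``support_floor`` proteins
    in the pool — a reproducible surrogate for reading an inflection point
    off the curve.  An explicit ``override`` (e.g. a published threshold)
    short-circuits the rule.
    """
    if override is not None:
        return int(override)
    if curve.k.size == 0:
        raise ValueError("empty disease curve")
    supported = curve.n_proteins >= support_floor
    if not supported.any():
        raise ValueError(f"no K with pool size >= {support_floor}")
    fmax = curve.f[supported].max()
    ok = supported & (curve.f >= plateau_fraction * fmax)
    return int(curve.k[ok][0])


def partition_nontargets(n_set: set, diseases: pd.DataFrame, k: int) -> tuple:
    """Split N into Nd (>= k disease associations) and Nn (none at all)."""
    if k < 1:
        raise ValueError("K must be >= 1")
    counts = diseases.groupby("protein_id")["disease_id"].nunique() if diseases is not None else {}
    counts = dict(counts)
    nd = {p for p in n_set if counts.get(p, 0) >= k}
    nn = {p for p in n_set if counts.get(p, 0) == 0}
    return nd, nn


def build_cohorts(
    corpus,
    seed: int = 0,
    k_override: int | None = None,
    identity_cutoff: float = 0.90,
    length_tolerance: float = 0.10,
    plateau_fraction: float = 0.98,
    support_floor: int = 20,
    identity_table: pd.DataFrame | None = None,
    skip_identity: bool = False,
) -> CohortPartition:
    """Run the full cohort-construction protocol on a corpus.

    ``skip_identity`` leaves D+ = D (the identity scan is quadratic in the
    proteome and is only informative when near-duplicate sequences exist).
    """
    merged = merge_interactions(corpus.interactions)
    targets, counts = build_target_sets(merged, corpus.proteome)
    if not targets:
        raise ValueError("no drug targets found in the proteome")
    if skip_identity and identity_table is None:
        dplus = set(targets)
    else:
        dplus = expand_by_identity(
            targets, corpus.proteome, identity_cutoff, identity_table=identity_table
        )
    dh, dl, qinfo = split_promiscuity(targets, counts)
    non_targets = set(corpus.proteome) - dplus
    n_set, match_info = sample_size_matched(
        targets, non_targets, corpus.proteome, tolerance=length_tolerance, seed=seed
    )
    curve = disease_curve(targets, corpus.proteome, corpus.diseases)
    k_star = select_k(
        curve, plateau_fraction=plateau_fraction, support_floor=support_floor, override=k_override
    )
    nd, nn = partition_nontargets(n_set, corpus.diseases, k_star)
    part = CohortPartition(
        cohorts={"D": targets, "Dplus": dplus, "Dh": dh, "Dl": dl, "N": n_set, "Nd": nd, "Nn": nn},
        params={
            "seed": seed,
            "K": k_star,
            "identity_cutoff": identity_cutoff,
            "length_tolerance": length_tolerance,
            "plateau_fraction": plateau_fraction,
            "support_floor": support_floor,
            "quartiles": {"P75": qinfo["P75"], "P25": qinfo["P25"]},
            "quartiles_degenerate": qinfo["degenerate"],
            "n_skipped_in_matching": len(match_info["skipped"]),
            "interaction_counts": counts,
        },
    )
    part.validate()
    return part
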