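"""Per-protein sequence-derived markers.

Covers residue-level conservation (relative entropy against a background
distribution, binarised at a pooled percentile threshold), putative surface
content from relative solvent accessibility, intrinsic-disorder content and
region lengths, domain counts and coverage, isoform counts, and the content
of disordered protein-binding residues.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import log, nearest_rank_percentile

#: Sequence-derived numeric marker columns, in reporting order.
SEQUENCE_MARKERS = [
    "cons_fraction",
    "surface_fraction",
    "cons_surface_fraction",
    "disorder_content",
    "longest_disordered_region",
    "mean_disordered_region",
    "domain_count",
    "domain_coverage",
    "isoform_count",
    "binding_content",
]

#: Binarisation cutoffs: exposure/disorder/binding use >= cutoff; the pooled
#: conservation threshold uses a strict > comparison (top-20% reading of the
#: 80th percentile).
RSA_CUTOFF = 0.15
DISORDER_CUTOFF = 0.5
BINDING_CUTOFF = 0.5
CONSERVATION_PERCENTILE = 0.80


def conservation_scores(pssm) -> np.ndarray:
    """Per-residue relative entropy sum_a p_i(a) ln(p_i(a)/q(a)), natural log.

    Non-negative by Gibbs' inequality; zero exactly when the position matches
    the background.
    """
    probs, bg = pssm.probs, pssm.background
    if np.any(probs <= 0) or np.any(bg <= 0):
        raise ValueError(f"{pssm.protein_id}: zero probability in PSSM (invariant breach)")
    return np.einsum("ij,ij->i", probs, np.log(probs / bg))


def binarize_by_percentile(
    pooled_scores: np.ndarray, per_protein_scores: np.ndarray, q: float = CONSERVATION_PERCENTILE
) -> tuple:
    """Mark residues conserved when their score strictly exceeds the pooled
    nearest-rank q-percentile; returns (flags, threshold)."""
    pooled = np.asarray(pooled_scores)
    if pooled.size == 0:
        raise ValueError("empty pooled conservation score distribution")
    threshold = nearest_rank_percentile(pooled, q)
    return np.asarray(per_protein_scores) > threshold, threshold


def surface_fraction(rsa_track: np.ndarray, cutoff: float = RSA_CUTOFF) -> float:
    """Fraction of residues with relative solvent accessibility >= cutoff."""
    track = np.asarray(rsa_track)
    return float(np.mean(track >= cutoff))


def conserved_surface_fraction(conserved: np.ndarray, exposed: np.ndarray) -> float | None:
    """Conserved residues among exposed ones; None (absent) when nothing is exposed."""
    conserved = np.asarray(conserved, dtype=bool)
    exposed = np.asarray(exposed, dtype=bool)
    if conserved.shape != exposed.shape:
        raise ValueError("conserved/exposed vectors differ in length")
    n_exposed = int(exposed.sum())
    if n_exposed == 0:
        return None
    return float((conserved & exposed).sum()) / n_exposed


def disorder_stats(disorder_track: np.ndarray, cutoff: float = DISORDER_CUTOFF) -> tuple:
    """(content, longest region, mean region length) of disordered runs.

    A residue is disordered when its score is at or above the cutoff;
    regions are maximal runs of disordered residues.
    """
    flags = np.asarray(disorder_track) >= cutoff
    content = float(flags.mean())
    if not flags.any():
        return content, 0, 0.0
    padded = np.concatenate([[0], flags.view(np.int8), [0]])
    diff = np.diff(padded)
    run_lengths = np.flatnonzero(diff == -1) - np.flatnonzero(diff == 1)
    return content, int(run_lengths.max()), float(run_lengths.mean())


def domain_stats(domains, length: int) -> tuple:
    """(count, coverage) of domain intervals; overlaps are counted separately
    but the coverage is over the interval union."""
    count = len(domains)
    if count == 0:
        return 0, 0.0
    covered = np.zeros(length, dtype=bool)
    for start, end in domains:
        if not (0 <= start < end <= length):
            raise ValueError(f"domain ({start}, {end}) outside sequence of length {length}")
        covered[start:end] = True
    return count, float(covered.mean())


def binding_content(binding_track: np.ndarray, cutoff: float = BINDING_CUTOFF) -> float:
    """Fraction of residues predicted to be disordered protein-binding."""
    return float(np.mean(np.asarray(binding_track) >= cutoff))


def pooled_conservation_threshold(proteome, pssms, pool_ids, q: float = CONSERVATION_PERCENTILE):
    """Conservation threshold from the pooled residue distribution of pool_ids.

    The pool is the combined D and N cohorts; the realised value is
    data-dependent and recomputed on every run, never hard-coded.
    """
    pooled = [
        conservation_scores(pssms[p]) for p in sorted(pool_ids) if p in pssms
    ]
    if not pooled:
        raise ValueError("no PSSMs available for the conservation pool")
    return nearest_rank_percentile(np.concatenate(pooled), q)


def assemble_markers(
    proteome,
    pssms,
    partition,
    conservation_q: float = CONSERVATION_PERCENTILE,
    rsa_cutoff: float = RSA_CUTOFF,
    disorder_cutoff: float = DISORDER_CUTOFF,
    binding_cutoff: float = BINDING_CUTOFF,
) -> tuple:
    """Build the per-protein marker table over every cohort member.

    The conservation threshold is computed once on the pooled D union N
    residues and applied to all cohorts.  Missing tracks or PSSMs yield
    absent (NaN) markers, never zeros.  Returns (DataFrame indexed by
    protein_id, params dict recording the realised thresholds).
    """
    members = sorted(set().union(*partition.cohorts.values()))
    pool = partition["D"] | partition["N"]
    try:
        threshold = pooled_conservation_threshold(proteome, pssms, pool, conservation_q)
    except ValueError:
        threshold = None
        log.warning("assemble_markers: no PSSMs for the D+N pool; conservation absent")
    rows = []
    for pid in members:
        rec = proteome[pid]
        row = {"protein_id": pid, "length": rec.length, "isoform_count": rec.isoform_count}
        row["domain_count"], row["domain_coverage"] = domain_stats(rec.domains, rec.length)
        exposed = None
        if "rsa" in rec.tracks:
            exposed = np.asarray(rec.tracks["rsa"]) >= rsa_cutoff
            row["surface_fraction"] = float(exposed.mean())
        else:
            row["surface_fraction"] = np.nan
        if pid in pssms and threshold is not None:
            scores = conservation_scores(pssms[pid])
            conserved = scores > threshold
            row["cons_fraction"] = float(conserved.mean())
            if exposed is not None:
                csf = conserved_surface_fraction(conserved, exposed)
                row["cons_surface_fraction"] = np.nan if csf is None else csf
            else:
                row["cons_surface_fraction"] = np.nan
        else:
            row["cons_fraction"] = np.nan
            row["cons_surface_fraction"] = np.nan
            if threshold is not None:
                log.info("assemble_markers: %s has no PSSM; conservation absent", pid)
        if "disorder" in rec.tracks:
            content, longest, mean_len = disorder_stats(rec.tracks["disorder"], disorder_cutoff)
            row["disorder_content"] = content
            row["longest_disordered_region"] = longest
            row["mean_disordered_region"] = mean_len
        else:
            row["disorder_content"] = np.nan
            row["longest_disordered_region"] = np.nan
            row["mean_disordered_region"] = np.nan
        if "binding" in rec.tracks:
            row["binding_content"] = binding_content(rec.tracks["binding"], binding_cutoff)
        else:
            row["binding_content"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("protein_id")
    params = {
        "conservation_threshold": threshold,
        "conservation_percentile": conservation_q,
        "rsa_cutoff": rsa_cutoff,
        "disorder_cutoff": disorder_cutoff,
        "binding_cutoff": binding_cutoff,
    }
    return table, params
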