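# Methods

This note documents the models, conventions, and numerical choices behind
the package, and what the synthetic-data experiments do and do not
demonstrate.

## Cohort construction

Interaction tables are merged by canonical structure string: compounds with
identical structures collapse onto the lowest-sorting compound id, rows
whose status is neither *approved* nor *experimental* are dropped, and
duplicate (compound, protein) pairs are removed. Drug targets `D` are the
proteome members left with at least one interaction; promiscuity counts are
distinct canonical compounds per protein.

**Percentiles.** Every percentile in the package (promiscuity quartiles,
conservation threshold, hub cutoff) is the nearest-rank statistic: the value
at 1-based index `ceil(q·n)` of the sorted sample. It is deterministic and
always an observed value, which keeps integer cutoffs (drug counts, node
degrees) integral. Quartile membership is tie-inclusive on both sides; a
count distribution so tied that the quartiles overlap is flagged degenerate
rather than rejected.

**Identity expansion (`D+`).** Sequence identity is identical columns over
the local-alignment length (Smith–Waterman, BLOSUM62, gap open 11 / extend
1, via Biopython's PairwiseAligner). Like BLAST's word seeding, a candidate
pair must first share a minimum 5-mer overlap and have compatible lengths;
without such a seed filter, short perfect local matches between unrelated
sequences would masquerade as ≥ 90% identity. A precomputed identity table
from an external aligner is accepted as an alternative input. The scan is
quadratic, so pipeline callers can disable it when the corpus is known to
contain no homologs.

**Size matching (`N`).** Targets are processed in a seeded random order;
each draws one unused non-target with length within 10% of its own. When no
candidate exists the tolerance widens in +0.05 steps to at most 0.30, and a
target that still cannot be matched is skipped and reported — skipping
preserves the matching guarantee instead of forcing bad matches. All
randomness flows from one top-level seed through named substreams, so any
stage is reproducible in isolation.

**Choosing K.** The disease curve records, for every minimal association
count K, the pool of proteins with ≥ K associations and the drug-target
fraction `f(K)` within it. The published analysis reads an inflection point
off this curve by eye; the package operationalises it as the smallest K
with `f(K) ≥ 0.98 · max f`, restricted to K whose pool holds at least 20
proteins (both configurable). A literature threshold (e.g. K = 13) can be
passed as an override and then wins unconditionally. `Nd` is the part of
`N` at or above K; `Nn` is the part with no associations at all; proteins
strictly between belong to neither.

## Sequence markers

Conservation is the per-position relative entropy (natural log) of the
PSSM-derived amino-acid distribution against a background distribution.
PSSM probabilities come from the weighted-observed-percentage columns of
the PSI-BLAST ASCII dialect (not the log-odds), divided by 100, with a
1e-4 pseudocount and row renormalisation so all entries are strictly
positive; the background defaults to uniform 1/20 and is configurable. The
binarisation threshold is recomputed on every run as the pooled 80th
percentile over the combined `D ∪ N` residues and never hard-coded, because
it is a property of the data. Conservation uses a strict `>` comparison
(the top-20% reading of an 80th percentile); the exposure (RSA ≥ 0.15),
disorder (≥ 0.5), and binding (≥ 0.5) binarisations are inclusive. Both
the longest and the mean disordered-region length are reported because
either could be the intended region-length summary. Domain coverage is the
length of the interval union over the chain length; intervals are 1-based
inclusive in files and 0-based half-open internally, converted once at I/O.
Missing tracks or PSSMs produce absent (NaN) markers, never zeros.

## Network markers

The PPI graph is undirected and simple. Definitions: degree; betweenness by
Brandes accumulation normalised by `(n−1)(n−2)/2`; closeness restricted to
a node's component, `(n_c−1)/Σ d(i,j)`, zero for isolated nodes;
eigenvector centrality per component from a dense symmetric
eigendecomposition, normalised to unit maximum within each component
(unit-L2 is available; single nodes score 0); information centrality
`n_c / Σ_j (C_ii + C_jj − 2C_ij)` with `C = (L + J)^{-1}` per component;
subgraph centrality from the full eigendecomposition (`Σ_j v_ij² e^{λ_j}`),
with a truncated power series (k ≤ 20) above a node-count threshold; the
edge-clustering-coefficient sum `Σ_{j∈N(i)} z_ij / min(d_i−1, d_j−1)` with
zero terms when the denominator vanishes; and local average connectivity,
the mean within-neighbourhood degree of a node's neighbours. Betweenness
and the all-pairs distance matrix are computed through igraph's C routines
for speed; every measure is validated against independent brute-force
oracles (path enumeration, dense inverses, matrix exponential, power
iteration) in the test suite.

Redundancy pruning uses Spearman rank correlation — centralities are
heavy-tailed, so a rank coefficient is the stable choice. The retained
subset {betweenness, eigenvector, closeness, information} is verified for
pairwise |ρ| < 0.6 with every removed measure covered at |ρ| > 0.8; when a
given network violates that, a greedy re-selection (seeds first, then the
rest in registry order) keeps measures that stay below 0.6 against
everything already kept and reports the uncovered removals. On dense
preferential-attachment graphs most centralities rank-correlate strongly
with betweenness, so the greedy set can legitimately contain a non-seed
measure; the report makes that visible rather than hiding it.

Hubs are a property of the whole interactome: the cutoff is the
nearest-rank 90th-percentile degree of the complete graph, applied with
`≥`, and cohort membership is considered only afterwards. At least 10% of
nodes are hubs by construction; ties can only enlarge the set.

## Statistics

Numeric cohort comparisons are gated on normality: the case-3
Anderson–Darling statistic (mean and variance estimated) with the
small-sample adjustment `A²(1 + 0.75/n + 2.25/n²)` and the standard
piecewise exponential p-approximation. Both groups must pass at p ≥ 0.05
for the Welch t-test; otherwise the Wilcoxon rank-sum with tie-corrected
normal approximation and continuity correction is used, and groups smaller
than 8 force the rank-sum branch. Requiring acceptance in *both* groups is
the conservative reading of an ambiguous gate; every result records which
branch ran and why. All tests are two-sided. The implementation's null
rejection rate is 4.9% ± 0.2 at n = 5000 (measured over 20,000 replicates),
i.e. the gate is calibrated and slightly conservative.

Fisher's exact test uses the probability-mass two-sided rule (the sum of
hypergeometric probabilities no larger than the observed table's); odds
ratios are `ad/bc` with ∞ when `bc = 0`. Enrichment uses the one-sided
(greater) alternative because over-representation is directional. No
multiple-testing correction is applied to the pairwise marker comparisons —
mirroring the analysis this package reimplements — and that fact is
recorded in the run manifest; the enrichment q-values are Benjamini–
Hochberg within each GO namespace separately.

The relative-difference summary is `(median(X) − median(D)) / IQR(D)` with
nearest-rank quartiles; the reference row is identically zero and entries
with `IQR(D) = 0` are absent, not zero.

## GO analysis

Annotations are ancestor-closed over the DAG before counting (standard
over-representation practice; configurable off). A term is associated with
a cohort when it occurs at least 10 times in the cohort, its fold ratio
`(k_S/|S|)/(k_R/|R|)` exceeds 2, and its q-value is below 0.05. Note an
arithmetic consequence: the fold ratio is capped at `|R|/|S|`, so a cohort
holding half the reference proteome can never exceed 2 — enrichment for
such a cohort is structurally empty, and experiments that need D-level
enrichment must embed the cohorts in a larger reference. Edge weights
default to the canonical Wang contribution factors (is_a 0.8, part_of 0.6).
Term similarity is the Wang measure (S-values by downward max-propagation
over the ancestor closure); set similarity is the best-match average, and
cohort similarity is computed on the enriched (passing) term sets per
namespace — the full annotated sets are available as an alternative mode —
then averaged over MF/BP/CC with absent cells excluded.

## Synthetic corpora

The generator emulates the statistical structure of the real inputs:
log-normal sequence lengths (μ = 5.93, σ = 0.55, clamped to 60–1800),
i.i.d. sequences, truncated power-law drug-interaction counts (exponent
1.6, max 443, spanning two orders of magnitude), Zipf compound popularity
with planted duplicate structures and an `other`-status fraction,
overdispersed three-regime disease counts, preferential-attachment PPI
networks, and three-namespace random DAGs with Poisson annotations.

Group structure: every protein carries an intent — `target`, `nd`
(high-disease), `nn` (disease-free), or `background`. Marker effects are
planted as location offsets on group means (targets: disorder −0.15,
conservation −0.13, surface −0.10, binding −0.05, +1.7 isoforms, +1.2
domains; the nd group intermediate on conservation and surface, +1.4
domains, and binding +0.02 so it is the highest). The default offsets were
power-calibrated: each claimed ordering must be detectable at the p < 0.05
tier in at least 95% of corpora at the default study size, with the
smallest realised cohort (Nd, roughly 60 proteins) setting the binding
constraint. Per-residue tracks are realised from protein-level target
contents through segment-wise beta noise, so thresholded aggregates are
monotone in (approximately affine in) the planted content and region
lengths are meaningful; RSA is a per-residue bimodal mixture. PSSM rows are
Dirichlet draws, concentrated on the observed residue at planted-conserved
positions and near-background elsewhere, which makes the pooled-percentile
threshold fall between the two relative-entropy modes. Network effects are
planted through group-specific attachment bias and group-specific edge
counts per arriving node — bias alone separates the degree tail but barely
moves closeness medians on small-world graphs.

The disease mixture (targets: 94% associated, 1 + NB(14, 3); nd:
1 + NB(25, 0.8); background: 1 + NB(2.5, 5); nn: zero) was shaped so the
analytic `f(K)` rises steeply while the background regime dies out and then
declines gently, giving a well-defined plateau onset. The manifest records
that onset computed *analytically* from the configured distributions under
the same selection rule the pipeline applies to sampled data — the ground
truth is a property of the model, not of a realisation.

The manifest also records every planted ordering with the statistic it is
claimed on (median for continuous markers; mean for Poisson-discrete counts,
whose medians tie) and the expected signs of the relative-difference
summary; `evaluate_recovery` scores a run against it. `null_mode` zeroes
every offset, equalises the network parameters, and reduces planted
annotation rates to background, while keeping the disease regimes that
define the cohorts — so the comparison battery runs under a true null.

What passing recovery tests shows: the pipeline detects location shifts of
the planted sizes at n ≈ 500 + 500 with the stated significance tiers, and
its summaries point in the planted directions. What it does not show:
performance on real proteomes, where markers correlate with each other and
with length in ways the generator only partially mimics (length-dependent
disorder is modelled; e.g. disorder–binding coupling is not), where
annotations are incomplete and biased toward studied proteins, and where
identity structure is far richer than planted near-duplicates.

## Problem sizes and defaults

Default study conditions are 500 targets + 500 non-targets; recovery and
cohort-mechanics checks run 50 seeds at that size, calibration checks use
1,000 null replicates at n = 100 per branch and 100 synthetic corpora for
null enrichment, and oracle sweeps cover all connected graphs on ≤ 7 nodes
(the atlas enumeration stops at 7), seeded 8-node graphs, 100 random graphs
on ≤ 12 nodes, and every 2×2 table with entries ≤ 12. GO-pattern
experiments use corpora whose cohorts are a minority of the reference
(e.g. 250 + 1250) for the fold-ratio reason above.

## Known limitations

* The local-alignment identity is a desk-scale stand-in for BLAST; its
  k-mer prefilter can in principle miss heavily gapped homologs.
* `network centrality` (the edge-clustering-coefficient sum) follows one
  published reading of an ambiguously cited measure; it is isolated behind
  the measure registry so an alternative definition can be swapped in.
* Eigenvector centrality across disconnected components is normalised per
  component (unit max); cross-component magnitudes are therefore not
  comparable, by design.
* The enrichment fold-ratio cap for large cohorts is inherent to the
  ratio's definition, not a bug; see the GO section.
* Sequences are i.i.d. and chemically structureless; structure strings are
  opaque canonical keys, sufficient for merge logic but nothing else.
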