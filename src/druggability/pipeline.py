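"""End-to-end orchestration: corpus -> cohorts -> markers -> statistics -> report.

A run reads (or synthesises) a corpus, builds the seven cohorts, computes
the sequence and network markers, runs the cohort comparisons and the
relative-difference summary, performs GO enrichment and cohort similarity,
and writes everything as TSV/JSON together with a manifest echoing the
configuration and every realised threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from ._util import log
from . import __version__
from . import cohorts as ch
from . import netmarkers as nm
from . import ontology as onto
from . import seqmarkers as sm
from . import stats as st
from . import synthetic as synth
from . import corpus as cio


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run_out"
    synthetic: bool = False
    corpus_dir: str | None = None
    k_override: int | None = None
    identity_expansion: bool = True
    write_corpus: bool = False
    enrichment_min_count: int = onto.MIN_COUNT
    synthetic_config: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def compute_markers(corp: cio.Corpus, partition) -> tuple:
    """Sequence + network markers for every cohort member, plus realised params."""
    table, params = sm.assemble_markers(corp.proteome, corp.pssms, partition)
    centrality = nm.compute_all_centralities(corp.ppi)
    hubs, hub_cutoff = nm.annotate_hubs(corp.ppi)
    params["hub_degree_cutoff"] = hub_cutoff
    for col in nm.MEASURES:
        table[col] = centrality[col].reindex(table.index)
    table["is_hub"] = [float(p in hubs) if p in centrality.index else np.nan
                       for p in table.index]
    return table, centrality, hubs, params


def _file_hashes(directory) -> dict:
    out = {}
    if directory is None or not os.path.isdir(directory):
        return out
    for root, _, files in os.walk(directory):
        for fname in sorted(files):
            path = os.path.join(root, fname)
            with open(path, "rb") as fh:
                digest = hashlib.sha256(fh.read()).hexdigest()
            out[os.path.relpath(path, directory)] = digest
    return out


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest.

    Any stage failure aborts with the stage name attached to the exception.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(config.out_dir, "run.log"))
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        return _run_stages(config)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig) -> dict:
    stage = "corpus"
    try:
        if config.synthetic:
            syn_cfg = synth.SyntheticConfig(seed=config.seed, **config.synthetic_config)
            corpus_dir = None
            if config.write_corpus:
                corpus_dir = os.path.join(config.out_dir, "corpus")
            corp, gen_manifest = synth.generate_corpus(syn_cfg, out_dir=corpus_dir)
            if corpus_dir is not None:
                corp, gen_manifest = synth.read_corpus(corpus_dir)
            input_hashes = _file_hashes(corpus_dir)
        elif config.corpus_dir:
            corp, gen_manifest = synth.read_corpus(config.corpus_dir)
            input_hashes = _file_hashes(config.corpus_dir)
        else:
            raise ValueError("either synthetic=True or corpus_dir is required")
        cio.validate_cross_references(corp.proteome, corp.diseases, corp.annotations)

        stage = "cohorts"
        partition = ch.build_cohorts(
            corp,
            seed=config.seed,
            k_override=config.k_override,
            skip_identity=not config.identity_expansion,
        )
        curve = ch.disease_curve(partition["D"], corp.proteome, corp.diseases)

        stage = "markers"
        markers, centrality, hubs, marker_params = compute_markers(corp, partition)

        stage = "statistics"
        selection = nm.select_orthogonal(centrality)
        comparisons = st.compare_all(markers, partition, disease_classes=corp.diseases)
        reldiff = st.relative_difference(markers, partition)

        stage = "functions"
        enrichment_frames = {}
        similarity = None
        if corp.dag is not None and corp.annotations is not None:
            reference = set(corp.proteome)
            for name in ("D", "N", "Nd", "Nn"):
                if partition[name]:
                    res = onto.enrich(partition[name], reference, corp.annotations,
                                      corp.dag, min_count=config.enrichment_min_count)
                    enrichment_frames[name] = onto.enrichment_to_frame(res)
            similarity = onto.cohort_similarity(
                partition, corp.annotations, corp.dag, reference
            )

        stage = "report"
        out = config.out_dir
        ch_frame = partition.to_frame()
        cio.write_table(ch_frame, os.path.join(out, "cohorts.tsv"))
        cio.write_table(curve.to_frame(), os.path.join(out, "disease_curve.tsv"))
        markers.reset_index().to_csv(os.path.join(out, "markers.tsv"), sep="\t", index=False)
        centrality.reset_index().to_csv(os.path.join(out, "centrality.tsv"), sep="\t",
                                        index=False)
        pd.DataFrame({"protein_id": sorted(hubs)}).to_csv(
            os.path.join(out, "hubs.tsv"), sep="\t", index=False
        )
        st.results_to_frame(comparisons).to_csv(
            os.path.join(out, "comparisons.tsv"), sep="\t", index=False
        )
        reldiff.reset_index(names="cohort").to_csv(
            os.path.join(out, "relative_differences.tsv"), sep="\t", index=False
        )
        for name, frame in enrichment_frames.items():
            frame.to_csv(os.path.join(out, f"enrichment_{name}.tsv"), sep="\t", index=False)
        if similarity is not None:
            similarity.reset_index().to_csv(os.path.join(out, "similarity.tsv"), sep="\t",
                                            index=False)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "input_hashes": input_hashes,
            "cohort_sizes": {k: len(v) for k, v in partition.cohorts.items()},
            "realized": {
                "K": partition.params["K"],
                "conservation_threshold": marker_params["conservation_threshold"],
                "hub_degree_cutoff": marker_params["hub_degree_cutoff"],
                "quartiles": partition.params["quartiles"],
            },
            "centrality_selection": {
                "kept": selection["kept"],
                "verified": selection["verified"],
            },
            "multiple_testing": "none for pairwise marker comparisons; "
                                "BH FDR within enrichment namespaces",
        }
        if config.synthetic and gen_manifest is not None:
            manifest["generator"] = {
                "expected_plateau_k": gen_manifest.get("expected_plateau_k"),
                "null_mode": gen_manifest.get("config", {}).get("null_mode"),
            }
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
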