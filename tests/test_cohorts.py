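"""Cohort construction: merging, quartiles, size matching, disease curve."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from druggability import cohorts as ch
from druggability import corpus as cio
from druggability import synthetic as synth


def _interactions(rows):
    return pd.DataFrame(rows, columns=["compound_id", "structure", "protein_id",
                                       "drug_status"])


class TestMergeInteractions:
    def test_identical_structures_merge_to_one_interaction(self):
        raw = _interactions([("c1", "s1", "p1", "approved"),
                             ("c2", "s1", "p1", "approved")])
        merged = ch.merge_interactions(raw)
        assert len(merged) == 1
        assert merged["compound_id"].iloc[0] == "c1"  # lowest-sorting id wins

    def test_non_drug_rows_removed(self):
        raw = _interactions([("c1", "s1", "p1", "other")])
        assert ch.merge_interactions(raw).empty

    def test_distinct_compounds_kept(self):
        rows = [(f"c{i}", f"s{i}", p, "approved") for i in range(3) for p in ("p1", "p2")]
        assert len(ch.merge_interactions(_interactions(rows))) == 6


class TestTargetSets:
    def test_counts_of_distinct_canonical_compounds(self):
        proteome = {"p1": None, "p2": None}
        merged = ch.merge_interactions(_interactions(
            [("c1", "s1", "p1", "approved"), ("c2", "s1", "p1", "approved"),
             ("c3", "s3", "p1", "approved"), ("c9", "s9", "px", "approved")]
        ))
        targets, counts = ch.build_target_sets(merged, proteome)
        assert targets == {"p1"}
        assert counts["p1"] == 2  # c1/c2 share a structure; px is unknown


class TestIdentityExpansion:
    def test_identical_sequence_included(self):
        proteome = {
            "t": cio.ProteinRecord("t", "ACDEFGHIKLMNPQRSTVWY" * 3),
            "p": cio.ProteinRecord("p", "ACDEFGHIKLMNPQRSTVWY" * 3),
        }
        assert ch.expand_by_identity({"t"}, proteome) == {"t", "p"}

    def test_unrelated_sequence_excluded(self):
        rng = np.random.default_rng(5)
        aa = np.array(list(cio.AMINO_ACIDS))
        proteome = {
            "t": cio.ProteinRecord("t", "".join(rng.choice(aa, 90))),
            "p": cio.ProteinRecord("p", "".join(rng.choice(aa, 90))),
        }
        assert ch.expand_by_identity({"t"}, proteome) == {"t"}

    def test_ninety_five_percent_identity_included(self):
        rng = np.random.default_rng(7)
        aa = np.array(list(cio.AMINO_ACIDS))
        base = rng.choice(aa, 100)
        variant = base.copy()
        variant[rng.choice(100, size=5, replace=False)] = "W"
        proteome = {
            "t": cio.ProteinRecord("t", "".join(base)),
            "p": cio.ProteinRecord("p", "".join(variant)),
        }
        assert ch.pairwise_identity(proteome["p"].sequence,
                                    proteome["t"].sequence) >= 0.90
        assert "p" in ch.expand_by_identity({"t"}, proteome)

    def test_precomputed_identity_table(self):
        proteome = {"t": None, "p": None, "q": None}
        table = pd.DataFrame(
            [("p", "t", 0.95), ("q", "t", 0.5)],
            columns=["protein_a", "protein_b", "identity"],
        )
        out = ch.expand_by_identity({"t"}, proteome, identity_table=table)
        assert out == {"t", "p"}

    def test_cutoff_validation(self):
        with pytest.raises(ValueError):
            ch.expand_by_identity(set(), {}, cutoff=1.5)


class TestPromiscuitySplit:
    def test_nearest_rank_quartiles(self):
        targets = {f"p{i}" for i in range(1, 9)}
        counts = {f"p{i}": i for i in range(1, 9)}
        dh, dl, info = ch.split_promiscuity(targets, counts)
        assert dh == {"p6", "p7", "p8"} and dl == {"p1", "p2"}
        assert info["P75"] == 6 and info["P25"] == 2

    def test_all_tied_counts_degenerate(self, caplog):
        targets = {f"p{i}" for i in range(4)}
        counts = {p: 7 for p in targets}
        with caplog.at_level("WARNING"):
            dh, dl, info = ch.split_promiscuity(targets, counts)
        assert dh == dl == targets and info["degenerate"]

    def test_single_promiscuous_outlier(self):
        # nearest-rank P75 of [1, 1, 1, 100] is the 3rd order statistic (1),
        # so the tie-inclusive split degenerates and is flagged
        targets = {"a", "b", "c", "d"}
        counts = {"a": 1, "b": 1, "c": 1, "d": 100}
        dh, dl, info = ch.split_promiscuity(targets, counts)
        assert "d" in dh and dl == {"a", "b", "c"}
        assert info["degenerate"]

    def test_too_few_targets_error(self):
        with pytest.raises(ValueError):
            ch.split_promiscuity({"a"}, {"a": 1})


def _proteome_of_lengths(lengths):
    return {
        pid: cio.ProteinRecord(pid, "A" * n) for pid, n in lengths.items()
    }


class TestSizeMatching:
    def test_only_candidate_within_tolerance_chosen(self):
        proteome = _proteome_of_lengths({"t": 100, "a": 105, "b": 200})
        n, info = ch.sample_size_matched({"t"}, {"a", "b"}, proteome, seed=0)
        assert n == {"a"} and not info["skipped"]

    def test_escalation_then_skip(self):
        proteome = _proteome_of_lengths({"t": 100, "a": 150})
        n, info = ch.sample_size_matched({"t"}, {"a"}, proteome, seed=0)
        assert n == set() and info["skipped"] == ["t"]

    def test_widened_tolerance_recorded(self):
        proteome = _proteome_of_lengths({"t": 100, "a": 118})
        n, info = ch.sample_size_matched({"t"}, {"a"}, proteome, seed=0)
        assert n == {"a"}
        assert info["widened"] and info["widened"][0][1] == pytest.approx(0.20)

    def test_same_seed_reproduces_selection(self, small_corpus):
        corp, _ = small_corpus
        targets = {p for p in corp.proteome if p.startswith("T")}
        pool = set(corp.proteome) - targets
        n1, _ = ch.sample_size_matched(targets, pool, corp.proteome, seed=42)
        n2, _ = ch.sample_size_matched(targets, pool, corp.proteome, seed=42)
        n3, _ = ch.sample_size_matched(targets, pool, corp.proteome, seed=43)
        assert n1 == n2
        assert n1 != n3  # different stream, almost surely different draw

    def test_empty_pool_error(self):
        with pytest.raises(ValueError):
            ch.sample_size_matched({"t"}, set(), {}, seed=0)

    def test_matched_lengths_not_distinguishable(self):
        """Matched N lengths come from the same distribution as D lengths."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = synth.SyntheticConfig(seed=seed, n_targets=160, n_nontargets=320)
            corp, _ = synth.generate_corpus(cfg)
            part = ch.build_cohorts(corp, seed=seed, skip_identity=True)
            lengths_d = [corp.proteome[p].length for p in part["D"]]
            lengths_n = [corp.proteome[p].length for p in part["N"]]
            if mannwhitneyu(lengths_d, lengths_n).pvalue > 0.05:
                hits += 1
        assert hits >= n_seeds - 2


class TestDiseaseCurve:
    def test_all_targets_curve_is_one(self):
        proteome = {"p1": None, "p2": None}
        diseases = pd.DataFrame(
            [("p1", "d1", "c"), ("p2", "d1", "c"), ("p2", "d2", "c")],
            columns=["protein_id", "disease_id", "disease_class"],
        )
        curve = ch.disease_curve({"p1", "p2"}, proteome, diseases)
        assert np.all(curve.f == 1.0)

    def test_fraction_enumeration(self):
        proteome = {p: None for p in ("t1", "t2", "x")}
        rows = [("t1", f"d{i}", "c") for i in range(5)]
        rows += [("t2", f"e{i}", "c") for i in range(5)]
        rows += [("x", "d0", "c")]
        diseases = pd.DataFrame(rows, columns=["protein_id", "disease_id", "disease_class"])
        curve = ch.disease_curve({"t1", "t2"}, proteome, diseases)
        assert curve.f[0] == pytest.approx(2 / 3)
        assert curve.f[1] == pytest.approx(1.0)

    def test_pool_size_non_increasing(self, small_corpus):
        corp, _ = small_corpus
        targets = {p for p in corp.proteome if p.startswith("T")}
        curve = ch.disease_curve(targets, corp.proteome, corp.diseases)
        assert np.all(np.diff(curve.n_proteins) <= 0)

    def test_no_data_error(self):
        with pytest.raises(ValueError):
            ch.disease_curve(set(), {}, pd.DataFrame())


class TestSelectK:
    def test_plateau_rule(self):
        curve = ch.DiseaseCurve(
            k=np.arange(1, 7),
            n_proteins=np.array([100, 90, 80, 70, 60, 50]),
            f=np.array([0.60, 0.70, 0.75, 0.75, 0.75, 0.75]),
        )
        assert ch.select_k(curve) == 3  # first f >= 0.98 * 0.75 = 0.735

    def test_monotone_max_at_first_k(self):
        curve = ch.DiseaseCurve(np.array([1, 2]), np.array([50, 40]),
                                np.array([0.9, 0.9]))
        assert ch.select_k(curve) == 1

    def test_override_wins(self):
        curve = ch.DiseaseCurve(np.array([1]), np.array([50]), np.array([1.0]))
        assert ch.select_k(curve, override=13) == 13

    def test_support_floor_error(self):
        curve = ch.DiseaseCurve(np.array([1]), np.array([5]), np.array([1.0]))
        with pytest.raises(ValueError):
            ch.select_k(curve)


class TestPartitionNontargets:
    def test_rule_application(self):
        diseases = pd.DataFrame(
            [("b", f"d{i}", "c") for i in range(5)] + [("c", f"d{i}", "c") for i in range(20)],
            columns=["protein_id", "disease_id", "disease_class"],
        )
        nd, nn = ch.partition_nontargets({"a", "b", "c"}, diseases, 13)
        assert nd == {"c"} and nn == {"a"}

    def test_k_of_one(self):
        diseases = pd.DataFrame([("b", "d0", "c")],
                                columns=["protein_id", "disease_id", "disease_class"])
        nd, nn = ch.partition_nontargets({"a", "b"}, diseases, 1)
        assert nd == {"b"} and nn == {"a"}

    def test_empty_n(self):
        assert ch.partition_nontargets(set(), pd.DataFrame(
            columns=["protein_id", "disease_id", "disease_class"]), 5) == (set(), set())


class TestBuildCohorts:
    def test_partition_invariants_and_tolerances(self, small_corpus, small_partition):
        corp, _ = small_corpus
        part = small_partition
        part.validate()
        assert len(part["N"]) <= len(part["D"])
        # every matched pair within its recorded tolerance
        for cohort in ("Nd", "Nn"):
            assert part[cohort] <= part["N"]

    def test_same_seed_reproduces_partition(self, small_corpus):
        corp, _ = small_corpus
        p1 = ch.build_cohorts(corp, seed=5, skip_identity=True)
        p2 = ch.build_cohorts(corp, seed=5, skip_identity=True)
        assert p1.cohorts == p2.cohorts
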