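"""GO enrichment and Wang/BMA semantic similarity."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from druggability import corpus as cio
from druggability import ontology as onto
from druggability import synthetic as synth

import oracles as orc


def chain_dag(depth, weight_rel="is_a"):
    """t0 (root) <- t1 <- ... <- t_depth, one namespace."""
    g = nx.DiGraph()
    for i in range(depth + 1):
        g.add_node(f"t{i}", namespace="MF")
    for i in range(1, depth + 1):
        g.add_edge(f"t{i}", f"t{i-1}", relation=weight_rel,
                   weight=cio.DEFAULT_EDGE_WEIGHTS[weight_rel])
    return cio.GoDag(g)


class TestWangSimilarity:
    def test_identity(self):
        dag = chain_dag(3)
        assert onto.wang_term_similarity("t2", "t2", dag) == pytest.approx(1.0)

    def test_two_term_parent_value(self):
        dag = chain_dag(1)
        sim = onto.wang_term_similarity("t1", "t0", dag)
        assert sim == pytest.approx(1.8 / 2.8, abs=1e-12)  # 0.642857...

    def test_symmetry(self):
        dag = chain_dag(4)
        assert onto.wang_term_similarity("t1", "t4", dag) == pytest.approx(
            onto.wang_term_similarity("t4", "t1", dag))

    def test_monotone_decay_along_chain(self):
        dag = chain_dag(6)
        sims = [onto.wang_term_similarity("t6", f"t{k}", dag) for k in range(6, -1, -1)]
        assert all(a >= b - 1e-12 for a, b in zip(sims, sims[1:]))

    def test_matches_chain_oracle(self):
        dag = chain_dag(5)
        for da in range(6):
            for db in range(6):
                assert onto.wang_term_similarity(f"t{da}", f"t{db}", dag) == (
                    pytest.approx(orc.oracle_wang_chain(da, db), abs=1e-12))

    def test_disjoint_components_have_zero_similarity(self):
        g = nx.DiGraph()
        for t in ("a0", "a1", "b0", "b1"):
            g.add_node(t, namespace="MF")
        g.add_edge("a1", "a0", relation="is_a", weight=0.8)
        g.add_edge("b1", "b0", relation="is_a", weight=0.8)
        dag = cio.GoDag(g)
        assert onto.wang_term_similarity("a1", "b1", dag) == 0.0

    def test_cross_namespace_and_unknown_term_errors(self, fixture_corpus):
        dag = fixture_corpus.dag
        with pytest.raises(ValueError):
            onto.wang_term_similarity("MF:A", "BP:X", dag)
        with pytest.raises(ValueError):
            onto.wang_term_similarity("MF:A", "nope", dag)


class TestBmaSimilarity:
    def test_identical_sets(self):
        dag = chain_dag(3)
        assert onto.set_similarity_bma(["t1", "t3"], ["t1", "t3"], dag) == (
            pytest.approx(1.0))

    def test_singletons_reduce_to_pairwise(self):
        dag = chain_dag(2)
        s = onto.wang_term_similarity("t1", "t2", dag)
        assert onto.set_similarity_bma(["t1"], ["t2"], dag) == pytest.approx(s)

    def test_two_vs_one_hand_computed(self):
        dag = chain_dag(3)
        s13 = onto.wang_term_similarity("t1", "t3", dag)
        s23 = onto.wang_term_similarity("t2", "t3", dag)
        expected = (s13 + s23 + max(s13, s23)) / 3
        assert onto.set_similarity_bma(["t1", "t2"], ["t3"], dag) == (
            pytest.approx(expected))

    def test_bounded_by_pairwise_extremes(self):
        dag = chain_dag(5)
        t1, t2 = ["t1", "t4"], ["t2", "t5"]
        sims = [onto.wang_term_similarity(a, b, dag) for a in t1 for b in t2]
        bma = onto.set_similarity_bma(t1, t2, dag)
        assert min(sims) - 1e-12 <= bma <= max(sims) + 1e-12

    def test_empty_set_error(self):
        with pytest.raises(ValueError):
            onto.set_similarity_bma([], ["t0"], chain_dag(1))


class TestEnrichment:
    def _setup(self, n_ref=1000, n_set=20, k_set=10, k_ref=50):
        g = nx.DiGraph()
        g.add_node("root", namespace="MF")
        g.add_node("term", namespace="MF")
        g.add_node("other", namespace="MF")
        g.add_edge("term", "root", relation="is_a", weight=0.8)
        g.add_edge("other", "root", relation="is_a", weight=0.8)
        dag = cio.GoDag(g)
        reference = [f"p{i}" for i in range(n_ref)]
        in_set = reference[:n_set]
        rows = [(p, "term") for p in in_set[:k_set]]
        rows += [(p, "term") for p in reference[n_set : n_set + (k_ref - k_set)]]
        rows += [(p, "other") for p in reference[::3]]
        ann = pd.DataFrame(rows, columns=["protein_id", "term_id"])
        return dag, set(reference), set(in_set), ann

    def test_fold_ratio_and_pass(self):
        dag, ref, in_set, ann = self._setup()
        results = {r.term_id: r for r in onto.enrich(in_set, ref, ann, dag)}
        r = results["term"]
        assert r.fold_ratio == pytest.approx((10 / 20) / (50 / 1000))  # 10.0
        assert r.p_value == pytest.approx(
            orc.oracle_fisher_greater(10, 10, 40, 940), rel=1e-9)
        assert r.passes

    def test_count_filter_blocks_small_sets(self):
        dag, ref, in_set, ann = self._setup(k_set=9, k_ref=9)
        results = {r.term_id: r for r in onto.enrich(in_set, ref, ann, dag)}
        assert results["term"].fold_ratio > 2
        assert not results["term"].passes

    def test_term_absent_from_set_not_enriched(self):
        dag, ref, in_set, ann = self._setup(k_set=0, k_ref=40)
        results = {r.term_id: r for r in onto.enrich(in_set, ref, ann, dag)}
        assert results["term"].fold_ratio == 0.0
        assert not results["term"].passes

    def test_ancestor_closure_counts_parents(self):
        dag, ref, in_set, ann = self._setup()
        results = {r.term_id: r for r in onto.enrich(in_set, ref, ann, dag)}
        # every annotation propagates to the root
        assert results["root"].count_in_reference == len(set(ann["protein_id"]))

    def test_empty_set_error(self):
        dag, ref, _, ann = self._setup()
        with pytest.raises(ValueError):
            onto.enrich(set(), ref, ann, dag)

    def test_set_must_be_subset_of_reference(self):
        dag, ref, _, ann = self._setup()
        with pytest.raises(ValueError):
            onto.enrich({"zz"}, ref, ann, dag)

    def test_null_annotations_rarely_pass(self):
        """With annotations independent of the protein set, almost no term
        passes the over-representation filters."""
        fractions = []
        for seed in range(10):
            cfg = synth.SyntheticConfig(seed=seed, n_targets=60, n_nontargets=180,
                                        null_mode=True)
            corp, _ = synth.generate_corpus(cfg)
            reference = set(corp.proteome)
            subset = {p for p in corp.proteome if p.startswith("T")}
            results = onto.enrich(subset, reference, corp.annotations, corp.dag)
            if results:
                fractions.append(np.mean([r.passes for r in results]))
        assert np.mean(fractions) <= 0.05


class TestWorkedFixtureEnrichment:
    def test_exactly_the_planted_term_passes(self, fixture_corpus, expected):
        corp = fixture_corpus
        s = {"A1", "A2", "B1", "B2"}
        results = onto.enrich(s, set(corp.proteome), corp.annotations, corp.dag,
                              close_ancestors=False, min_count=4)
        passing = [r.term_id for r in results if r.passes]
        assert passing == ["MF:A"]
        r = {x.term_id: x for x in results}["MF:A"]
        assert r.p_value == pytest.approx(expected["fisher_planted_term"]["p_greater"],
                                          rel=1e-12)


@pytest.fixture(scope="module")
def go_corpus():
    """Planted-GO corpus where cohorts are a minority of the reference, so
    the fold-ratio filter is attainable."""
    cfg = synth.SyntheticConfig(seed=23, n_targets=250, n_nontargets=1250,
                                nd_fraction=0.15, planted_annotation_rate=0.6)
    corp, _ = synth.generate_corpus(cfg)
    from druggability import cohorts as ch

    part = ch.build_cohorts(corp, seed=23, skip_identity=True)
    return corp, part


class TestCohortSimilarity:
    def test_identical_cohorts_have_similarity_one(self, go_corpus):
        corp, part = go_corpus
        from druggability.cohorts import CohortPartition

        twin = CohortPartition(cohorts={**part.cohorts, "N": set(part["D"])})
        out = onto.cohort_similarity(twin, corp.annotations, corp.dag,
                                     set(corp.proteome), pairs=[("D", "N")])
        row = out.loc["D-N"]
        assert all(np.isnan(v) or v == pytest.approx(1.0) for v in row)
        assert row["mean"] == pytest.approx(1.0)

    def test_shared_mf_terms_raise_mf_similarity_above_bp(self, go_corpus):
        """Targets and the high-disease group share planted MF terms but have
        disjoint planted BP terms, so MF similarity must exceed BP."""
        corp, part = go_corpus
        out = onto.cohort_similarity(part, corp.annotations, corp.dag,
                                     set(corp.proteome), pairs=[("D", "Nd")])
        row = out.loc["D-Nd"]
        assert np.isfinite(row["MF"]) and np.isfinite(row["BP"])
        assert row["MF"] > row["BP"]

    def test_empty_enrichment_cell_absent_with_warning(self, caplog):
        cfg = synth.SyntheticConfig(seed=29, n_targets=40, n_nontargets=80,
                                    null_mode=True)
        corp, _ = synth.generate_corpus(cfg)
        from druggability import cohorts as ch

        part = ch.build_cohorts(corp, seed=29, skip_identity=True)
        with caplog.at_level("WARNING"):
            out = onto.cohort_similarity(part, corp.annotations, corp.dag,
                                         set(corp.proteome))
        assert out.isna().any().any()
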