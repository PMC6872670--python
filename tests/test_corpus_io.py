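"""Parsers and writers: format handling, invariant enforcement, round trips."""

import numpy as np
import pandas as pd
import pytest

from druggability import corpus as cio


# ---------------------------------------------------------------------------
# FASTA


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestFasta:
    def test_single_record(self, tmp_path):
        assert cio.read_fasta(_write(tmp_path, "a.fa", ">p1\nMKV\n")) == [("p1", "MKV")]

    def test_header_token_and_case_normalisation(self, tmp_path):
        recs = cio.read_fasta(_write(tmp_path, "a.fa", ">p1 some description\nmkv\n>p2\nACDE\n"))
        assert recs == [("p1", "MKV"), ("p2", "ACDE")]

    def test_non_canonical_letters_become_x(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            recs = cio.read_fasta(_write(tmp_path, "a.fa", ">p1\nMKB\n"))
        assert recs == [("p1", "MKX")]
        assert any("non-canonical" in r.message for r in caplog.records)

    @pytest.mark.parametrize("text", ["", ">p1\nMKV\n>p1\nACD\n"])
    def test_empty_or_duplicate_is_hard_error(self, tmp_path, text):
        with pytest.raises(cio.CorpusError):
            cio.read_fasta(_write(tmp_path, "bad.fa", text))

    def test_round_trip(self, tmp_path):
        records = [("p1", "MKV" * 30), ("p2", "ACDEFGHIKLMNPQRSTVWY")]
        path = tmp_path / "rt.fa"
        cio.write_fasta(records, path)
        assert cio.read_fasta(path) == records


# ---------------------------------------------------------------------------
# PSSM


class TestPssm:
    def test_uniform_tsv_row(self, tmp_path):
        path = _write(tmp_path, "p.tsv", "\t".join(["0.05"] * 20) + "\n")
        pssm = cio.read_pssm(path, pseudocount=0.0)
        assert np.allclose(pssm.probs, 0.05)

    def test_pseudocount_renormalisation(self, tmp_path):
        row = ["1.0"] + ["0.0"] * 19
        path = _write(tmp_path, "p.tsv", "\t".join(row) + "\n")
        pssm = cio.read_pssm(path, pseudocount=1e-4)
        assert pssm.probs[0, 0] == pytest.approx((1 + 1e-4) / (1 + 20e-4))
        assert pssm.probs[0, 1] == pytest.approx(1e-4 / (1 + 20e-4))

    def test_ascii_dialect_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(20), size=3)
        path = tmp_path / "p.pssm"
        cio.write_pssm_ascii("p1", "MKV", probs * 100.0, path)
        pssm = cio.read_pssm(path, expected_length=3)
        assert pssm.probs.shape == (3, 20)
        # percentages are written rounded; agreement is to the percent level
        assert np.abs(pssm.probs - probs).max() < 0.02

    def test_length_mismatch_and_negatives_are_errors(self, tmp_path):
        path = _write(tmp_path, "p.tsv", "\t".join(["0.05"] * 20) + "\n")
        with pytest.raises(cio.CorpusError):
            cio.read_pssm(path, expected_length=2)
        bad = _write(tmp_path, "neg.tsv", "\t".join(["-0.05"] + ["0.05"] * 19) + "\n")
        with pytest.raises(cio.CorpusError):
            cio.read_pssm(bad)


# ---------------------------------------------------------------------------
# TSV tables and tracks


class TestTables:
    def test_duplicate_rows_dropped(self, tmp_path):
        text = ("compound_id\tstructure\tprotein_id\tdrug_status\n"
                "c1\ts1\tp1\tapproved\n" "c1\ts1\tp1\tapproved\n")
        df = cio.read_table(_write(tmp_path, "i.tsv", text), "interactions")
        assert len(df) == 1

    def test_missing_column_is_hard_error(self, tmp_path):
        text = "compound_id\tstructure\tprotein_id\nc1\ts1\tp1\n"
        with pytest.raises(cio.CorpusError, match="drug_status"):
            cio.read_table(_write(tmp_path, "i.tsv", text), "interactions")

    def test_unknown_protein_flagged_not_dropped(self):
        proteome = {"p1": cio.ProteinRecord("p1", "MKV")}
        diseases = pd.DataFrame(
            [("p1", "d1", "ca"), ("px", "d2", "cb")],
            columns=["protein_id", "disease_id", "disease_class"],
        )
        report = cio.validate_cross_references(proteome, diseases)
        assert len(report) == 1 and "px" in report[0]

    def test_track_length_mismatch_is_hard_error(self):
        proteome = {"p1": cio.ProteinRecord("p1", "MKV")}
        track = pd.DataFrame(
            {"protein_id": ["p1", "p1"], "position": [1, 2], "score": [0.1, 0.2]}
        )
        with pytest.raises(cio.CorpusError):
            cio.attach_tracks(proteome, track, "disorder")

    def test_track_round_trip(self):
        proteome = {"p1": cio.ProteinRecord("p1", "MKV")}
        track = pd.DataFrame(
            {"protein_id": ["p1"] * 3, "position": [1, 2, 3], "score": [0.1, 0.5, 0.9]}
        )
        cio.attach_tracks(proteome, track, "disorder")
        out = cio.tracks_to_table(proteome, "disorder")
        pd.testing.assert_frame_equal(out, track)

    def test_domain_coordinates_are_one_based_inclusive_in_files(self):
        proteome = {"p1": cio.ProteinRecord("p1", "MKVLLL")}
        cio.attach_domains(
            proteome,
            pd.DataFrame({"protein_id": ["p1"], "start": [2], "end": [4]}),
        )
        assert proteome["p1"].domains == [(1, 4)]  # 0-based half-open internally
        with pytest.raises(cio.CorpusError):
            cio.attach_domains(
                proteome, pd.DataFrame({"protein_id": ["p1"], "start": [3], "end": [9]})
            )


# ---------------------------------------------------------------------------
# ontology


class TestGoDag:
    def test_two_term_edgelist_default_weight(self, tmp_path):
        text = "child\tparent\trelation\tnamespace\nA\tB\tis_a\tMF\n"
        dag, _ = cio.read_go(_write(tmp_path, "d.tsv", text))
        assert dag.graph.number_of_edges() == 1
        assert dag.graph.edges["A", "B"]["weight"] == pytest.approx(0.8)

    def test_part_of_weight(self, tmp_path):
        text = "child\tparent\trelation\tnamespace\nA\tB\tpart_of\tCC\n"
        dag, _ = cio.read_go(_write(tmp_path, "d.tsv", text))
        assert dag.graph.edges["A", "B"]["weight"] == pytest.approx(0.6)

    def test_annotation_to_unknown_term_dropped(self, tmp_path):
        dag_text = "child\tparent\trelation\tnamespace\nA\tB\tis_a\tMF\n"
        ann_text = "protein_id\tterm_id\np1\tA\np1\tZZ\n"
        dag, ann = cio.read_go(
            _write(tmp_path, "d.tsv", dag_text), _write(tmp_path, "a.tsv", ann_text)
        )
        assert list(ann["term_id"]) == ["A"]

    def test_self_edge_is_cycle_error(self, tmp_path):
        text = "child\tparent\trelation\tnamespace\nA\tA\tis_a\tMF\n"
        with pytest.raises(cio.CorpusError, match="cycle"):
            cio.read_go(_write(tmp_path, "d.tsv", text))

    def test_obo_round_trip(self, tmp_path, fixture_corpus):
        from druggability.synthetic import _write_obo

        path = tmp_path / "ont.obo"
        _write_obo(fixture_corpus.dag, path)
        dag, _ = cio.read_go(path)
        assert set(dag.graph.nodes) == set(fixture_corpus.dag.graph.nodes)
        assert set(dag.graph.edges) == set(fixture_corpus.dag.graph.edges)
        for child, parent in dag.graph.edges:
            assert (dag.graph.edges[child, parent]["relation"]
                    == fixture_corpus.dag.graph.edges[child, parent]["relation"])

    def test_ancestor_closure_includes_self(self, fixture_corpus):
        dag = fixture_corpus.dag
        assert dag.ancestors("MF:A") == {"MF:A", "MF:R"}
        assert dag.ancestors("MF:R") == {"MF:R"}


class TestRecordInvariants:
    def test_track_outside_unit_interval_rejected(self):
        rec = cio.ProteinRecord("p1", "MKV")
        rec.tracks["disorder"] = np.array([0.0, 0.5, 1.5])
        with pytest.raises(cio.CorpusError):
            rec.validate()

    def test_domain_outside_sequence_rejected(self):
        rec = cio.ProteinRecord("p1", "MKV", domains=[(0, 5)])
        with pytest.raises(cio.CorpusError):
            rec.validate()

    def test_pssm_row_sum_enforced(self):
        probs = np.full((2, 20), 0.05)
        probs[0, 0] = 0.5
        with pytest.raises(cio.CorpusError):
            cio.Pssm("p1", probs, cio.uniform_background()).validate()
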