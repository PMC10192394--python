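"""Sequence I/O, PSP window extraction, and benchmark construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kprfunc import seqio
from kprfunc.seqio import PSPItem, ProteinRecord


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestReadFasta:
    def test_minimal_record(self, tmp_path):
        recs = seqio.read_fasta(write(tmp_path, "a.fa", ">p1\nMKG\n"))
        assert recs == [ProteinRecord("p1", "MKG")]

    def test_case_folding_and_multi_record(self, tmp_path):
        recs = seqio.read_fasta(write(tmp_path, "a.fa", ">p1\nmkg\n>p2\nKK\n"))
        assert [r.sequence for r in recs] == ["MKG", "KK"]

    def test_u_and_o_mapped_to_x(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            recs = seqio.read_fasta(write(tmp_path, "a.fa", ">p1\nMUKO\n"))
        assert recs[0].sequence == "MXKX"
        assert any("U/O" in r.message for r in caplog.records)

    def test_duplicate_accession_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate accession 'p1'"):
            seqio.read_fasta(write(tmp_path, "a.fa", ">p1\nMK\n>p1\nGG\n"))

    def test_sequence_before_header_names_line(self, tmp_path):
        with pytest.raises(ValueError, match=":1:"):
            seqio.read_fasta(write(tmp_path, "a.fa", "MKG\n>p1\nAA\n"))

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            assert seqio.read_fasta(write(tmp_path, "a.fa", "")) == []
        assert any("no FASTA records" in r.message for r in caplog.records)

    def test_roundtrip_with_write_fasta(self, tmp_path):
        recs = [ProteinRecord("p1", "MKG" * 50), ProteinRecord("p2", "KK")]
        seqio.write_fasta(tmp_path / "out.fa", recs)
        assert seqio.read_fasta(tmp_path / "out.fa") == recs


class TestExtractPsp:
    def test_single_residue_protein_fully_padded(self):
        item = seqio.extract_psp(ProteinRecord("x", "K"), 1)
        assert item.peptide == "*" * 30 + "K" + "*" * 30
        assert len(item.peptide) == 61

    def test_histone_h2b_window(self):
        # H2B fragment Ala12..Lys24 with the propionylated K at position 17
        seq = "M" + "A" * 10 + "AGKAQKNITKTDK" + "A" * 10
        item = seqio.extract_psp(ProteinRecord("H2B", seq), 17)
        centre = len(item.peptide) // 2
        assert item.peptide[centre - 2 : centre + 5] == "AQKNITK"
        assert item.position == 17

    def test_non_lysine_position_rejected(self):
        with pytest.raises(ValueError, match="'A', not K"):
            seqio.extract_psp(ProteinRecord("x", "AKA"), 1)

    def test_position_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            seqio.extract_psp(ProteinRecord("x", "AK"), 5)

    @settings(derandomize=True, max_examples=30)
    @given(st.text(alphabet="ACDKGK", min_size=1, max_size=120), st.integers(0, 40))
    def test_total_over_all_lysines_with_fixed_width(self, seq, m):
        rec = ProteinRecord("p", seq)
        for pos, ch in enumerate(seq, start=1):
            if ch == "K":
                item = seqio.extract_psp(rec, pos, m=m, n=m)
                assert len(item.peptide) == 2 * m + 1
                assert item.peptide[m] == "K"


class TestPSPItemInvariants:
    def test_central_residue_must_be_lysine(self):
        with pytest.raises(ValueError, match="not K"):
            PSPItem("p", 1, "A" * 61)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            PSPItem("p", 1, "A" * 30 + "K" + "A" * 30, label="bogus")


class TestBuildBenchmark:
    def test_other_lysines_become_negatives(self):
        res = seqio.build_benchmark([("p", 1)], [ProteinRecord("p", "KAKA")], m=2, n=2)
        assert [(it.position, it.label) for it in res.items] == [
            (1, "positive"),
            (3, "negative"),
        ]

    def test_duplicate_peptides_collapse_positive_wins(self):
        prot = [ProteinRecord("a", "AKA"), ProteinRecord("b", "AKA")]
        res = seqio.build_benchmark([("a", 2)], prot, m=2, n=2)
        assert len(res.items) == 1
        assert res.items[0].label == "positive"

    def test_deterministic_and_idempotent(self, tmp_path):
        proteome = [ProteinRecord("p1", "KAKAKG"), ProteinRecord("p2", "GGKAKA")]
        sites = [("p1", 1), ("p2", 3)]
        a = seqio.build_benchmark(sites, proteome, m=3, n=3)
        b = seqio.build_benchmark(sites, proteome, m=3, n=3)
        seqio.write_benchmark_table(tmp_path / "a.tsv", a.items)
        seqio.write_benchmark_table(tmp_path / "b.tsv", b.items)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        # rebuilding from its own positive sites changes nothing
        again = seqio.build_benchmark(
            [(it.source_accession, it.position) for it in a.positives], proteome, m=3, n=3
        )
        assert again.items == a.items

    def test_non_lysine_positive_reported_not_dropped(self):
        res = seqio.build_benchmark(
            [("p", 1), ("p", 2)], [ProteinRecord("p", "AK")], m=1, n=1
        )
        assert list(res.rejects["position"]) == [1]
        assert "not K" in res.rejects["reason"].iloc[0]
        assert [it.position for it in res.positives] == [2]


class TestTables:
    def test_elm_roundtrip(self, tmp_path):
        items = [PSPItem("p1", 17, "*" * 30 + "K" + "A" * 30)]
        seqio.write_elm(tmp_path / "e.tsv", items)
        df = seqio.read_elm(tmp_path / "e.tsv")
        assert df.iloc[0].tolist() == ["p1", 17, items[0].peptide]

    def test_elm_non_integer_position(self, tmp_path):
        p = write(tmp_path, "e.tsv", "p1\tseven\t" + "*" * 30 + "K" + "*" * 30 + "\n")
        with pytest.raises(ValueError, match="non-integer position"):
            seqio.read_elm(p)

    def test_prediction_roundtrip_and_formatting(self, tmp_path):
        import pandas as pd

        pep = "*" * 30 + "K" + "*" * 30
        rows = pd.DataFrame(
            [
                {"accession": "p1", "position": 17, "residue": "K",
                 "predictor": "KprFunc", "peptide": pep, "score": 0.91, "cutoff": 0.55},
                {"accession": "p2", "position": 3, "residue": "K",
                 "predictor": "KprFunc", "peptide": pep, "score": 1.0, "cutoff": 0.5},
            ]
        )
        seqio.write_predictions(tmp_path / "p.tsv", rows)
        text = (tmp_path / "p.tsv").read_text()
        assert "0.9100" in text and "1.0000" in text
        back = seqio.read_predictions(tmp_path / "p.tsv")
        assert back["score"].tolist() == [0.91, 1.0]
        assert back["position"].tolist() == [17, 3]

    def test_prediction_missing_column_rejected(self, tmp_path):
        p = write(tmp_path, "p.tsv", "accession\tposition\n" "p1\t2\n")
        with pytest.raises(ValueError, match="expected columns"):
            seqio.read_predictions(p)

    def test_benchmark_table_roundtrip(self, tmp_path):
        items = [
            PSPItem("p1", 1, "*" * 30 + "K" + "A" * 30, "positive"),
            PSPItem("p1", 5, "G" * 30 + "K" + "*" * 30, "negative"),
        ]
        seqio.write_benchmark_table(tmp_path / "b.tsv", items)
        assert seqio.read_benchmark_table(tmp_path / "b.tsv") == items
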