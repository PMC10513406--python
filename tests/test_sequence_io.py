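"""FASTA / label-TSV / prediction-TSV round trips and alphabet rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rospred import (
    LabeledExample,
    ProteinRecord,
    normalize_sequence,
    read_fasta,
    read_label_table,
    read_predictions,
    write_fasta,
    write_label_table,
    write_predictions,
)
from rospred.ensemble import HierarchicalPrediction
from rospred.sequence_io import (
    ALPHABET,
    NEGATIVE_SENTINEL,
    NormalizationReport,
    SequenceIOError,
    join_labels,
)
from conftest import random_records


class TestReadFasta:
    def test_case_normalization_and_order(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">a\nMKV\n>b\nacd\n")
        records, report = read_fasta(p)
        assert [r.id for r in records] == ["a", "b"]
        assert [r.sequence for r in records] == ["MKV", "ACD"]
        assert report.total == 0

    def test_selenocysteine_remapped_with_report(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">a\nMKU\n")
        records, report = read_fasta(p)
        assert records[0].sequence == "MKC"
        assert report.substitutions == {"U->C": 1}

    def test_pyrrolysine_and_junk_remapped(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">a\nMOJ\n")
        records, report = read_fasta(p)
        assert records[0].sequence == "MKX"
        assert report.total == 2

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">a\nMK\n>a\nVV\n")
        with pytest.raises(SequenceIOError, match="duplicate"):
            read_fasta(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_fasta(tmp_path / "nope.fasta")

    def test_multiline_sequences_joined(self, tmp_path):
        p = tmp_path / "in.fasta"
        p.write_text(">a desc here\nMKV\nACD\n")
        records, _ = read_fasta(p)
        assert records[0].sequence == "MKVACD"
        assert records[0].description == "desc here"


class TestWriteFasta:
    def test_single_record_round_trip(self, tmp_path):
        p = tmp_path / "out.fasta"
        write_fasta([ProteinRecord(id="a", sequence="MKV")], p)
        records, _ = read_fasta(p)
        assert records == [ProteinRecord(id="a", sequence="MKV")]

    def test_empty_collection_gives_valid_empty_file(self, tmp_path):
        p = tmp_path / "out.fasta"
        write_fasta([], p)
        records, _ = read_fasta(p)
        assert records == []

    def test_thousand_random_records_round_trip(self, tmp_path, rng):
        records = random_records(rng, 1000, min_len=1, max_len=120)
        p = tmp_path / "out.fasta"
        write_fasta(records, p)
        back, _ = read_fasta(p)
        assert [r.id for r in back] == [r.id for r in records]
        assert [r.sequence for r in back] == [r.sequence for r in records]

    def test_long_sequences_wrapped_at_60(self, tmp_path):
        p = tmp_path / "out.fasta"
        write_fasta([ProteinRecord(id="a", sequence="A" * 130)], p)
        lines = p.read_text().splitlines()
        assert [len(x) for x in lines[1:]] == [60, 60, 10]


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet=st.characters(codec="ascii"), min_size=0, max_size=80))
def test_normalization_idempotent_and_on_alphabet(raw):
    once = normalize_sequence(raw, NormalizationReport())
    assert set(once) <= set(ALPHABET)
    assert normalize_sequence(once) == once


class TestLabelTable:
    def test_positive_and_negative_rows(self, tmp_path):
        p = tmp_path / "labels.tsv"
        p.write_text("s1\tpos\tcatalase\ns2\tneg\n")
        labels = read_label_table(p)
        assert labels == {"s1": (True, "catalase"), "s2": (False, None)}

    def test_positive_without_class_rejected(self, tmp_path):
        p = tmp_path / "labels.tsv"
        p.write_text("s3\tpos\n")
        with pytest.raises(SequenceIOError, match="lacks a class"):
            read_label_table(p)

    def test_unknown_token_rejected(self, tmp_path):
        p = tmp_path / "labels.tsv"
        p.write_text("s1\tmaybe\tcatalase\n")
        with pytest.raises(SequenceIOError, match="unknown level-1"):
            read_label_table(p)

    def test_round_trip_via_examples(self, tmp_path):
        examples = [
            LabeledExample(
                record=ProteinRecord(id="x", sequence="MKV"),
                positive=True,
                level2="catalase",
            ),
            LabeledExample(
                record=ProteinRecord(id="y", sequence="ACD"), positive=False
            ),
        ]
        p = tmp_path / "labels.tsv"
        write_label_table(examples, p)
        labels = read_label_table(p)
        rejoined = join_labels([e.record for e in examples], labels)
        assert rejoined == examples

    def test_join_requires_every_record_labeled(self):
        with pytest.raises(SequenceIOError, match="no label"):
            join_labels([ProteinRecord(id="z", sequence="MK")], {})


class TestLabeledExampleInvariants:
    def test_negative_with_class_rejected(self):
        with pytest.raises(SequenceIOError):
            LabeledExample(
                record=ProteinRecord(id="a", sequence="MK"),
                positive=False,
                level2="catalase",
            )

    def test_positive_without_class_rejected(self):
        with pytest.raises(SequenceIOError):
            LabeledExample(
                record=ProteinRecord(id="a", sequence="MK"), positive=True
            )


class TestPredictionTSV:
    def _preds(self):
        return [
            HierarchicalPrediction(
                id="p1",
                level1_votes=(True, True, False),
                positive=True,
                level2_class="catalase",
                level2_probabilities=(0.7, 0.2, 0.1),
            ),
            HierarchicalPrediction(
                id="n1",
                level1_votes=(False, False, True),
                positive=False,
                level2_class=NEGATIVE_SENTINEL,
                level2_probabilities=None,
            ),
        ]

    def test_written_columns_and_sentinel(self, tmp_path):
        p = tmp_path / "pred.tsv"
        write_predictions(self._preds(), p)
        lines = p.read_text().splitlines()
        assert lines[0].split("\t") == [
            "id", "level1_decision", "level1_votes", "level2_class",
            "level2_probabilities",
        ]
        neg_row = lines[2].split("\t")
        assert neg_row[1] == "neg"
        assert neg_row[3] == NEGATIVE_SENTINEL
        assert neg_row[4] == ""

    def test_probability_vector_normalized(self, tmp_path):
        p = tmp_path / "pred.tsv"
        write_predictions(self._preds(), p)
        rows = read_predictions(p)
        assert abs(sum(rows[0].level2_probabilities) - 1.0) < 1e-9
        assert rows[0].level2_class == "catalase"

    def test_empty_prediction_set_header_only(self, tmp_path):
        p = tmp_path / "pred.tsv"
        write_predictions([], p)
        assert p.read_text().count("\n") == 1
        assert read_predictions(p) == []

    def test_round_trip(self, tmp_path):
        p = tmp_path / "pred.tsv"
        preds = self._preds()
        write_predictions(preds, p)
        rows = read_predictions(p)
        assert [r.id for r in rows] == ["p1", "n1"]
        assert rows[0].level1_votes == (True, True, False)
        assert rows[1].positive is False
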