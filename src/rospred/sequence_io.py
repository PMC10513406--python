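"""Reading and writing the formats the framework touches.

Protein sequences travel as FASTA, labels as a two/three-column TSV
(``id<TAB>level1<TAB>level2``), and predictions as a five-column TSV.
All residue strings are normalized onto a fixed 23-letter alphabet:
the 20 standard amino acids plus ``X`` (unknown), ``B`` (Asx) and
``Z`` (Glx).  The rare residues selenocysteine (``U``) and pyrrolysine
(``O``) are remapped to their structural analogues ``C`` and ``K``;
any other letter becomes ``X``.  Substitution counts are reported so
that silent data mangling is impossible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_RESIDUES = "XBZ"
#: the 23-letter alphabet every stored sequence is drawn from
ALPHABET = STANDARD_RESIDUES + AMBIGUOUS_RESIDUES

#: sentinel class emitted when the level-1 gate rejects a sequence
NEGATIVE_SENTINEL = "non-ROSes"

_REMAP = {"U": "C", "O": "K"}

POSITIVE_TOKENS = frozenset({"pos", "positive", "1", "roses"})
NEGATIVE_TOKENS = frozenset({"neg", "negative", "0", "non-roses"})


class SequenceIOError(ValueError):
    """Malformed input file or record."""


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry after alphabet normalization."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceIOError("record id must be non-empty")
        if not self.sequence:
            raise SequenceIOError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise SequenceIOError(
                f"record {self.id!r}: characters {sorted(bad)} outside the "
                f"23-letter alphabet; normalize with normalize_sequence() first"
            )


@dataclass(frozen=True)
class LabeledExample:
    """A record with its binary gate label and, for positives, a class."""

    record: ProteinRecord
    positive: bool
    level2: str | None = None

    def __post_init__(self) -> None:
        if self.positive and self.level2 is None:
            raise SequenceIOError(
                f"positive example {self.record.id!r} lacks a level-2 class"
            )
        if not self.positive and self.level2 is not None:
            raise SequenceIOError(
                f"negative example {self.record.id!r} must not carry a class"
            )


@dataclass
class NormalizationReport:
    """Counts of residue substitutions applied while reading."""

    substitutions: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.substitutions.values())

    def record(self, original: str, replacement: str) -> None:
        key = f"{original}->{replacement}"
        self.substitutions[key] = self.substitutions.get(key, 0) + 1


def normalize_sequence(raw: str, report: NormalizationReport | None = None) -> str:
    """Uppercase and map onto the 23-letter alphabet (idempotent)."""
    out = []
    for ch in raw.upper():
        if ch in ALPHABET:
            out.append(ch)
            continue
        sub = _REMAP.get(ch, "X")
        if report is not None:
            report.record(ch, sub)
        out.append(sub)
    return "".join(out)


def read_fasta(path: str | Path) -> tuple[list[ProteinRecord], NormalizationReport]:
    """Read FASTA, preserving order, normalizing residues.

    Raises on missing files, duplicate ids and empty sequences.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = NormalizationReport()
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceIOError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq), report)
        if not seq:
            raise SequenceIOError(f"record {rec.id!r} in {path}: empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    return records, report


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records, sequences wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seq_records)


def read_label_table(path: str | Path) -> dict[str, tuple[bool, str | None]]:
    """Read ``id<TAB>level1[<TAB>level2]`` rows into a mapping.

    ``level1`` accepts pos/neg (and common synonyms).  Positives must
    carry a level-2 class; negatives must not.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels: dict[str, tuple[bool, str | None]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SequenceIOError(f"{path}:{lineno}: expected ≥2 columns")
            seq_id, token = parts[0], parts[1].lower()
            level2 = parts[2] if len(parts) > 2 and parts[2] else None
            if seq_id in labels:
                raise SequenceIOError(f"{path}:{lineno}: duplicate id {seq_id!r}")
            if token in POSITIVE_TOKENS:
                if level2 is None:
                    raise SequenceIOError(
                        f"{path}:{lineno}: positive row {seq_id!r} lacks a class"
                    )
                labels[seq_id] = (True, level2)
            elif token in NEGATIVE_TOKENS:
                if level2 is not None:
                    raise SequenceIOError(
                        f"{path}:{lineno}: negative row {seq_id!r} carries a class"
                    )
                labels[seq_id] = (False, None)
            else:
                raise SequenceIOError(
                    f"{path}:{lineno}: unknown level-1 token {parts[1]!r}"
                )
    return labels


def write_label_table(examples: Iterable[LabeledExample], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ex in examples:
            if ex.positive:
                fh.write(f"{ex.record.id}\tpos\t{ex.level2}\n")
            else:
                fh.write(f"{ex.record.id}\tneg\n")


def join_labels(
    records: Sequence[ProteinRecord],
    labels: Mapping[str, tuple[bool, str | None]],
) -> list[LabeledExample]:
    """Pair records with their label rows; every record must be labeled."""
    examples = []
    for rec in records:
        if rec.id not in labels:
            raise SequenceIOError(f"no label for record {rec.id!r}")
        positive, level2 = labels[rec.id]
        examples.append(LabeledExample(record=rec, positive=positive, level2=level2))
    return examples


PREDICTION_COLUMNS = (
    "id",
    "level1_decision",
    "level1_votes",
    "level2_class",
    "level2_probabilities",
)


def write_predictions(predictions: Iterable, path: str | Path) -> None:
    """Write prediction rows as TSV with a fixed column order.

    Accepts any objects exposing ``id``, ``level1_votes`` (sequence of
    bool), ``positive`` (bool), ``level2_class`` (str) and
    ``level2_probabilities`` (sequence of float or None).
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for p in predictions:
            votes = ",".join("pos" if v else "neg" for v in p.level1_votes)
            decision = "pos" if p.positive else "neg"
            if p.level2_probabilities is None:
                probs = ""
            else:
                probs = ",".join(f"{x:.6f}" for x in p.level2_probabilities)
            fh.write(
                f"{p.id}\t{decision}\t{votes}\t{p.level2_class}\t{probs}\n"
            )


@dataclass(frozen=True)
class PredictionRow:
    """One parsed row of a prediction TSV."""

    id: str
    level1_votes: tuple[bool, ...]
    positive: bool
    level2_class: str
    level2_probabilities: tuple[float, ...] | None


def read_predictions(path: str | Path) -> list[PredictionRow]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[PredictionRow] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PREDICTION_COLUMNS:
            raise SequenceIOError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(PREDICTION_COLUMNS):
                raise SequenceIOError(f"{path}:{lineno}: expected 5 columns")
            seq_id, decision, votes, level2, probs = parts
            rows.append(
                PredictionRow(
                    id=seq_id,
                    level1_votes=tuple(v == "pos" for v in votes.split(",")),
                    positive=decision == "pos",
                    level2_class=level2,
                    level2_probabilities=(
                        tuple(float(x) for x in probs.split(",")) if probs else None
                    ),
                )
            )
    return rows


def fasta_string(records: Iterable[ProteinRecord]) -> str:
    """FASTA serialization as a string (used for determinism checks)."""
    buf = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=60)
    writer.write_file(
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    )
    return buf.getvalue()
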