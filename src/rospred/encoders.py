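"""Feature encoders for the three component classifiers.

Three representations are produced from a protein sequence:

* frequency-ranked integer tokens, post-padded to a fixed length
  (input to the convolutional network);
* CKSAAGP — composition of k-spaced amino-acid *group* pairs, 25
  ordered group pairs per spacing (input to the feed-forward net);
* CKSAAP — composition of k-spaced amino-acid pairs, 400 ordered
  residue pairs per spacing (input to the boosted trees).

For spacing ``k`` a pair is two positions exactly ``k`` residues
apart-minus-one, i.e. positions ``(i, i+k+1)``; a sequence of length
``L`` admits ``L - k - 1`` such pairs and that count is the
normalizing denominator.  Pairs touching an ambiguous residue
(X/B/Z) count toward the denominator but no numerator cell, so each
k-block sums to 1 minus the ambiguous mass.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequence_io import ProteinRecord, STANDARD_RESIDUES

#: the conventional 5-group physicochemical partition of the 20 residues
DEFAULT_GROUP_SCHEME: dict[str, str] = {
    "g1.aliphatic": "GAVLMI",
    "g2.aromatic": "FYW",
    "g3.positive": "KRH",
    "g4.negative": "DE",
    "g5.uncharged": "STCPNQ",
}


class EncoderError(ValueError):
    """Sequence cannot be encoded under the requested parameters."""


@dataclass(frozen=True)
class TokenVocabulary:
    """Characters ranked by corpus frequency; rank 0 is the pad."""

    rank_of: Mapping[str, int]

    @property
    def max_index(self) -> int:
        return len(self.rank_of)

    @property
    def pad_index(self) -> int:
        return 0

    def to_dict(self) -> dict[str, int]:
        return dict(self.rank_of)

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "TokenVocabulary":
        return cls(rank_of=dict(d))


@dataclass(frozen=True)
class EncoderConfig:
    """Shared encoder settings.

    ``k_max`` is the largest spacing (residues between a pair);
    ``pad_length`` the fixed token-row length; ``group_scheme`` the
    5-way residue partition used by CKSAAGP.
    """

    k_max: int = 5
    pad_length: int = 1000
    group_scheme: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SCHEME)
    )

    def __post_init__(self) -> None:
        if self.k_max < 0:
            raise ValueError("k_max must be non-negative")
        if self.pad_length < 1:
            raise ValueError("pad_length must be ≥ 1")
        covered = "".join(sorted("".join(self.group_scheme.values())))
        if covered != "".join(sorted(STANDARD_RESIDUES)):
            raise ValueError(
                "group_scheme must partition the 20 standard residues exactly"
            )


def build_vocabulary(records: Iterable[ProteinRecord]) -> TokenVocabulary:
    """Rank characters by descending corpus frequency, ties lexicographic.

    ``X`` is always included (it is the fallback for unseen characters
    at encode time); if unobserved it receives the last rank.
    """
    counts: Counter[str] = Counter()
    for rec in records:
        counts.update(rec.sequence)
    if not counts:
        raise EncoderError("cannot build a vocabulary from an empty corpus")
    ordered = sorted(counts, key=lambda c: (-counts[c], c))
    if "X" not in counts:
        ordered.append("X")
    return TokenVocabulary(rank_of={c: i + 1 for i, c in enumerate(ordered)})


def encode_tokens(
    record: ProteinRecord, vocab: TokenVocabulary, pad_length: int
) -> np.ndarray:
    """Map residues to ranks, truncate/post-pad to ``pad_length``."""
    if pad_length < 1:
        raise ValueError("pad_length must be ≥ 1")
    fallback = vocab.rank_of["X"]
    row = np.zeros(pad_length, dtype=np.int64)
    for i, ch in enumerate(record.sequence[:pad_length]):
        row[i] = vocab.rank_of.get(ch, fallback)
    return row


def encode_token_matrix(
    records: Sequence[ProteinRecord], vocab: TokenVocabulary, pad_length: int
) -> np.ndarray:
    return np.stack([encode_tokens(r, vocab, pad_length) for r in records]) \
        if records else np.zeros((0, pad_length), dtype=np.int64)


def _pair_features(
    sequence: str,
    k_max: int,
    symbol_of: Mapping[str, int],
    n_symbols: int,
    what: str,
) -> np.ndarray:
    """Shared k-spaced ordered-pair counting for CKSAAP/CKSAAGP."""
    L = len(sequence)
    if L < k_max + 2:
        raise EncoderError(
            f"{what}: sequence of length {L} admits no pair at spacing "
            f"k={k_max} (needs length ≥ {k_max + 2})"
        )
    codes = np.array([symbol_of.get(ch, -1) for ch in sequence], dtype=np.int64)
    out = np.zeros((k_max + 1) * n_symbols * n_symbols, dtype=np.float64)
    for k in range(k_max + 1):
        a = codes[: L - k - 1]
        b = codes[k + 1:]
        valid = (a >= 0) & (b >= 0)
        idx = a[valid] * n_symbols + b[valid]
        block = np.bincount(idx, minlength=n_symbols * n_symbols).astype(np.float64)
        out[k * n_symbols**2 : (k + 1) * n_symbols**2] = block / (L - k - 1)
    return out


def cksaap_feature_names(k_max: int) -> list[str]:
    return [
        f"{a}{b}|{k}"
        for k in range(k_max + 1)
        for a in STANDARD_RESIDUES
        for b in STANDARD_RESIDUES
    ]


def cksaap(sequence: str, k_max: int = 5) -> np.ndarray:
    """Composition of k-spaced amino-acid pairs, 400·(k_max+1) features."""
    symbol_of = {ch: i for i, ch in enumerate(STANDARD_RESIDUES)}
    return _pair_features(sequence, k_max, symbol_of, 20, "cksaap")


def cksaagp_feature_names(
    k_max: int, group_scheme: Mapping[str, str] | None = None
) -> list[str]:
    groups = list(group_scheme or DEFAULT_GROUP_SCHEME)
    return [f"{a}~{b}|{k}" for k in range(k_max + 1) for a in groups for b in groups]


def cksaagp(
    sequence: str,
    k_max: int = 5,
    group_scheme: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Composition of k-spaced amino-acid *group* pairs, 25·(k_max+1) features."""
    scheme = group_scheme or DEFAULT_GROUP_SCHEME
    symbol_of = {
        ch: gi for gi, members in enumerate(scheme.values()) for ch in members
    }
    n_groups = len(scheme)
    return _pair_features(sequence, k_max, symbol_of, n_groups, "cksaagp")


def write_feature_table(
    matrix: np.ndarray,
    feature_names: Sequence[str],
    ids: Sequence[str],
    path,
) -> None:
    """Export a feature matrix as TSV with an ``id`` column and the
    feature names as header."""
    import pandas as pd

    if matrix.shape != (len(ids), len(feature_names)):
        raise ValueError("matrix shape does not match ids × feature_names")
    df = pd.DataFrame(matrix, columns=list(feature_names))
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def encode_feature_matrix(
    records: Sequence[ProteinRecord],
    encoder: str,
    config: EncoderConfig,
) -> np.ndarray:
    """Stack per-record descriptor rows; ``encoder`` is cksaap|cksaagp."""
    if encoder == "cksaap":
        dim = 400 * (config.k_max + 1)
        rows = [cksaap(r.sequence, config.k_max) for r in records]
    elif encoder == "cksaagp":
        dim = len(config.group_scheme) ** 2 * (config.k_max + 1)
        rows = [
            cksaagp(r.sequence, config.k_max, config.group_scheme) for r in records
        ]
    else:
        raise ValueError(f"unknown encoder {encoder!r}")
    return np.stack(rows) if rows else np.zeros((0, dim))
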