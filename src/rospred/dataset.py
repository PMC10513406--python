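"""Dataset-construction pipeline: redundancy reduction and hard negatives.

Mirrors the standard protein-database workflow — cluster near-identical
sequences at a high identity threshold keeping one representative per
cluster (CD-HIT-style greedy incremental clustering), then pick the
negatives that most resemble the positive set so the gate is forced to
learn a sharp boundary — but with self-contained algorithms: a global
alignment identity (match +1, mismatch 0, linear gap −1) and an
alignment-free k-mer cosine similarity in place of external BLAST
scores.

Because several global alignments can share the optimal score while
differing in match count, identity is made canonical: among all
alignments the DP maximizes (score, matches, −alignment_length)
lexicographically, which is well defined because lexicographic order
is preserved under per-column addition.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np

from .sequence_io import LabeledExample, ProteinRecord


class DatasetError(ValueError):
    pass


_NEG_INF = (-(10**9), 0, 0)


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned columns under the canonical
    global alignment (see module docstring).  Symmetric, in [0, 1]."""
    if not a or not b:
        raise DatasetError("cannot align an empty sequence")
    n, m = len(a), len(b)
    # DP over (score, matches, -length) triples, lexicographic max.
    prev = [(-j, 0, -j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(-i, 0, -i)]
        ai = a[i - 1]
        for j in range(1, m + 1):
            match = 1 if ai == b[j - 1] else 0
            d = prev[j - 1]
            diag = (d[0] + match, d[1] + match, d[2] - 1)
            u = prev[j]
            up = (u[0] - 1, u[1], u[2] - 1)
            l = cur[j - 1]
            left = (l[0] - 1, l[1], l[2] - 1)
            best = diag
            if up > best:
                best = up
            if left > best:
                best = left
            cur.append(best)
        prev = cur
    _, matches, neg_len = prev[m]
    return matches / (-neg_len)


@dataclass
class ClusterResult:
    representatives: list[str]
    member_of: dict[str, str]
    threshold: float


def greedy_cluster(
    records: Sequence[ProteinRecord], threshold: float
) -> ClusterResult:
    """CD-HIT-style greedy incremental clustering.

    Records are processed by decreasing length (ties by id); each
    joins the first-founded representative with identity ≥ threshold,
    else founds a new cluster.
    """
    if not 0 < threshold <= 1:
        raise DatasetError("threshold must be in (0, 1]")
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise DatasetError("duplicate record ids")
    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    representatives: list[str] = []
    member_of: dict[str, str] = {}
    for rec in order:
        home = None
        for rep_id in representatives:
            if pairwise_identity(rec.sequence, by_id[rep_id].sequence) >= threshold:
                home = rep_id
                break
        if home is None:
            representatives.append(rec.id)
            member_of[rec.id] = rec.id
        else:
            member_of[rec.id] = home
    return ClusterResult(
        representatives=representatives, member_of=member_of, threshold=threshold
    )


def _kmer_profile(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_similarity(a: str, b: str, k: int = 3) -> float:
    """Cosine similarity between k-mer count profiles, in [0, 1]."""
    if len(a) < k or len(b) < k:
        raise DatasetError(f"sequences must be at least k={k} residues long")
    pa, pb = _kmer_profile(a, k), _kmer_profile(b, k)
    if pa == pb:
        return 1.0
    dot = sum(pa[w] * pb[w] for w in pa.keys() & pb.keys())
    if dot == 0:
        return 0.0
    na = sqrt(sum(c * c for c in pa.values()))
    nb = sqrt(sum(c * c for c in pb.values()))
    return min(dot / (na * nb), 1.0)


@dataclass
class SimilarityRanking:
    """Candidates ordered by best similarity against any positive."""

    score_of: dict[str, float]
    ordering: list[str]  # descending score, ties by id ascending


def rank_by_similarity(
    candidates: Sequence[ProteinRecord],
    positives: Sequence[ProteinRecord],
    k: int = 3,
) -> SimilarityRanking:
    score_of = {
        c.id: max(kmer_similarity(c.sequence, p.sequence, k) for p in positives)
        for c in candidates
    }
    ordering = sorted(score_of, key=lambda cid: (-score_of[cid], cid))
    return SimilarityRanking(score_of=score_of, ordering=ordering)


def mine_hard_negatives(
    candidates: Sequence[ProteinRecord],
    positives: Sequence[ProteinRecord],
    n: int,
    k: int = 3,
) -> tuple[list[ProteinRecord], SimilarityRanking]:
    """Select the n candidates most similar to the positive set."""
    if n > len(candidates):
        raise DatasetError(
            f"requested {n} hard negatives from {len(candidates)} candidates"
        )
    ranking = rank_by_similarity(candidates, positives, k)
    by_id = {c.id: c for c in candidates}
    selected = [by_id[cid] for cid in ranking.ordering[:n]]
    return selected, ranking


def stratified_split(
    dataset: Sequence[LabeledExample],
    test_fraction: float,
    seed: int,
) -> tuple[list[LabeledExample], list[LabeledExample]]:
    """Seeded split stratified jointly on (level-1 label, level-2 class).

    Strata with a single member cannot be split; they are kept in the
    training set and a warning is issued.
    """
    if not 0 < test_fraction < 1:
        raise DatasetError("test_fraction must be in (0, 1)")
    strata: dict[tuple[bool, str | None], list[int]] = {}
    for i, ex in enumerate(dataset):
        strata.setdefault((ex.positive, ex.level2), []).append(i)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for key in sorted(strata, key=str):
        members = strata[key]
        if len(members) < 2:
            warnings.warn(
                f"stratum {key} has a single member; kept in the training set"
            )
            train_idx.extend(members)
            continue
        perm = rng.permutation(len(members))
        n_test = int(round(len(members) * test_fraction))
        n_test = min(max(n_test, 1), len(members) - 1)
        for pos, j in enumerate(perm):
            (test_idx if pos < n_test else train_idx).append(members[j])
    train_idx.sort()
    test_idx.sort()
    return [dataset[i] for i in train_idx], [dataset[i] for i in test_idx]
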