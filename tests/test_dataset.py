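"""Dataset construction: alignment identity vs an independent DP
oracle, greedy clustering, k-mer similarity, hard-negative mining and
the stratified split."""

import numpy as np
import pytest

from rospred import (
    LabeledExample,
    ProteinRecord,
    greedy_cluster,
    kmer_similarity,
    mine_hard_negatives,
    pairwise_identity,
    stratified_split,
)
from rospred.dataset import DatasetError, rank_by_similarity
from conftest import random_records, random_sequence


def oracle_identity(a: str, b: str) -> float:
    """Independent full-table DP over (score, matches, -length)
    lexicographic triples; match +1, mismatch 0, linear gap -1."""
    n, m = len(a), len(b)
    T = [[None] * (m + 1) for _ in range(n + 1)]
    T[0][0] = (0, 0, 0)
    for i in range(1, n + 1):
        T[i][0] = (-i, 0, -i)
    for j in range(1, m + 1):
        T[0][j] = (-j, 0, -j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1 if a[i - 1] == b[j - 1] else 0
            cand = [
                (T[i - 1][j - 1][0] + s, T[i - 1][j - 1][1] + s, T[i - 1][j - 1][2] - 1),
                (T[i - 1][j][0] - 1, T[i - 1][j][1], T[i - 1][j][2] - 1),
                (T[i][j - 1][0] - 1, T[i][j - 1][1], T[i][j - 1][2] - 1),
            ]
            T[i][j] = max(cand)
    _, matches, neg_len = T[n][m]
    return matches / (-neg_len)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKVA", "MKVA") == 1.0

    def test_single_mismatch(self):
        assert pairwise_identity("AAAA", "AAAT") == 0.75

    def test_symmetry_and_oracle_on_random_pairs(self, rng):
        for _ in range(50):
            a = random_sequence(rng, int(rng.integers(1, 31)))
            b = random_sequence(rng, int(rng.integers(1, 31)))
            got = pairwise_identity(a, b)
            assert got == pytest.approx(oracle_identity(a, b), abs=1e-12)
            assert got == pytest.approx(pairwise_identity(b, a), abs=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(DatasetError):
            pairwise_identity("", "MK")


class TestGreedyCluster:
    def _records(self, seqs):
        return [ProteinRecord(id=f"s{i}", sequence=s) for i, s in enumerate(seqs)]

    def test_duplicate_collapsed_distinct_kept(self):
        records = [
            ProteinRecord(id="a", sequence="AAAA"),
            ProteinRecord(id="b", sequence="AAAA"),
            ProteinRecord(id="c", sequence="AAAT"),
        ]
        result = greedy_cluster(records, 0.99)
        reps = {records[0].id, records[2].id}
        assert set(result.representatives) == reps
        assert result.member_of["b"] in {"a"}  # joins the duplicate's cluster

    def test_all_distinct_at_strict_threshold(self, rng):
        records = random_records(rng, 12, min_len=20, max_len=30)
        result = greedy_cluster(records, 1.0)
        assert len(result.representatives) == 12

    def test_threshold_one_equals_set_dedup(self, rng):
        seqs = [random_sequence(rng, 15) for _ in range(6)]
        seqs = seqs + seqs[:3]  # exact duplicates
        records = self._records(seqs)
        result = greedy_cluster(records, 1.0)
        assert len(result.representatives) == len(set(seqs))

    def test_every_representative_maps_to_itself(self, rng):
        records = random_records(rng, 10, min_len=8, max_len=20)
        result = greedy_cluster(records, 0.5)
        for rep in result.representatives:
            assert result.member_of[rep] == rep

    def test_members_meet_threshold_with_representative(self, rng):
        records = random_records(rng, 15, min_len=10, max_len=20)
        result = greedy_cluster(records, 0.4)
        by_id = {r.id: r for r in records}
        for member, rep in result.member_of.items():
            if member != rep:
                assert (
                    pairwise_identity(
                        by_id[member].sequence, by_id[rep].sequence
                    )
                    >= 0.4
                )

    def test_reclustering_representatives_is_fixed_point(self, rng):
        records = random_records(rng, 15, min_len=10, max_len=20)
        result = greedy_cluster(records, 0.5)
        by_id = {r.id: r for r in records}
        again = greedy_cluster([by_id[r] for r in result.representatives], 0.5)
        assert len(again.representatives) == len(result.representatives)

    def test_invalid_threshold(self):
        with pytest.raises(DatasetError):
            greedy_cluster([], 0.0)


class TestKmerSimilarity:
    def test_identical(self):
        assert kmer_similarity("MKVAMKVA", "MKVAMKVA", k=3) == 1.0

    def test_disjoint_profiles(self):
        assert kmer_similarity("AAAA", "TTTT", k=3) == 0.0

    def test_matches_profile_dot_product_oracle(self, rng):
        for _ in range(50):
            a = random_sequence(rng, int(rng.integers(5, 40)))
            b = random_sequence(rng, int(rng.integers(5, 40)))
            # oracle: explicit profile vectors over the union of 3-mers
            kmers = sorted(
                {a[i : i + 3] for i in range(len(a) - 2)}
                | {b[i : i + 3] for i in range(len(b) - 2)}
            )
            va = np.array([sum(a[i : i + 3] == w for i in range(len(a) - 2)) for w in kmers])
            vb = np.array([sum(b[i : i + 3] == w for i in range(len(b) - 2)) for w in kmers])
            denom = np.linalg.norm(va) * np.linalg.norm(vb)
            want = float(va @ vb) / denom if va @ vb else 0.0
            assert kmer_similarity(a, b, k=3) == pytest.approx(want, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(DatasetError):
            kmer_similarity("MK", "MKVA", k=3)


class TestHardNegativeMining:
    def test_near_positive_selected(self):
        positives = [ProteinRecord(id="p", sequence="AAAAAA")]
        candidates = [
            ProteinRecord(id="near", sequence="AAAAAT"),
            ProteinRecord(id="far", sequence="TTTTTT"),
        ]
        selected, ranking = mine_hard_negatives(candidates, positives, 1, k=3)
        assert [r.id for r in selected] == ["near"]
        assert ranking.score_of["near"] > ranking.score_of["far"]

    def test_all_candidates_returned_ranked(self, rng):
        positives = random_records(rng, 3, min_len=10, max_len=20, prefix="p")
        candidates = random_records(rng, 8, min_len=10, max_len=20, prefix="c")
        selected, ranking = mine_hard_negatives(candidates, positives, 8)
        assert [r.id for r in selected] == ranking.ordering
        scores = [ranking.score_of[r.id] for r in selected]
        assert scores == sorted(scores, reverse=True)

    def test_selected_scores_dominate_unselected(self, rng):
        positives = random_records(rng, 3, min_len=15, max_len=25, prefix="p")
        candidates = random_records(rng, 10, min_len=15, max_len=25, prefix="c")
        selected, ranking = mine_hard_negatives(candidates, positives, 4)
        chosen = {r.id for r in selected}
        worst_chosen = min(ranking.score_of[c] for c in chosen)
        for cid in set(ranking.score_of) - chosen:
            assert ranking.score_of[cid] <= worst_chosen

    def test_equal_scores_tie_broken_by_id(self):
        positives = [ProteinRecord(id="p", sequence="MKVAMKVA")]
        candidates = [
            ProteinRecord(id="b", sequence="WWWWWW"),
            ProteinRecord(id="a", sequence="HHHHHH"),
        ]
        ranking = rank_by_similarity(candidates, positives)
        assert ranking.ordering == ["a", "b"]  # both score 0.0

    def test_overdraw_rejected(self):
        positives = [ProteinRecord(id="p", sequence="MKVAMKVA")]
        with pytest.raises(DatasetError):
            mine_hard_negatives([], positives, 1)


class TestStratifiedSplit:
    def _dataset(self, rng, per_class=20, classes=5):
        data = []
        for c in range(classes):
            for i in range(per_class):
                rec = ProteinRecord(
                    id=f"c{c}_{i}", sequence=random_sequence(rng, 20)
                )
                data.append(
                    LabeledExample(record=rec, positive=True, level2=f"class{c}")
                )
        return data

    def test_per_class_test_counts(self, rng):
        data = self._dataset(rng)
        train, test = stratified_split(data, 0.2, seed=1)
        assert len(test) == 20
        for c in range(5):
            assert sum(ex.level2 == f"class{c}" for ex in test) == 4

    def test_same_seed_identical_partition(self, rng):
        data = self._dataset(rng)
        s1 = stratified_split(data, 0.2, seed=7)
        s2 = stratified_split(data, 0.2, seed=7)
        assert s1 == s2

    def test_union_and_disjointness(self, rng):
        data = self._dataset(rng, per_class=7, classes=3)
        train, test = stratified_split(data, 0.3, seed=2)
        ids_train = {ex.record.id for ex in train}
        ids_test = {ex.record.id for ex in test}
        assert not ids_train & ids_test
        assert ids_train | ids_test == {ex.record.id for ex in data}

    def test_singleton_stratum_warned_and_kept_in_train(self, rng):
        data = self._dataset(rng, per_class=5, classes=2)
        lone = LabeledExample(
            record=ProteinRecord(id="lone", sequence=random_sequence(rng, 20)),
            positive=False,
        )
        with pytest.warns(UserWarning, match="single member"):
            train, test = stratified_split(data + [lone], 0.2, seed=3)
        assert any(ex.record.id == "lone" for ex in train)

    def test_invalid_fraction(self):
        with pytest.raises(DatasetError):
            stratified_split([], 0.0, seed=1)
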