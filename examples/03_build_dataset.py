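"""Dataset construction: identity clustering and hard-negative mining.

Near-identical sequences are collapsed at a 99% global-alignment
identity threshold (one representative per cluster, CD-HIT style);
negatives are then ranked by k-mer cosine similarity against the
positive set and the most positive-like ones kept, forcing the gate
to learn a sharp boundary.
"""

from rospred import (
    ProteinRecord,
    greedy_cluster,
    mine_hard_negatives,
    pairwise_identity,
)

base = "MKVLWAALLVTFLAGCQAKVEQAVETEPAVLFKAGDLWWHHKRPLVAAGE"
records = [
    ProteinRecord(id="orig", sequence=base),
    ProteinRecord(id="copy", sequence=base),                 # exact duplicate
    ProteinRecord(id="one_sub", sequence="A" + base[1:]),    # 98% identical
    ProteinRecord(id="distant", sequence=base[::-1]),
]
result = greedy_cluster(records, threshold=0.99)
print(f"{len(records)} records -> {len(result.representatives)} representatives "
      f"at 99% identity: {result.representatives}")
print("identity(orig, one_sub) =",
      round(pairwise_identity(base, "A" + base[1:]), 3))

positives = [ProteinRecord(id="pos", sequence=base)]
candidates = [
    ProteinRecord(id="near_positive", sequence=base[:30] + "GGGGGGGGGG"),
    ProteinRecord(id="unrelated", sequence="PYNQSTCDEDE" * 4),
]
selected, ranking = mine_hard_negatives(candidates, positives, n=1, k=3)
print("\nhard-negative scores (3-mer cosine vs the positive set):")
for cid in ranking.ordering:
    print(f"  {cid}: {ranking.score_of[cid]:.3f}")
print("selected as hard negative:", selected[0].id)
# The candidate sharing a 30-residue prefix with the positive scores
# far higher and is the one kept for training.
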