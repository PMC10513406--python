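"""Encode one sequence into the three feature views.

The same protein is shown as (i) frequency-ranked integer tokens for
the convolutional network, (ii) the CKSAAP residue-pair composition
for the boosted trees, and (iii) the CKSAAGP group-pair composition
for the feed-forward net.
"""

import numpy as np

from rospred import (
    ProteinRecord,
    build_vocabulary,
    cksaagp,
    cksaap,
    encode_tokens,
)
from rospred.encoders import cksaap_feature_names

records = [
    ProteinRecord(id="demo1", sequence="MKVLWAALLVTFLAGCQAKVEQAVET"),
    ProteinRecord(id="demo2", sequence="EPAVLFKAGDLWWHH"),
]

vocab = build_vocabulary(records)
tokens = encode_tokens(records[0], vocab, pad_length=30)
print("token row (rank 1 = most frequent residue in the corpus):")
print(tokens)

ap = cksaap(records[0].sequence, k_max=5)
names = cksaap_feature_names(5)
top = np.argsort(ap)[::-1][:5]
print(f"\nCKSAAP: {ap.size} features; top pairs "
      "(pair|spacing -> fraction of pairs at that spacing):")
for i in top:
    print(f"  {names[i]} -> {ap[i]:.3f}")

gp = cksaagp(records[0].sequence, k_max=5)
print(f"\nCKSAAGP: {gp.size} features; each 25-feature spacing block "
      f"sums to {gp[:25].sum():.3f} (1.0 when no ambiguous residues)")
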