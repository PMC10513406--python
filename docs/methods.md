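# Methods

## The classification model

`rospred` treats ROS-scavenging-enzyme annotation as a two-stage
decision.  Stage one is a binary gate (ROSes vs non-ROSes) formed by
hard-voting three component classifiers; stage two assigns an enzyme
family to gated-positive sequences by soft-voting the same three
algorithm families retrained on positives only.  The design premise
is heterogeneity: the three components see different representations
of the sequence (raw token order, residue-pair composition,
group-pair composition) and use different inductive biases
(convolution + attention, shallow dense net, boosted axis-aligned
trees), so their errors are only weakly correlated and a majority or
averaged vote suppresses individual failure modes.  The vote is
deliberately simple — no stacking, no learned weights, no calibration
— and the gate is strict: a sequence rejected at level 1 is never
scored at level 2, so the sentinel class `non-ROSes` and a concrete
family are mutually exclusive by construction.

Assumptions worth stating explicitly:

* the component probability outputs are treated as comparable enough
  to average without calibration;
* the level-1 vote of each component is its probability argmax, i.e.
  a 0.5 threshold — no component-specific operating point is tuned;
* soft-vote ties are broken by the lowest class index in the fixed
  class order, so prediction is deterministic even in degenerate
  cases.

## Feature encoders

**Tokens.**  Characters are ranked by descending corpus frequency
(ties broken lexicographically), mapped to integers 1…N, truncated or
post-padded with 0 to a fixed length L.  The vocabulary is built from
the training corpus only; characters unseen at training time encode
as the rank of `X`.  Sequences are normalized to a 23-letter alphabet
(20 standard residues + X/B/Z; U→C, O→K, anything else →X, with
substitution counts reported).

**CKSAAP.**  For spacing k, the ordered pair (a,b) at positions
(i, i+k+1) is counted and divided by the number of position pairs at
that spacing, L−k−1.  Pairs touching an ambiguous residue (X/B/Z)
count toward the denominator but no cell, so each 400-feature block
sums to 1 minus the ambiguous mass.  Default k_max = 5 (2,400
features), the common convention for this descriptor family.

**CKSAAGP.**  The same statistic over the conventional five
physicochemical groups — aliphatic {G,A,V,L,M,I}, aromatic {F,Y,W},
positively charged {K,R,H}, negatively charged {D,E}, uncharged polar
{S,T,C,P,N,Q} — giving 25 ordered group pairs per spacing (150
features).  No gap-penalty term beyond the spacing itself is applied;
the descriptor's name sometimes suggests one, but no standard
definition exists and the spacing already encodes the gap.  The
group descriptor is algebraically the residue descriptor aggregated
through the partition, and the test suite asserts that identity.

The encoder default pad length is 1,000 residues, generous for
typical enzymes; the pipeline configuration used for the synthetic
benchmark sets it to the benchmark's maximum sequence length (200),
which loses nothing and keeps the convolution stack small.

## Component models

**CNN** (`_nn.py`, pure NumPy with hand-written backpropagation):
trainable embedding (dim 64) → three valid-padding 1-D convolutions
(64 filters, kernel widths 3/5/7, ReLU) → single-head scaled
dot-product self-attention with a residual connection → global max
pooling → linear softmax head.  Adam (lr 1e-3), batch 32, 20 epochs,
cross-entropy.  The attention layer sits after the convolution
stack, consistent with listing it last in the layer inventory; the
residual connection is a stability choice.  All parameters are
float32; training is a pure function of the seed on a given machine.

**FFNN** (scikit-learn `MLPClassifier` behind the module surface):
hidden widths 16/8/4 — the narrow descending pattern of the
reference four-layer design — with the input layer sized to the
actual CKSAAGP dimension and the output to the number of classes.
(A printed input width of 20 cannot carry a 150-dimensional
descriptor; sizing to the data is the only consistent reading.)
Full-batch SGD, constant lr 0.01, cross-entropy.  Two departures
from the initial design proved necessary: raw CKSAAGP fractions live
on a ~0.04 scale and full-batch SGD on them collapses to the
majority class, so a `StandardScaler` precedes the net; and 100
epochs underfits (≈0.92 training accuracy on the benchmark gate
task), so the default is 600 epochs.

**GBT** (xgboost): learning rate 0.1, max depth 20, 150 rounds,
γ = 0, subsample 0.9 — the reference hyperparameters, kept verbatim.
Persistence and prediction go through the raw `Booster` so that a
freshly trained and a reloaded model share one prediction path and
round-trip bit-identically.

All three expose the same contract: `predict_proba` rows sum to 1
within 1e-6, class order is fixed and serialized, and
`load(save(m))` reproduces probabilities exactly.  No class
reweighting is applied anywhere; the dataset builder controls the
negative:positive ratio instead.

## Dataset construction

Redundancy reduction is greedy incremental clustering in decreasing
length order (ties by id): a sequence joins the first-founded
representative with identity ≥ the threshold (default 0.99), else
founds a cluster — the CD-HIT processing order without its k-mer
prefilter, exact rather than heuristic.  Identity comes from global
alignment with match +1, mismatch 0, linear gap −1.  Because
co-optimal alignments can disagree on match counts, identity is made
canonical: the DP maximizes (score, matches, −alignment length)
lexicographically, which is well defined since lexicographic order
is preserved under per-column addition.  Identity = matches /
alignment length.

Hard negatives are mined by scoring each candidate with its best
k-mer-profile cosine similarity (k = 3, the smallest protein word
with usable specificity) against any positive, then keeping the
top-n with ties broken by id.  This is an alignment-free stand-in
for similarity-ranked negative selection; it preserves the property
that matters — the retained negatives are the ones most likely to be
confused with positives — without external binaries or E-value
semantics.

The stratified split is seeded, stratifies jointly on (gate label,
family), and reports singleton strata with a warning while keeping
them in training, so rare families never abort a build.

## The synthetic benchmark

The generator emulates the statistical shape of a curated enzyme
corpus: several positive families of deliberately unequal size
(real family sizes are heavily skewed), each defined by a distinct
implanted motif; background negatives drawn uniformly over the 20
standard residues; and a share of hard negatives carrying only the
first half of a randomly chosen family motif, sitting close to the
decision boundary while remaining learnably negative.

Defaults, chosen once as realistic study conditions: 5 families with
sizes 120/90/60/45/25 (340 positives), negative:positive ratio 1.8
(mirroring the ~60k:34k imbalance typical of mined negative sets),
sequence lengths 80–200, per-residue mutation rate 0.05 on the
implanted motif, hard-negative fraction 0.3, seed 42.  The five
default motifs are 10-mers with distinct physicochemical-group
signatures (aromatic-, positive-, negative-charged, aliphatic,
polar runs) so that every feature view — token order, residue
pairs, group pairs — carries class signal.

What the benchmark does *not* emulate: real amino-acid background
composition, phylogenetic correlation between sequences, multi-domain
architecture, and motif degeneracy beyond point substitution.
Passing the end-to-end recovery test therefore shows the machinery is
correct and the ensemble can learn motif-defined family structure at
realistic imbalance; it does not certify accuracy on real enzyme
corpora.

At mutation rate 0 a nearest-motif substring oracle classifies every
positive perfectly; the test suite uses this as the ceiling against
which trained models are sanity-checked.

## Numerical and degenerate-input choices

* Zero-denominator metrics (precision with no positive predictions,
  recall for an empty class) are reported as absent with a warning,
  never coerced to 0.
* Probability rows are validated to 1e-6; per-spacing descriptor
  blocks to 1e-9.
* Sequences too short to admit a pair at some spacing k raise an
  error naming k; in batch prediction such records yield per-record
  error entries and never abort the batch.
* All randomness flows from explicit integer seeds; per-model seeds
  are derived deterministically from the run seed.

## Problem sizes

The default test suite trains the full hierarchy twice on the
340-positive benchmark (once for recovery, once to confirm
byte-identical reruns) and completes in about two minutes on one
CPU; the acceptance script is a single training run, under one
minute.  These sizes were picked so the whole evaluation cycle stays
interactive while keeping class imbalance and family-size skew at
the levels described above.

## Known limitations

* The CNN is a minimal NumPy implementation: single attention head,
  no layer normalization, no dropout, no early stopping, CPU only.
  It is adequate for the benchmark scale; very long sequences
  (pad length ≫ 1,000) make the attention matrix the dominant cost.
* Greedy clustering is O(n²) alignments with quadratic DP inside —
  exact but not suitable for hundred-thousand-sequence corpora.
* Determinism guarantees are per-machine (BLAS reduction order can
  differ across builds), which is the standard caveat for seeded
  numerical training.
* The ensemble offers no rejection option beyond the binary gate and
  no probability calibration; downstream users should treat the
  soft-vote probabilities as scores, not frequencies.
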