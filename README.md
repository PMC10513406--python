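# rospred

Hierarchical ensemble classification of reactive-oxygen-species
(ROS) scavenging enzymes from protein sequence.

Microbes neutralize ROS — superoxide anion, hydrogen peroxide,
hydroxyl radical, singlet oxygen — with a diverse repertoire of
scavenging enzymes (catalases, peroxidases, thioredoxin reductases,
…).  Annotating these enzymes from sequence alone is hard: the
families share no single diagnostic motif and alignment-based
transfer fails for remote homologs.  `rospred` is a library (plus a
thin CLI) for people who want to build and evaluate such annotators:
it implements a two-level ensemble classifier, the dataset
construction pipeline around it, and a fully synthetic benchmark so
that every stage is testable without downloading anything.

## The method

Prediction is hierarchical.  For a query sequence *x*:

1. **Level 1 (gate).**  Three heterogeneous classifiers each cast a
   binary vote *v_k(x) ∈ {ROSes, non-ROSes}*, and the gate decision
   is the hard majority vote (2-of-3).  The components differ in both
   algorithm and feature view:
   * **CNN** — embedding of frequency-ranked residue tokens, three
     1-D convolutions, single-head scaled-dot-product self-attention,
     global max pooling, softmax head (Adam, cross-entropy);
   * **FFNN** — four-layer feed-forward net (ReLU, full-batch SGD,
     cross-entropy) on the CKSAAGP descriptor: the composition of
     k-spaced amino-acid *group* pairs, 25 ordered pairs of the five
     physicochemical groups per spacing k = 0…5 (150 features);
   * **GBT** — gradient-boosted trees (learning rate 0.1, depth 20,
     150 rounds, γ = 0, subsample 0.9) on the CKSAAP descriptor: the
     composition of k-spaced amino-acid pairs, 400 ordered residue
     pairs per spacing (2,400 features).

   For each spacing k, CKSAAP(a,b,k) = N(a,b,k) / (L − k − 1), the
   fraction of position pairs (i, i+k+1) holding residues (a, b).

2. **Level 2 (class).**  Only if the gate accepts, the three level-2
   models' class-probability vectors are soft-voted — averaged
   unweighted, argmax of the mean — to assign one of the enzyme
   families.  Rejected sequences receive the sentinel `non-ROSes`
   and no level-2 probabilities are computed.

Around the classifier the package provides the standard corpus
workflow: greedy identity clustering at a 99% global-alignment
identity threshold (one representative per cluster), hard-negative
mining by ranking candidate negatives on k-mer cosine similarity to
the positive set, stratified train/test splitting, binary and
per-class metrics, and the three-method correctness Venn attribution.

## Worked example

`examples/04_train_and_predict.py` generates a 3-family synthetic
benchmark (140 positives, 252 negatives), trains the full hierarchy
and scores the held-out 20%:

```
held-out gate accuracy (ROSes vs non-ROSes): 0.987
held-out family accuracy over true positives: 0.964

example prediction for pos_family1_3:
  component votes (cnn, ffnn, gbt): ['pos', 'pos', 'pos']
  gate decision: ROSes
  soft-voted family: family1
  averaged family probabilities: [0.997, 0.001, 0.001]
```

The gate accuracy is the fraction of held-out sequences whose
ROSes/non-ROSes decision is right; family accuracy is measured over
the true positives only, so a gate false negative counts against it.
The near-one-hot averaged probabilities say all three level-2 models
agree on the family.  The other scripts in `examples/` walk the
remaining capabilities: benchmark simulation, feature encoding,
dataset construction, and evaluation/Venn attribution.

The same workflow is scriptable from a shell:

```sh
rospred simulate --out sim
rospred build-dataset --fasta sim/sequences.fasta --labels sim/labels.tsv --out ds
rospred train --fasta ds/train.fasta --labels ds/train.labels.tsv --out bundle
rospred predict --bundle bundle --fasta ds/test.fasta --out predictions.tsv
rospred evaluate --predictions predictions.tsv --truth ds/test.labels.tsv --out metrics.json
```

## Layout

* `src/rospred/sequence_io.py` — FASTA / label-TSV / prediction-TSV,
  23-letter alphabet normalization
* `src/rospred/encoders.py` — tokenization, CKSAAP, CKSAAGP
* `src/rospred/component_models.py`, `src/rospred/_nn.py` — the three
  classifiers behind one probability contract
* `src/rospred/ensemble.py` — hard/soft voting, two-level train and
  predict, bundle persistence
* `src/rospred/dataset.py` — identity clustering, hard-negative
  mining, stratified split
* `src/rospred/synthetic.py` — benchmark generator
* `src/rospred/evaluation.py` — metrics and Venn attribution
* `docs/methods.md` — model assumptions, parameter choices, known
  limitations
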