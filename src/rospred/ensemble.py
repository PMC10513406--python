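"""Two-level hierarchical ensemble.

Level 1 gates a sequence as a ROS-scavenging enzyme (ROSes) or not by
a hard 2-of-3 majority vote of the three component classifiers, each
voting its probability argmax.  Sequences that pass the gate are
assigned a ROSes class at level 2 by soft voting: the three level-2
models' class-probability vectors are averaged unweighted and the
argmax of the mean wins (ties broken by the lowest class index).
Gated-negative sequences receive the sentinel class and no level-2
probabilities are ever computed for them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .component_models import (
    CnnConfig,
    ComponentModel,
    FfnnConfig,
    GbtConfig,
    ModelError,
    train_cnn,
    train_ffnn,
    train_gbt,
)
from .encoders import (
    EncoderConfig,
    EncoderError,
    TokenVocabulary,
    build_vocabulary,
    cksaagp,
    cksaap,
    encode_token_matrix,
)
from .sequence_io import NEGATIVE_SENTINEL, LabeledExample, ProteinRecord

#: fixed order in which the three kinds vote
KIND_ORDER = ("cnn", "ffnn", "gbt")

LEVEL1_CLASSES = [NEGATIVE_SENTINEL, "ROSes"]


class EnsembleError(ValueError):
    pass


def hard_vote(votes: Sequence[bool]) -> bool:
    """Strict 2-of-3 majority of binary votes."""
    if len(votes) != 3:
        raise EnsembleError(f"hard_vote needs exactly 3 votes, got {len(votes)}")
    return sum(bool(v) for v in votes) >= 2


def soft_vote(
    prob_rows: Sequence[np.ndarray], class_names: Sequence[str]
) -> tuple[str, np.ndarray]:
    """Unweighted mean of three probability vectors; argmax of the mean.

    Ties go to the lowest class index.  Inputs must be normalized
    within 1e-6.
    """
    if len(prob_rows) != 3:
        raise EnsembleError(f"soft_vote needs exactly 3 rows, got {len(prob_rows)}")
    rows = [np.asarray(r, dtype=np.float64) for r in prob_rows]
    n = len(class_names)
    for r in rows:
        if r.shape != (n,):
            raise EnsembleError(
                f"probability row of length {r.shape} does not match "
                f"{n} classes"
            )
        if abs(r.sum() - 1.0) > 1e-6 or (r < 0).any():
            raise EnsembleError("probability row is not normalized")
    mean = np.mean(rows, axis=0)
    return class_names[int(np.argmax(mean))], mean


@dataclass(frozen=True)
class HierarchicalPrediction:
    """One record's gate votes, decision and (if positive) class."""

    id: str
    level1_votes: tuple[bool, bool, bool]  # cnn, ffnn, gbt
    positive: bool
    level2_class: str
    level2_probabilities: tuple[float, ...] | None

    def __post_init__(self) -> None:
        if self.positive != (sum(self.level1_votes) >= 2):
            raise EnsembleError("decision does not match the majority of votes")
        if not self.positive and self.level2_class != NEGATIVE_SENTINEL:
            raise EnsembleError("negative decision must carry the sentinel class")
        if not self.positive and self.level2_probabilities is not None:
            raise EnsembleError("negative decision must carry no probabilities")
        if self.positive and self.level2_class == NEGATIVE_SENTINEL:
            raise EnsembleError("positive decision cannot carry the sentinel")


@dataclass(frozen=True)
class PredictionError:
    id: str
    message: str


@dataclass
class BatchPredictionResult:
    predictions: list[HierarchicalPrediction]
    errors: list[PredictionError] = field(default_factory=list)


@dataclass(frozen=True)
class ModelConfigs:
    cnn: CnnConfig = CnnConfig()
    ffnn: FfnnConfig = FfnnConfig()
    gbt: GbtConfig = GbtConfig()

    def reseeded(self, seed: int) -> "ModelConfigs":
        """Derive distinct per-model seeds from one base seed."""
        from dataclasses import replace

        return ModelConfigs(
            cnn=replace(self.cnn, seed=(seed * 6 + 1) % (2**31)),
            ffnn=replace(self.ffnn, seed=(seed * 6 + 2) % (2**31)),
            gbt=replace(self.gbt, seed=(seed * 6 + 3) % (2**31)),
        )


@dataclass
class EnsembleBundle:
    """Everything needed to predict: 3+3 models, vocabulary, encoder config."""

    level1_models: dict[str, ComponentModel]
    level2_models: dict[str, ComponentModel]
    vocab: TokenVocabulary
    encoder_config: EncoderConfig
    class_names: list[str]

    def __post_init__(self) -> None:
        for level, models in (("1", self.level1_models), ("2", self.level2_models)):
            if tuple(models) != KIND_ORDER:
                raise EnsembleError(
                    f"level-{level} models must be exactly {KIND_ORDER}"
                )
        for m in self.level2_models.values():
            if m.classes != self.class_names:
                raise EnsembleError("level-2 models disagree on the class set")

    # ----------------------------------------------------------- persistence

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for kind, model in self.level1_models.items():
            model.save(directory / f"level1_{kind}")
        for kind, model in self.level2_models.items():
            model.save(directory / f"level2_{kind}")
        meta = {
            "format_version": 1,
            "class_names": self.class_names,
            "vocab": self.vocab.to_dict(),
            "encoder_config": {
                "k_max": self.encoder_config.k_max,
                "pad_length": self.encoder_config.pad_length,
                "group_scheme": dict(self.encoder_config.group_scheme),
            },
        }
        (directory / "ensemble.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleBundle":
        directory = Path(directory)
        meta = json.loads((directory / "ensemble.json").read_text())
        enc = meta["encoder_config"]
        return cls(
            level1_models={
                k: ComponentModel.load(directory / f"level1_{k}") for k in KIND_ORDER
            },
            level2_models={
                k: ComponentModel.load(directory / f"level2_{k}") for k in KIND_ORDER
            },
            vocab=TokenVocabulary.from_dict(meta["vocab"]),
            encoder_config=EncoderConfig(
                k_max=enc["k_max"],
                pad_length=enc["pad_length"],
                group_scheme=enc["group_scheme"],
            ),
            class_names=list(meta["class_names"]),
        )


def _encode_all(
    records: Sequence[ProteinRecord],
    vocab: TokenVocabulary,
    config: EncoderConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tokens = encode_token_matrix(records, vocab, config.pad_length)
    gp = np.stack(
        [cksaagp(r.sequence, config.k_max, config.group_scheme) for r in records]
    )
    ap = np.stack([cksaap(r.sequence, config.k_max) for r in records])
    return tokens, gp, ap


def train_hierarchy(
    dataset: Sequence[LabeledExample],
    encoder_config: EncoderConfig | None = None,
    model_configs: ModelConfigs | None = None,
    seed: int = 0,
) -> EnsembleBundle:
    """Train the full two-level ensemble.

    Level-1 models see every example with a binary target; level-2
    models see the positive examples only, targeting their class.
    The token vocabulary is built from the training sequences only.
    """
    if not dataset:
        raise EnsembleError("empty training dataset")
    encoder_config = encoder_config or EncoderConfig()
    configs = (model_configs or ModelConfigs()).reseeded(seed)

    records = [ex.record for ex in dataset]
    positives = [ex for ex in dataset if ex.positive]
    class_names = sorted({ex.level2 for ex in positives})
    if len(class_names) < 2:
        raise EnsembleError(
            "training data must contain positives from at least 2 classes"
        )

    vocab = build_vocabulary(records)
    tokens, gp, ap = _encode_all(records, vocab, encoder_config)
    y1 = [LEVEL1_CLASSES[1] if ex.positive else LEVEL1_CLASSES[0] for ex in dataset]

    pos_idx = [i for i, ex in enumerate(dataset) if ex.positive]
    y2 = [dataset[i].level2 for i in pos_idx]

    level1 = {
        "cnn": train_cnn(tokens, y1, configs.cnn, LEVEL1_CLASSES,
                         vocab_size=vocab.max_index),
        "ffnn": train_ffnn(gp, y1, configs.ffnn, LEVEL1_CLASSES),
        "gbt": train_gbt(ap, y1, configs.gbt, LEVEL1_CLASSES),
    }
    level2 = {
        "cnn": train_cnn(tokens[pos_idx], y2, configs.cnn, class_names,
                         vocab_size=vocab.max_index),
        "ffnn": train_ffnn(gp[pos_idx], y2, configs.ffnn, class_names),
        "gbt": train_gbt(ap[pos_idx], y2, configs.gbt, class_names),
    }
    return EnsembleBundle(
        level1_models=level1,
        level2_models=level2,
        vocab=vocab,
        encoder_config=encoder_config,
        class_names=class_names,
    )


def predict_hierarchical(
    bundle: EnsembleBundle, records: Sequence[ProteinRecord]
) -> BatchPredictionResult:
    """Predict a batch; per-record encoder failures never abort the batch."""
    result = BatchPredictionResult(predictions=[])
    valid: list[ProteinRecord] = []
    for rec in records:
        try:
            cksaagp(rec.sequence, bundle.encoder_config.k_max,
                    bundle.encoder_config.group_scheme)
        except EncoderError as exc:
            result.errors.append(PredictionError(id=rec.id, message=str(exc)))
            continue
        valid.append(rec)
    if not valid:
        return result

    tokens, gp, ap = _encode_all(valid, bundle.vocab, bundle.encoder_config)
    inputs = {"cnn": tokens, "ffnn": gp, "gbt": ap}

    pos_index = LEVEL1_CLASSES.index("ROSes")
    votes_by_kind = {
        kind: bundle.level1_models[kind].predict_proba(inputs[kind]).argmax(axis=1)
        == pos_index
        for kind in KIND_ORDER
    }
    decisions = [
        hard_vote([votes_by_kind[k][i] for k in KIND_ORDER])
        for i in range(len(valid))
    ]

    gated = [i for i, d in enumerate(decisions) if d]
    level2_probs: dict[int, tuple[str, np.ndarray]] = {}
    if gated:
        probs_by_kind = {
            kind: bundle.level2_models[kind].predict_proba(inputs[kind][gated])
            for kind in KIND_ORDER
        }
        for j, i in enumerate(gated):
            rows = [probs_by_kind[k][j] for k in KIND_ORDER]
            level2_probs[i] = soft_vote(rows, bundle.class_names)

    for i, rec in enumerate(valid):
        votes = tuple(bool(votes_by_kind[k][i]) for k in KIND_ORDER)
        if decisions[i]:
            cls, mean = level2_probs[i]
            pred = HierarchicalPrediction(
                id=rec.id,
                level1_votes=votes,
                positive=True,
                level2_class=cls,
                level2_probabilities=tuple(float(x) for x in mean),
            )
        else:
            pred = HierarchicalPrediction(
                id=rec.id,
                level1_votes=votes,
                positive=False,
                level2_class=NEGATIVE_SENTINEL,
                level2_probabilities=None,
            )
        result.predictions.append(pred)
    return result
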