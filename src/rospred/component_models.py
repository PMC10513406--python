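"""The three component classifiers behind one probability contract.

Every trained model, whatever its kind, exposes ``predict_proba`` rows
that are non-negative and sum to 1, an ordered ``classes`` list whose
argmax defines the model's hard vote, and a directory-based
``save``/``load`` round trip that reproduces predictions exactly.

Kinds:

* ``cnn``  — convolutional network with self-attention on integer
  token rows (see :mod:`rospred._nn`);
* ``ffnn`` — feed-forward network (ReLU, SGD, cross-entropy) on
  CKSAAGP group-pair features;
* ``gbt``  — gradient-boosted trees on CKSAAP features, with the
  reference hyperparameters (learning rate 0.1, depth 20, 150
  rounds, gamma 0, subsample 0.9).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
import xgboost as xgb
from xgboost import XGBClassifier

from ._nn import ConvAttentionConfig, ConvAttentionNet

FORMAT_VERSION = 1


class _BoosterWrapper:
    """Predict through the raw Booster so that freshly trained and
    reloaded boosted-tree models share one prediction path."""

    def __init__(self, booster: "xgb.Booster", n_classes: int):
        self.booster = booster
        self.n_classes = n_classes

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        raw = self.booster.predict(xgb.DMatrix(X), validate_features=False)
        if raw.ndim == 1:  # binary objective emits p(class 1)
            raw = np.column_stack([1.0 - raw, raw])
        return raw.astype(np.float64)

CnnConfig = ConvAttentionConfig


@dataclass(frozen=True)
class FfnnConfig:
    """Feed-forward net settings; hidden widths follow the narrow
    descending 16/8/4 pattern of the reference four-layer design,
    with input sized to the descriptor and output to n_classes."""

    hidden_dims: tuple[int, ...] = (16, 8, 4)
    epochs: int = 600
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_dims or any(h <= 0 for h in self.hidden_dims):
            raise ValueError("hidden_dims must be positive")
        if list(self.hidden_dims) != sorted(self.hidden_dims, reverse=True):
            raise ValueError("hidden_dims must be descending")


@dataclass(frozen=True)
class GbtConfig:
    learning_rate: float = 0.1
    max_depth: int = 20
    n_estimators: int = 150
    gamma: float = 0.0
    subsample: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.max_depth, self.n_estimators) <= 0:
            raise ValueError("learning_rate, max_depth, n_estimators must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be ≥ 0")
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample must be in (0, 1]")


class ModelError(ValueError):
    """Invalid training data or model state."""


def _encode_labels(
    labels: Sequence, class_names: Sequence[str] | None
) -> tuple[np.ndarray, list[str]]:
    labels = [str(x) for x in labels]
    if len(labels) == 0:
        raise ModelError("empty training set")
    present = sorted(set(labels))
    if class_names is None:
        classes = present
    else:
        classes = [str(c) for c in class_names]
        missing = set(classes) - set(present)
        if missing:
            raise ModelError(f"declared classes absent from training data: {sorted(missing)}")
    if len(classes) < 2:
        raise ModelError("training data must contain at least 2 classes")
    index = {c: i for i, c in enumerate(classes)}
    try:
        y = np.array([index[x] for x in labels], dtype=np.int64)
    except KeyError as exc:
        raise ModelError(f"label {exc} not in declared classes") from exc
    return y, classes


class ComponentModel:
    """A trained classifier of one of the three kinds."""

    def __init__(self, kind: str, feature_spec: str, classes: list[str],
                 config, inner, input_dim: int):
        self.kind = kind
        self.feature_spec = feature_spec
        self.classes = classes
        self.config = config
        self.inner = inner
        self.input_dim = input_dim

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def predict_proba(self, inputs: np.ndarray) -> np.ndarray:
        inputs = np.asarray(inputs)
        if inputs.ndim != 2 or inputs.shape[1] != self.input_dim:
            raise ModelError(
                f"{self.kind}: expected input of shape (n, {self.input_dim}), "
                f"got {inputs.shape}"
            )
        if inputs.shape[0] == 0:
            return np.zeros((0, self.n_classes))
        if self.kind == "cnn":
            probs = self.inner.predict_proba(inputs.astype(np.int64))
        else:
            probs = np.asarray(self.inner.predict_proba(inputs), dtype=np.float64)
        return probs

    def predict(self, inputs: np.ndarray) -> list[str]:
        probs = self.predict_proba(inputs)
        return [self.classes[i] for i in probs.argmax(axis=1)]

    # ----------------------------------------------------------- persistence

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": FORMAT_VERSION,
            "kind": self.kind,
            "feature_spec": self.feature_spec,
            "classes": self.classes,
            "input_dim": self.input_dim,
            "config": asdict(self.config),
            "seed": self.config.seed,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
        if self.kind == "cnn":
            np.savez(directory / "params.npz", **self.inner.state_arrays())
        elif self.kind == "ffnn":
            joblib.dump(self.inner, directory / "model.joblib")
        else:
            self.inner.booster.save_model(directory / "model.ubj")

    @classmethod
    def load(cls, directory: str | Path) -> "ComponentModel":
        directory = Path(directory)
        meta_path = directory / "metadata.json"
        if not meta_path.exists():
            raise ModelError(f"no metadata.json in {directory}")
        try:
            meta = json.loads(meta_path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelError(f"corrupt metadata in {directory}: {exc}") from exc
        if meta.get("format_version") != FORMAT_VERSION:
            raise ModelError(
                f"unsupported model format version {meta.get('format_version')!r}"
            )
        kind = meta["kind"]
        classes = list(meta["classes"])
        cfg_dict = dict(meta["config"])
        if kind == "cnn":
            cfg_dict["kernel_widths"] = tuple(cfg_dict["kernel_widths"])
            config = CnnConfig(**cfg_dict)
            arrays = dict(np.load(directory / "params.npz"))
            vocab_size = arrays["E"].shape[0] - 1
            inner = ConvAttentionNet.from_state(
                vocab_size, len(classes), config, arrays
            )
        elif kind == "ffnn":
            cfg_dict["hidden_dims"] = tuple(cfg_dict["hidden_dims"])
            config = FfnnConfig(**cfg_dict)
            inner = joblib.load(directory / "model.joblib")
        elif kind == "gbt":
            config = GbtConfig(**cfg_dict)
            booster = xgb.Booster()
            booster.load_model(str(directory / "model.ubj"))
            inner = _BoosterWrapper(booster, len(classes))
        else:
            raise ModelError(f"unknown model kind {kind!r}")
        return cls(kind, meta["feature_spec"], classes, config,
                   inner, meta["input_dim"])


def train_cnn(
    tokens: np.ndarray,
    labels: Sequence,
    config: CnnConfig | None = None,
    class_names: Sequence[str] | None = None,
    vocab_size: int | None = None,
) -> ComponentModel:
    """Fit the conv/attention net on integer token rows.

    ``vocab_size`` defaults to the largest token index observed.
    Deterministic for a fixed config seed.
    """
    config = config or CnnConfig()
    tokens = np.asarray(tokens, dtype=np.int64)
    if tokens.ndim != 2 or tokens.shape[0] == 0:
        raise ModelError("tokens must be a non-empty (n, L) integer matrix")
    y, classes = _encode_labels(labels, class_names)
    if len(y) != tokens.shape[0]:
        raise ModelError("labels not aligned to token rows")
    if vocab_size is None:
        vocab_size = int(tokens.max())
    net = ConvAttentionNet(vocab_size, len(classes), config)
    net.fit(tokens, y)
    return ComponentModel("cnn", "tokens", classes, config, net, tokens.shape[1])


def train_ffnn(
    features: np.ndarray,
    labels: Sequence,
    config: FfnnConfig | None = None,
    class_names: Sequence[str] | None = None,
) -> ComponentModel:
    """Fit the feed-forward net (full-batch SGD) on CKSAAGP rows."""
    config = config or FfnnConfig()
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] == 0:
        raise ModelError("features must be a non-empty (n, d) matrix")
    y, classes = _encode_labels(labels, class_names)
    if len(y) != features.shape[0]:
        raise ModelError("labels not aligned to feature rows")
    clf = Pipeline(
        [
            # group-pair fractions live on a ~1/L scale; standardize so
            # full-batch SGD sees unit-variance inputs
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=config.hidden_dims,
                    activation="relu",
                    solver="sgd",
                    learning_rate="constant",
                    learning_rate_init=config.learning_rate,
                    batch_size=features.shape[0],
                    max_iter=config.epochs,
                    n_iter_no_change=config.epochs,
                    tol=0.0,
                    random_state=config.seed,
                ),
            ),
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(features, y)
    return ComponentModel("ffnn", "cksaagp", classes, config, clf, features.shape[1])


def train_gbt(
    features: np.ndarray,
    labels: Sequence,
    config: GbtConfig | None = None,
    class_names: Sequence[str] | None = None,
) -> ComponentModel:
    """Fit gradient-boosted trees on CKSAAP rows."""
    config = config or GbtConfig()
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] == 0:
        raise ModelError("features must be a non-empty (n, d) matrix")
    y, classes = _encode_labels(labels, class_names)
    if len(y) != features.shape[0]:
        raise ModelError("labels not aligned to feature rows")
    clf = XGBClassifier(
        learning_rate=config.learning_rate,
        max_depth=config.max_depth,
        n_estimators=config.n_estimators,
        gamma=config.gamma,
        subsample=config.subsample,
        random_state=config.seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )
    clf.fit(features, y)
    inner = _BoosterWrapper(clf.get_booster(), len(classes))
    return ComponentModel("gbt", "cksaap", classes, config, inner, features.shape[1])
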