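"""Run configuration: one YAML document covering encoders, the three
model configs and dataset construction, echoed verbatim into every
command's output directory so runs are reproducible from their
artifacts alone."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .component_models import CnnConfig, FfnnConfig, GbtConfig
from .encoders import DEFAULT_GROUP_SCHEME, EncoderConfig
from .ensemble import ModelConfigs


@dataclass(frozen=True)
class DatasetConfig:
    identity_threshold: float = 0.99
    negative_ratio: float = 1.8
    test_fraction: float = 0.2
    hard_negative_k: int = 3


@dataclass(frozen=True)
class RunConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    models: ModelConfigs = field(default_factory=ModelConfigs)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    seed: int = 0

    # -------------------------------------------------------------- yaml i/o

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "encoder": {
                "k_max": self.encoder.k_max,
                "pad_length": self.encoder.pad_length,
                "group_scheme": dict(self.encoder.group_scheme),
            },
            "models": {
                "cnn": asdict(self.models.cnn),
                "ffnn": asdict(self.models.ffnn),
                "gbt": asdict(self.models.gbt),
            },
            "dataset": asdict(self.dataset),
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        enc = dict(data.pop("encoder", {}))
        enc.setdefault("group_scheme", dict(DEFAULT_GROUP_SCHEME))
        models = data.pop("models", {})
        cnn = dict(models.get("cnn", {}))
        if "kernel_widths" in cnn:
            cnn["kernel_widths"] = tuple(cnn["kernel_widths"])
        ffnn = dict(models.get("ffnn", {}))
        if "hidden_dims" in ffnn:
            ffnn["hidden_dims"] = tuple(ffnn["hidden_dims"])
        gbt = dict(models.get("gbt", {}))
        cfg = cls(
            encoder=EncoderConfig(**enc),
            models=ModelConfigs(
                cnn=CnnConfig(**cnn), ffnn=FfnnConfig(**ffnn), gbt=GbtConfig(**gbt)
            ),
            dataset=DatasetConfig(**data.pop("dataset", {})),
            seed=int(data.pop("seed", 0)),
        )
        if data:
            raise ValueError(f"unknown config fields: {sorted(data)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)
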