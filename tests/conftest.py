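"""Shared fixtures.

The expensive end-to-end pipeline (default synthetic benchmark →
stratified split → trained two-level ensemble → held-out predictions)
is trained once per session and shared by the tests that need it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from rospred import (
    EncoderConfig,
    LabeledExample,
    ProteinRecord,
    SyntheticSpec,
    generate_benchmark,
    predict_hierarchical,
    stratified_split,
    train_hierarchy,
    write_predictions,
)
from rospred.sequence_io import STANDARD_RESIDUES


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(STANDARD_RESIDUES))[rng.integers(20, size=length)])


def random_records(rng, n, min_len=10, max_len=50, prefix="r"):
    return [
        ProteinRecord(
            id=f"{prefix}{i}",
            sequence=random_sequence(rng, int(rng.integers(min_len, max_len + 1))),
        )
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@dataclass
class PipelineRun:
    spec: SyntheticSpec
    encoder_config: EncoderConfig
    seed: int
    train: list[LabeledExample]
    test: list[LabeledExample]
    bundle: object
    predictions: list
    errors: list
    tsv_bytes: bytes


def run_benchmark_pipeline(seed: int = 42) -> PipelineRun:
    """Generate the default benchmark, split 80/20, train, predict."""
    spec = SyntheticSpec(seed=seed)
    data = generate_benchmark(spec)
    train, test = stratified_split(data, test_fraction=0.2, seed=seed)
    encoder_config = EncoderConfig(k_max=5, pad_length=spec.seq_length_range[1])
    bundle = train_hierarchy(train, encoder_config=encoder_config, seed=seed)
    result = predict_hierarchical(bundle, [ex.record for ex in test])
    import pathlib
    import tempfile

    with tempfile.TemporaryDirectory() as td:
        path = pathlib.Path(td) / "predictions.tsv"
        write_predictions(result.predictions, path)
        tsv_bytes = path.read_bytes()
    return PipelineRun(
        spec=spec,
        encoder_config=encoder_config,
        seed=seed,
        train=train,
        test=test,
        bundle=bundle,
        predictions=result.predictions,
        errors=result.errors,
        tsv_bytes=tsv_bytes,
    )


@pytest.fixture(scope="session")
def benchmark_pipeline() -> PipelineRun:
    return run_benchmark_pipeline(seed=42)
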