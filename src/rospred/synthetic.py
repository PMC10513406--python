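"""Synthetic motif-implanted benchmark generator.

Emulates the statistical shape of a curated enzyme corpus without any
external data: several positive families of unequal size, each
defined by a distinct implanted residue motif; uniform-background
negatives; and "hard" negatives that carry only the first half of a
randomly chosen family motif, sitting deliberately close to the
positive/negative boundary.  Generation is a pure function of the
spec (including its seed).

The default spec is the "paper-shaped small" benchmark: 5 families,
340 positives with skewed sizes, 1.8 negatives per positive,
sequence lengths 80–200, a 5% per-residue substitution rate on the
implanted motif and background, and seed 42.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .sequence_io import LabeledExample, ProteinRecord, STANDARD_RESIDUES

#: group-distinct default motifs, one per family: aromatic-, positive-,
#: negative-charged, aliphatic and polar runs, so all three feature views
#: (tokens, residue pairs, group pairs) carry signal.
DEFAULT_MOTIFS = (
    "WWFYYWFWYF",
    "KRHKKRHRKH",
    "DEDDEEDDEE",
    "GAVLGAVLGA",
    "STCPNQSTCP",
)


class SyntheticSpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    class_sizes: tuple[int, ...] = (120, 90, 60, 45, 25)
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    class_names: tuple[str, ...] | None = None
    seq_length_range: tuple[int, int] = (80, 200)
    mutation_rate: float = 0.05
    negative_ratio: float = 1.8
    hard_negative_fraction: float = 0.3
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.class_sizes) < 2:
            raise SyntheticSpecError("need at least 2 classes")
        if len(self.motifs) != len(self.class_sizes):
            raise SyntheticSpecError("one motif per class is required")
        if any(n < 1 for n in self.class_sizes):
            raise SyntheticSpecError("class sizes must be ≥ 1")
        if len(set(self.motifs)) != len(self.motifs):
            raise SyntheticSpecError("motifs must be pairwise distinct")
        for i, a in enumerate(self.motifs):
            if len(a) < 5:
                raise SyntheticSpecError("motifs must be at least 5 residues")
            for j, b in enumerate(self.motifs):
                if i != j and a in b:
                    raise SyntheticSpecError(
                        f"motif {a!r} is a substring of {b!r}"
                    )
        lo, hi = self.seq_length_range
        if lo > hi or lo < max(len(m) for m in self.motifs):
            raise SyntheticSpecError(
                "seq_length_range.min must be ≥ the longest motif"
            )
        if not 0 <= self.mutation_rate < 1:
            raise SyntheticSpecError("mutation_rate must be in [0, 1)")
        if self.negative_ratio < 0:
            raise SyntheticSpecError("negative_ratio must be ≥ 0")
        if not 0 <= self.hard_negative_fraction <= 1:
            raise SyntheticSpecError("hard_negative_fraction must be in [0, 1]")
        if self.class_names is not None and len(self.class_names) != len(
            self.class_sizes
        ):
            raise SyntheticSpecError("one class name per class is required")

    @property
    def n_classes(self) -> int:
        return len(self.class_sizes)

    @property
    def names(self) -> tuple[str, ...]:
        if self.class_names is not None:
            return self.class_names
        return tuple(f"family{i + 1}" for i in range(self.n_classes))

    @property
    def n_positives(self) -> int:
        return sum(self.class_sizes)

    @property
    def n_negatives(self) -> int:
        return int(round(self.n_positives * self.negative_ratio))

    # ------------------------------------------------------------------ yaml

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "class_sizes": list(self.class_sizes),
            "motifs": list(self.motifs),
            "class_names": list(self.names),
            "seq_length_range": list(self.seq_length_range),
            "mutation_rate": self.mutation_rate,
            "negative_ratio": self.negative_ratio,
            "hard_negative_fraction": self.hard_negative_fraction,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise SyntheticSpecError(f"spec file {path} is not a mapping")
        kwargs = {}
        for key in (
            "class_sizes", "motifs", "class_names", "seq_length_range",
            "mutation_rate", "negative_ratio", "hard_negative_fraction", "seed",
        ):
            if key in data:
                value = data.pop(key)
                if isinstance(value, list):
                    value = tuple(value)
                kwargs[key] = value
        if data:
            raise SyntheticSpecError(f"unknown spec fields: {sorted(data)}")
        return cls(**kwargs)


_RESIDUES = np.array(list(STANDARD_RESIDUES))


def mutate_sequence(sequence: str, rate: float, seed: int) -> str:
    """Substitute each position independently with probability ``rate``,
    uniformly over the 19 other standard residues.  Length-preserving."""
    if not 0 <= rate < 1:
        raise SyntheticSpecError("rate must be in [0, 1)")
    if rate == 0 or not sequence:
        return sequence
    rng = np.random.default_rng(seed)
    chars = np.array(list(sequence))
    hits = rng.random(len(chars)) < rate
    out = chars.copy()
    for i in np.flatnonzero(hits):
        choices = _RESIDUES[_RESIDUES != chars[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_background(length: int, rng: np.random.Generator) -> str:
    return "".join(_RESIDUES[rng.integers(20, size=length)])


def _implant(motif: str, length: int, rate: float, rng: np.random.Generator) -> str:
    background = _random_background(length, rng)
    motif = mutate_sequence(motif, rate, int(rng.integers(2**31)))
    pos = int(rng.integers(length - len(motif) + 1))
    return background[:pos] + motif + background[pos + len(motif):]


def generate_family(
    motif: str,
    n: int,
    spec: SyntheticSpec,
    seed: int,
    id_prefix: str = "fam",
) -> list[ProteinRecord]:
    """n records of random background with the (mutated) motif implanted
    at a uniform-random position."""
    lo, hi = spec.seq_length_range
    if lo < len(motif):
        raise SyntheticSpecError("sequence length below motif length")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = _implant(motif, length, spec.mutation_rate, rng)
        records.append(ProteinRecord(id=f"{id_prefix}_{i + 1}", sequence=seq))
    return records


def generate_benchmark(spec: SyntheticSpec) -> list[LabeledExample]:
    """The full labeled benchmark: positives per family, then negatives
    (a ``hard_negative_fraction`` share carrying a half-motif)."""
    rng = np.random.default_rng(spec.seed)
    examples: list[LabeledExample] = []
    for ci, (name, motif, size) in enumerate(
        zip(spec.names, spec.motifs, spec.class_sizes)
    ):
        fam_seed = int(rng.integers(2**31))
        for rec in generate_family(motif, size, spec, fam_seed, id_prefix=f"pos_{name}"):
            examples.append(LabeledExample(record=rec, positive=True, level2=name))

    n_neg = spec.n_negatives
    n_hard = int(round(n_neg * spec.hard_negative_fraction))
    lo, hi = spec.seq_length_range
    for i in range(n_neg):
        length = int(rng.integers(lo, hi + 1))
        if i < n_hard:
            motif = spec.motifs[int(rng.integers(spec.n_classes))]
            half = motif[: len(motif) // 2]
            seq = _implant(half, length, spec.mutation_rate, rng)
        else:
            seq = _random_background(length, rng)
        rec = ProteinRecord(id=f"neg_{i + 1}", sequence=seq)
        examples.append(LabeledExample(record=rec, positive=False))
    return examples
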