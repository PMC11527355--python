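"""Experiment configuration: one YAML file driving the whole pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import yaml

from .attribution import AttributionOptions
from .bamodel import CNNConfig
from .phantom import PhantomParams

__all__ = ["ExperimentConfig"]


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of one phantom-to-report experiment.

    The cohort is split into non-overlapping train/validation/test sets
    (default fractions 0.8/0.1/0.1). ``seed`` is the master seed from
    which every stage derives its own independent stream.
    """

    n_subjects: int = 200
    age_low: float = 40.0
    age_high: float = 90.0
    split_fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    phantom: PhantomParams = field(default_factory=PhantomParams)
    cnn: CNNConfig = field(default_factory=CNNConfig.reduced)
    attribution: AttributionOptions = field(default_factory=AttributionOptions)
    nmi_bins: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be nonnegative")
        if not self.age_low < self.age_high:
            raise ValueError("age_low must be < age_high")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if any(f < 0 for f in self.split_fractions):
            raise ValueError("split fractions must be nonnegative")
        if self.cnn.input_size != self.phantom.grid_size:
            raise ValueError(
                f"CNN input size {self.cnn.input_size} must equal phantom grid "
                f"size {self.phantom.grid_size}")

    # -- (de)serialization ----------------------------------------------
    def to_yaml(self, path: Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        if "phantom" in raw and isinstance(raw["phantom"], dict):
            raw["phantom"] = PhantomParams(**raw["phantom"])
        if "cnn" in raw and isinstance(raw["cnn"], dict):
            cnn = dict(raw["cnn"])
            for key in ("filters", "dropout_blocks", "dense_sizes"):
                if key in cnn:
                    cnn[key] = tuple(cnn[key])
            raw["cnn"] = CNNConfig(**cnn)
        if "attribution" in raw and isinstance(raw["attribution"], dict):
            raw["attribution"] = AttributionOptions(**raw["attribution"])
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        return cls(**raw)
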