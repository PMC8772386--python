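"""Aggregate run configuration with lossless YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .alignment import AlignmentScoring
from .beam import PredictionConfig
from .model import ModelConfig
from .training import TrainingConfig
from .validation import ValidationConfig


@dataclass
class RunConfig:
    """Everything one end-to-end gap-filling run needs, in one place.

    Shipped defaults are the full-scale settings (embedding 128, 512 LSTM
    units, batch 128, up to 1000 epochs with patience 200, k_low 52,
    750-base predictions with beam width 64, 100 bp reciprocal probe,
    70% pass threshold); small-scale runs override them.
    """

    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    prediction: PredictionConfig = field(default_factory=PredictionConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)
    seed: int = 0

    _SECTIONS = ("model", "training", "prediction", "validation", "scoring")

    def to_dict(self) -> dict:
        d = {s: dataclasses.asdict(getattr(self, s)) for s in self._SECTIONS}
        d["seed"] = self.seed
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        types = {
            "model": ModelConfig,
            "training": TrainingConfig,
            "prediction": PredictionConfig,
            "validation": ValidationConfig,
            "scoring": AlignmentScoring,
        }
        kwargs = {s: types[s](**d[s]) for s in cls._SECTIONS if s in d}
        return cls(seed=d.get("seed", 0), **kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
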