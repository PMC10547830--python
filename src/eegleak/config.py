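"""Experiment configuration: one YAML file driving a full reproducible run.

Defaults mirror the reference experimental settings: windows 5/10/15/20/60 s,
non-overlap and 75% overlap (dictated per scheme), 10×10-fold CV, a 60%
voting threshold, batch size 5 and 300 training epochs at paper scale.  The
``desk`` scale shrinks the cohort, filter counts and epochs so the whole
grid runs on a laptop CPU.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import DEFAULT_WINDOWS_S
from .cohort import CohortSpec
from .cv import SCHEME_NAMES, CVScheme
from .errors import ConfigurationError
from .evaluate import VotingRule
from .models import ModelConfig


@dataclass
class ExperimentConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    windows_s: tuple[float, ...] = DEFAULT_WINDOWS_S
    schemes: tuple[str, ...] = SCHEME_NAMES
    models: tuple[str, ...] = ("compact_cnn", "deep_cnn")
    scale: str = "desk"
    k: int = 10
    repeats: int = 10
    seed: int = 0
    voting_threshold: float = 0.6
    output_dir: str = "eegleak_out"

    def __post_init__(self) -> None:
        for s in self.schemes:
            if s not in SCHEME_NAMES:
                raise ConfigurationError(f"unknown scheme {s!r}; valid: {SCHEME_NAMES}")
        VotingRule(self.voting_threshold)  # validates
        if self.scale not in ("paper", "desk"):
            raise ConfigurationError(f"scale must be 'paper' or 'desk', got {self.scale!r}")

    def scheme_objects(self) -> list[CVScheme]:
        return [CVScheme(s) for s in self.schemes]

    def model_configs(self) -> list[ModelConfig]:
        return [ModelConfig(family=f, scale=self.scale, seed=self.seed)
                for f in self.models]

    def voting(self) -> VotingRule:
        return VotingRule(self.voting_threshold)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["target_band"] = list(d["cohort"]["target_band"])
        d["windows_s"] = list(d["windows_s"])
        d["schemes"] = list(d["schemes"])
        d["models"] = list(d["models"])
        return d

    def manifest_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            if "target_band" in cohort:
                cohort["target_band"] = tuple(cohort["target_band"])
            cohort = CohortSpec(**cohort)
        for key in ("windows_s", "schemes", "models"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(cohort=cohort, **d)
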