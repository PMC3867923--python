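"""Experiment configuration: one object bundling every stage's settings.

A single master seed fans out to per-stage seeds through a counter-based
seed-sequence derivation, so a full experiment is reproducible from the
resolved configuration alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml
from numpy.random import SeedSequence

from .errors import ParameterError
from .instance_selection import IOConfig
from .prediction import PredictorConfig
from .preprocessing import PreprocessConfig
from .svm_tuning import LOConfig, PSOConfig
from .texture import GLCMConfig

__all__ = ["ExperimentConfig", "derive_seed"]

METHODS = ("iomil", "svm", "citation-knn", "wemisvm")


def derive_seed(master_seed: int, stage: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    child = SeedSequence(master_seed).spawn(stage + 1)[stage]
    return int(child.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ExperimentConfig:
    """End-to-end experiment settings.

    The default PSO budget here (10 particles x 12 iterations, 3-fold
    fitness) is the desk-scale working point for full pipeline runs; the
    :class:`~lesionmil.svm_tuning.PSOConfig` dataclass defaults describe
    the stand-alone tuner.
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    block_length: float = 113.0
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    io: IOConfig = field(default_factory=IOConfig)
    pso: PSOConfig = field(
        default_factory=lambda: PSOConfig(swarm_size=10, iterations=12, fitness_folds=3)
    )
    lo: LOConfig = field(default_factory=LOConfig)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    validation_groups: int = 5
    seed: int = 0
    methods: tuple[str, ...] = ("iomil",)
    per_class_counts: dict = field(
        default_factory=lambda: {"cancer": 80, "normal": 120}
    )
    phantom_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.validation_groups < 2:
            raise ParameterError(
                f"validation_groups must be >= 2, got {self.validation_groups}"
            )
        for m in self.methods:
            if m not in METHODS:
                raise ParameterError(f"unknown method {m!r}; choose from {METHODS}")

    def stage_seed(self, stage: int) -> int:
        return derive_seed(self.seed, stage)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        sub = {
            "preprocess": PreprocessConfig,
            "glcm": GLCMConfig,
            "io": IOConfig,
            "pso": PSOConfig,
            "lo": LOConfig,
            "predictor": PredictorConfig,
        }
        kwargs = {}
        for key, typ in sub.items():
            if key in data:
                val = data.pop(key)
                if isinstance(val, dict):
                    for tup_key in ("distances", "angles", "c_bounds", "g_bounds",
                                    "lesion_count_range", "lesion_radius_range"):
                        if tup_key in val and isinstance(val[tup_key], list):
                            val[tup_key] = tuple(val[tup_key])
                    val = typ(**val)
                kwargs[key] = val
        if "methods" in data and isinstance(data["methods"], list):
            data["methods"] = tuple(data["methods"])
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    def with_seed(self, seed: int) -> "ExperimentConfig":
        return replace(self, seed=seed)
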