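"""Run configuration: a versioned YAML schema that round-trips losslessly.

Unknown keys are rejected so typos fail before any compute.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .synth import Pattern

SCHEMA_VERSION = 1


def _from_mapping(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SimulateConfig:
    patterns: list = field(
        default_factory=lambda: ["normal", "biot", "tachypnea", "bradypnea", "cheyne_stokes"]
    )
    n_per_pattern: int = 4
    duration_s: float = 60.0
    sampling_rate: float = 20.0
    noise_sigma_mm: float = 0.1
    heartbeat: bool = True

    def validate(self) -> None:
        for p in self.patterns:
            Pattern(p)  # raises on unknown pattern names
        if self.n_per_pattern < 1:
            raise ValueError("n_per_pattern must be >= 1")
        if self.duration_s <= 0 or self.sampling_rate < 4:
            raise ValueError("invalid duration or sampling rate")
        if self.noise_sigma_mm < 0:
            raise ValueError("noise_sigma_mm must be >= 0")


@dataclass
class RadarConfig:
    base_range_m: float = 0.30
    dropout_rate: float = 0.0

    def validate(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.base_range_m <= 0:
            raise ValueError("base_range_m must be > 0")


@dataclass
class BandConfig:
    respiration: list = field(default_factory=lambda: [0.1, 0.6])
    heart: list = field(default_factory=lambda: [0.8, 4.0])

    def validate(self) -> None:
        for lo, hi in (self.respiration, self.heart):
            if not (0 < lo < hi):
                raise ValueError("bands must satisfy 0 < lo < hi")


@dataclass
class ApneaConfig:
    window: int = 80
    hop: int = 5
    min_len: int = 3
    mode: str = "anchored"

    def validate(self) -> None:
        if self.window < 1 or not (1 <= self.hop <= self.window) or self.min_len < 1:
            raise ValueError("invalid apnea windowing")
        if self.mode not in ("anchored", "trailing"):
            raise ValueError("apnea mode must be 'anchored' or 'trailing'")


@dataclass
class ClassifyConfig:
    model: str = "svm"
    cv_folds: int = 0  # 0 = holdout split instead of CV
    test_fraction: float = 0.5

    def validate(self) -> None:
        if self.model not in ("svm", "knn"):
            raise ValueError("model must be 'svm' or 'knn'")
        if self.cv_folds not in (0,) and self.cv_folds < 2:
            raise ValueError("cv_folds must be 0 or >= 2")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "vitalwave_run"
    schema_version: int = SCHEMA_VERSION
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    radar: RadarConfig = field(default_factory=RadarConfig)
    bands: BandConfig = field(default_factory=BandConfig)
    apnea: ApneaConfig = field(default_factory=ApneaConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)

    def validate(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {self.schema_version}")
        for section in (self.simulate, self.radar, self.bands, self.apnea, self.classify):
            section.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sections = {
            "simulate": SimulateConfig,
            "radar": RadarConfig,
            "bands": BandConfig,
            "apnea": ApneaConfig,
            "classify": ClassifyConfig,
        }
        kwargs = {}
        for name, scls in sections.items():
            if name in data:
                kwargs[name] = _from_mapping(scls, data.pop(name) or {})
        cfg = _from_mapping(cls, {**data, **kwargs})
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
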