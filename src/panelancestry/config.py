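"""Pipeline configuration.

Defaults carry the analysis constants (INFO > 0.4, minor AF > 0.01, group
thresholds 20 % / 15 % / 0.75, Bonferroni over 8 tests at q < 0.1) and the
simulator's study conditions; everything is overridable and the full
config (with a stable hash) is stamped into every output header.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig", "SimulatorConfig", "HMMConfig", "FilterConfig",
           "ThresholdConfig", "TestingConfig"]


@dataclass
class SimulatorConfig:
    n_pops: int = 3
    fst: object = None            # None -> per-population defaults
    n_hap_per_pop: int = 60
    m_sites: int = 2000
    n_ind: int = 200
    depth: float = 1.0
    error_rate: float = 0.01
    alpha: object = 0.1
    subpop_fraction: float = 0.1
    subpop_fst: float = 0.004
    n_hap_subpop: int = 40


@dataclass
class HMMConfig:
    rho: float = 1.0
    theta: float = 0.01
    n_hap_used: int = 100


@dataclass
class FilterConfig:
    info_min: float = 0.4
    af_min: float = 0.01


@dataclass
class ThresholdConfig:
    african_max: float = 20.0
    asian_max: float = 15.0
    aj_min: float = 0.75


@dataclass
class TestingConfig:
    n_tests: int = 8
    q_cut: float = 0.1
    smoking_bin_edges: list = field(default_factory=lambda: [0, 15, 30, 45, 60])

    def __post_init__(self):
        self.smoking_bin_edges = list(self.smoking_bin_edges)


def _build(cls, data):
    if isinstance(data, cls):
        return data
    return cls(**(data or {}))


@dataclass
class PipelineConfig:
    seed: int = 0
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    hmm: HMMConfig = field(default_factory=HMMConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    testing: TestingConfig = field(default_factory=TestingConfig)

    def __post_init__(self):
        self.simulator = _build(SimulatorConfig, self.simulator)
        self.hmm = _build(HMMConfig, self.hmm)
        self.filters = _build(FilterConfig, self.filters)
        self.thresholds = _build(ThresholdConfig, self.thresholds)
        self.testing = _build(TestingConfig, self.testing)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
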