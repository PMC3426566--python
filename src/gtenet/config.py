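"""Pipeline configuration: one dataclass per module, YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import DriveParams, NeuronParams, SynapseParams
from .fluorescence import CalciumParams, ScatterParams

__all__ = ["TopologyConfig", "DynamicsConfig", "EstimatorConfig",
           "EvaluationConfig", "PipelineConfig"]


@dataclass
class TopologyConfig:
    ensemble: str = "nonlocal"  # nonlocal | local
    n_neurons: int = 100
    p: float = 0.12
    target_cc: float = 0.5  # nonlocal ensemble
    lambda_mm: float = 0.5  # local ensemble
    area_side: float = 0.5


@dataclass
class DynamicsConfig:
    duration: float = 3600.0  # s of recording to simulate
    target_burst_rate: float = 0.1  # Hz
    tune_tol: float = 0.01  # Hz
    probe_duration: float = 200.0  # s per tuning probe
    tune: bool = True  # if False, use synapse.g_int as-is


@dataclass
class EstimatorConfig:
    methods: tuple = ("te",)
    order: int = 2
    same_bin: bool = True
    bins: int = 3
    cond_mode: str = "gauss2sd"  # gauss2sd | range2 | none | fixed
    cond_level: float | None = None  # used when cond_mode == "fixed"
    xc_lags: int = 2
    top_fraction: float = 0.10


@dataclass
class EvaluationConfig:
    fp_level: float = 0.10
    n_ranges: int = 7
    n_random_draws: int = 100
    n_hubs: int = 20


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a benchmark or real-data run."""

    topology: TopologyConfig = field(default_factory=TopologyConfig)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    drive: DriveParams = field(default_factory=DriveParams)
    calcium: CalciumParams = field(default_factory=CalciumParams)
    scatter: ScatterParams = field(default_factory=ScatterParams)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 1
    apply_scatter: bool = True
    outdir: str | None = None

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in obj.__dict__.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return enc(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        sections = {
            "topology": TopologyConfig,
            "neuron": NeuronParams,
            "synapse": SynapseParams,
            "drive": DriveParams,
            "calcium": CalciumParams,
            "scatter": ScatterParams,
            "dynamics": DynamicsConfig,
            "estimator": EstimatorConfig,
            "evaluation": EvaluationConfig,
        }
        for name, klass in sections.items():
            if name in kwargs and isinstance(kwargs[name], dict):
                sec = dict(kwargs[name])
                if name == "estimator" and "methods" in sec:
                    sec["methods"] = tuple(sec["methods"])
                kwargs[name] = klass(**sec)
        return cls(**kwargs)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "PipelineConfig":
        text = str(path_or_text)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        return cls.from_dict(yaml.safe_load(text))
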