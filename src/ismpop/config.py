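"""Pipeline configuration: one YAML/JSON file drives every stage.

A single global seed is threaded through all stochastic stages; the
canonical hash of the configuration is recorded in every output so runs
are reproducible and traceable.  Unknown keys are rejected with their full
key path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .core import ProcessEvent
from .detection import ClassifierThresholds, DetectionParams
from .reference import (
    ALPHA_IMAGE_PER_ML,
    BATCH_END_H,
    DILUTION_RATE_PER_H,
    PROCESS_END_H,
)
from .synthetic import InitialState, KineticParameters, OpticsParameters

__all__ = ["EvaluationParams", "PipelineConfig", "default_events", "default_config"]


@dataclass(frozen=True)
class EvaluationParams:
    iou_threshold: float = 0.5
    align: str = "nearest"      # MAPE alignment: nearest | interpolate
    max_gap_h: float = 1.0
    pool_viable: bool = False


def default_events() -> list[ProcessEvent]:
    """Event schedule of the 145-h reference run: four offgas-clogging
    episodes, a fresh-medium addition at 24 h, substrate limitation from
    40 h, an oxygen shutdown at 48.25–56 h with resupply afterwards, and
    the continuous feed from 75.5 h."""
    return [
        ProcessEvent("gas_blocking_1", "gas_blocking", 6.0, 12.0, 0.3),
        ProcessEvent("gas_blocking_2", "gas_blocking", 18.0, 21.0, 0.3),
        ProcessEvent("medium_addition", "medium_addition", 24.0, 24.5, 0.35),
        ProcessEvent("substrate_limitation", "substrate_limitation", 40.0, PROCESS_END_H, 0.5),
        ProcessEvent("oxygen_depletion", "oxygen_depletion", 48.25, 56.0, 1.0),
        ProcessEvent("oxygen_resupply", "oxygen_resupply", 56.0, PROCESS_END_H, 30.0),
        ProcessEvent("feed_start", "feed_start", BATCH_END_H, PROCESS_END_H, 4.5),
        ProcessEvent("gas_blocking_3", "gas_blocking", 81.0, 84.0, 0.3),
        ProcessEvent("gas_blocking_4", "gas_blocking", 120.0, 123.0, 0.3),
    ]


@dataclass
class PipelineConfig:
    """Everything the CLI pipeline needs, nested per stage."""

    kinetics: KineticParameters = field(default_factory=lambda: KineticParameters(D=DILUTION_RATE_PER_H))
    init: InitialState = field(default_factory=InitialState)
    optics: OpticsParameters = field(default_factory=OpticsParameters)
    detection: DetectionParams = field(default_factory=DetectionParams)
    classifier: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    evaluation: EvaluationParams = field(default_factory=EvaluationParams)
    events: list[ProcessEvent] = field(default_factory=default_events)
    alpha: float = ALPHA_IMAGE_PER_ML
    n_images_per_point: int = 1000
    smoothing_window: int = 5
    focus_threshold: float = 0.085
    t_end: float = PROCESS_END_H
    dt: float = 0.05
    sample_interval_h: float = 0.25
    seed: int = 0

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def conv(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            return obj

        return conv(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build_dataclass(cls, data, path="")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _build_dataclass(klass, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config error at {path or '<root>'}: expected a mapping")
    field_map = {f.name: f for f in dataclasses.fields(klass)}
    unknown = set(data) - set(field_map)
    if unknown:
        key = sorted(unknown)[0]
        raise ValueError(f"config error: unknown key {(path + '.' if path else '') + key!r}")
    kwargs = {}
    for name, value in data.items():
        f = field_map[name]
        sub_path = f"{path}.{name}" if path else name
        if name == "events":
            kwargs[name] = [
                _build_dataclass(ProcessEvent, ev, f"{sub_path}[{i}]")
                for i, ev in enumerate(value)
            ]
        elif isinstance(f.type, str) and f.type in _NESTED:
            kwargs[name] = _build_dataclass(_NESTED[f.type], value, sub_path)
        elif dataclasses.is_dataclass(f.type):
            kwargs[name] = _build_dataclass(f.type, value, sub_path)
        else:
            kwargs[name] = value
    return klass(**kwargs)


# dataclass field types may be strings under `from __future__ import annotations`
_NESTED = {
    "KineticParameters": KineticParameters,
    "InitialState": InitialState,
    "OpticsParameters": OpticsParameters,
    "DetectionParams": DetectionParams,
    "ClassifierThresholds": ClassifierThresholds,
    "EvaluationParams": EvaluationParams,
}


def default_config(seed: int = 0) -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.seed = seed
    return cfg
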