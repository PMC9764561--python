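"""Run configuration: defaults, validation, YAML round-trip.

A config is a flat-ish YAML document.  Top-level keys:

``params``          mapping of model-parameter overrides (standard
                    defaults otherwise), e.g. ``{k0: 0.5, k7: 2.0}``
``topology``        1 (single compartment) or 2 (coupled)
``seed``            integer seed for anything stochastic (synth suites)
``dt``, ``t_total``, ``t_transient``, ``record_stride``
                    integration protocol
``thresholds``      classifier-threshold overrides
``simulate``, ``sweep``, ``hopf_scan``, ``cycle_scan``, ``classify``,
``synth``, ``reproduce``
                    command-specific blocks (free-form mappings validated
                    by the command that consumes them)

Unknown keys are rejected; every run echoes the fully resolved config
next to its outputs so results are reproducible from the artifacts alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .params import ModelParams
from .waveform_analysis import ClassifierThresholds

__all__ = ["RunConfig", "load_config", "resolve", "dump_config"]

_COMMAND_BLOCKS = ("simulate", "sweep", "hopf_scan", "cycle_scan",
                   "classify", "synth", "reproduce")


@dataclass
class RunConfig:
    params: dict = field(default_factory=dict)
    topology: int = 1
    seed: int = 0
    dt: float = 5e-5
    t_total: float = 30.0
    t_transient: float = 20.0
    record_stride: int = 20
    thresholds: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)
    hopf_scan: dict = field(default_factory=dict)
    cycle_scan: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)
    reproduce: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.topology not in (1, 2):
            raise ValueError(f"topology must be 1 or 2, got {self.topology!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.t_transient < self.t_total:
            raise ValueError("need 0 <= t_transient < t_total")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        # validate overrides by constructing the objects they configure
        self.model_params()
        self.classifier_thresholds()

    def model_params(self) -> ModelParams:
        return ModelParams.from_dict(dict(self.params))

    def classifier_thresholds(self) -> ClassifierThresholds:
        known = {f.name for f in fields(ClassifierThresholds)}
        unknown = set(self.thresholds) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return ClassifierThresholds(**{k: float(v) for k, v in self.thresholds.items()})

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def with_overrides(self, assignments: dict) -> "RunConfig":
        """Apply ``--set key=value`` style overrides.

        Dotted keys address nested blocks (``sweep.param=k7``); bare keys
        that are model parameters (``k0=0.5``) go into ``params``.
        """
        d = self.to_dict()
        for key, value in assignments.items():
            parts = key.split(".")
            if len(parts) == 1 and key in ModelParams.field_names():
                d["params"][key] = value
            elif len(parts) == 1:
                if key not in d:
                    raise ValueError(f"unknown config key {key!r}")
                d[key] = value
            elif len(parts) == 2 and parts[0] in _COMMAND_BLOCKS + ("params", "thresholds"):
                d[parts[0]][parts[1]] = value
            else:
                raise ValueError(f"cannot resolve override key {key!r}")
        return RunConfig.from_dict(d)


def _coerce(value: str):
    """Parse a --set value string into bool/int/float/str."""
    s = str(value)
    low = s.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            continue
    return s


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; missing file or bad keys raise."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    return RunConfig.from_dict(data)


def resolve(config_path: Optional[str], assignments) -> RunConfig:
    cfg = load_config(config_path) if config_path else RunConfig()
    if assignments:
        parsed = {}
        for item in assignments:
            if "=" not in item:
                raise ValueError(f"--set expects key=value, got {item!r}")
            k, v = item.split("=", 1)
            parsed[k.strip()] = _coerce(v.strip())
        cfg = cfg.with_overrides(parsed)
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
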