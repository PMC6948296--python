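"""Run configuration: schema-validated nested dataclasses.

Every tunable of the pipeline lives here so that a run can be reproduced from
the resolved config file written next to its outputs.  Unknown keys are
rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


@dataclass
class FilterConfig:
    low_hz: float = 3.0
    high_hz: float = 45.0
    transition_hz: float = 1.0


@dataclass
class RrCorrectConfig:
    window: int = 5
    max_dev: float = 0.2


@dataclass
class WelchConfig:
    interp_hz: float = 4.0     # resampling rate for the RR / EDR tachograms
    nfft: int = 256
    window: str = "hann"
    overlap: float = 0.5       # fraction of nperseg
    ratio_cap: float = 1e6     # x/0 -> cap; 0/0 -> 0


@dataclass
class FeatureConfig:
    pnn50_denominator: str = "pairs"   # "pairs" (N-1) or "intervals" (N)
    min_beats_per_minute: int = 20


@dataclass
class TrainConfig:
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 128
    epochs: int = 200
    val_fraction: float = 0.1
    patience: int = 20
    seed: int = 0


@dataclass
class EvalConfig:
    ahi_threshold: float = 5.0
    # "evaluated": T = minutes actually scored (after window trimming);
    # "full": T = all labelled minutes of the recording.
    ahi_t_policy: str = "evaluated"


@dataclass
class RunConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    rr_correct: RrCorrectConfig = field(default_factory=RrCorrectConfig)
    welch: WelchConfig = field(default_factory=WelchConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    window: int = 5            # segments per model input, current one included
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return _build(cls, d, "")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _build(cls: type, d: dict[str, Any], prefix: str):
    if not isinstance(d, dict):
        raise ConfigError(f"section '{prefix or cls.__name__}' must be a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(names)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)} in section '{prefix or 'root'}'"
        )
    kwargs = {}
    for key, value in d.items():
        f = names[key]
        factory = f.default_factory
        if factory is not dataclasses.MISSING and dataclasses.is_dataclass(factory):
            kwargs[key] = _build(factory, value, f"{prefix}{key}.")
        else:
            kwargs[key] = value
    return cls(**kwargs)
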