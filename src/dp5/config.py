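"""Run configuration: defaults, JSON file loading, strict key checking."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields

from .exceptions import ConfigError


def _strict(cls, data: dict, prefix: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): "
                          f"{', '.join(sorted(prefix + k for k in unknown))}")
    return cls(**data)


@dataclass
class DescriptorConfig:
    cutoff: float = 5.0
    n_radial_bins: int = 24
    width: float = 0.5
    angular: bool = False


@dataclass
class KernelConfig:
    sigma: float | str = "auto"


@dataclass
class ErrorModelConfig:
    scheme: str = "window"  # window | two_tail
    bandwidth: float | str = "auto"
    allow_partial: bool = True


@dataclass
class CalibrationConfig:
    prior_correct: float = 0.5


@dataclass
class BenchmarkConfig:
    folds: int = 10
    max_incorrect_per_molecule: int | None = 4
    temperature: float = 298.15


@dataclass
class RunConfig:
    descriptor: DescriptorConfig = field(default_factory=DescriptorConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    error_model: ErrorModelConfig = field(default_factory=ErrorModelConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {
            "descriptor": DescriptorConfig,
            "kernel": KernelConfig,
            "error_model": ErrorModelConfig,
            "calibration": CalibrationConfig,
            "benchmark": BenchmarkConfig,
        }
        known = set(sections) | {"seed", "verbosity"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): "
                              f"{', '.join(sorted(unknown))}")
        kwargs = {}
        for name, section_cls in sections.items():
            if name in data:
                kwargs[name] = _strict(section_cls, data[name], name + ".")
        for name in ("seed", "verbosity"):
            if name in data:
                kwargs[name] = data[name]
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as handle:
            return cls.from_dict(json.load(handle))

    def to_dict(self) -> dict:
        return asdict(self)

    def descriptor_params(self):
        from .environments import DescriptorParams

        return DescriptorParams(
            cutoff=self.descriptor.cutoff,
            n_radial_bins=self.descriptor.n_radial_bins,
            width=self.descriptor.width,
            include_angular=self.descriptor.angular,
        )
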