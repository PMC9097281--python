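"""JSON run configuration: schema validation and (de)serialisation.

A RunConfig fully determines a pipeline run; persisting and re-loading
it re-executes to identical results for the deterministic stages.
Validation errors name the offending field path.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["ConfigError", "RunConfig"]


class ConfigError(ValueError):
    """A configuration field is missing, mistyped, or out of range."""


_STAGES = ("benchmark", "unbind", "string", "wham", "downhill", "mltsa")


@dataclass
class RunConfig:
    """Pipeline configuration.

    mode      : "benchmark" (analytical MLTSA benchmark) or "pocket"
                (unbind -> string -> wham -> downhill -> mltsa on the 2D
                pocket fixtures)
    stages    : ordered prefix of the mode's stage list to execute
    seed      : global seed; every stage derives child seeds from it
    out_dir   : run directory for artifacts and the manifest
    benchmark : keyword overrides for benchmarks.make_benchmark
    protocol  : keyword overrides for cvselect.ProtocolParams
    string    : string/WHAM settings (n_windows, steps_per_window, ...)
    ml        : MLTSA settings (n_replicas, classifiers, window, ...)
    """

    mode: str = "benchmark"
    stages: list = field(default_factory=list)
    seed: int = 0
    out_dir: str = "unbindkit_run"
    benchmark: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    string: dict = field(default_factory=dict)
    ml: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("benchmark", "pocket"):
            raise ConfigError(f"mode: expected 'benchmark' or 'pocket', got {self.mode!r}")
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed: expected integer, got {type(self.seed).__name__}")
        for i, s in enumerate(self.stages):
            if s not in _STAGES:
                raise ConfigError(f"stages[{i}]: unknown stage {s!r}; "
                                  f"valid: {', '.join(_STAGES)}")
        for name in ("benchmark", "protocol", "string", "ml"):
            val = getattr(self, name)
            if not isinstance(val, dict):
                raise ConfigError(f"{name}: expected a mapping, got "
                                  f"{type(val).__name__}")
        if self.ml.get("n_replicas", 1) < 1:
            raise ConfigError("ml.n_replicas: must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path) -> "RunConfig":
        try:
            data = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"invalid JSON in {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError("top level: expected a JSON object")
        return cls.from_dict(data)
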