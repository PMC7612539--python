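"""Run configuration: a fully serialisable bundle of every tunable default.

A :class:`RunConfig` captures the population spec, flow-wave shape, solver
settings, method selections and exclusion bounds; it round-trips through
YAML and hashes stably, so identical configs reproduce identical runs and
every dataset manifest can embed its generating configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

from .errors import ConfigurationError
from .virtual_population import CVParameterSpec, ExclusionBounds, FlowShape


@dataclass
class RunConfig:
    population: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: CVParameterSpec().to_dict())
    wave: Dict[str, float] = field(
        default_factory=lambda: {"dt": 1e-3, "k_lvet": 0.293, "m": 1.0,
                                 "skew": 1.0, "q_th": 0.02})
    windkessel: Dict[str, float] = field(
        default_factory=lambda: {"tol": 1e-6, "max_cycles": 200,
                                 "fit_starts": 4, "fit_seed": 20200241})
    exclusions: Dict[str, float] = field(
        default_factory=lambda: {"csbp_max": 220.0, "cdbp_min": 44.0,
                                 "cpp_min": 18.0, "cpp_max": 109.0})
    methods: Dict[str, str] = field(default_factory=dict)
    seed: int = 0
    limit: Optional[int] = None

    # ------------------------------------------------------------------
    def spec(self) -> CVParameterSpec:
        try:
            return CVParameterSpec(**{k: tuple(v) for k, v in self.population.items()})
        except TypeError as exc:
            raise ConfigurationError(f"bad population spec: {exc}")

    def shape(self) -> FlowShape:
        w = self.wave
        return FlowShape(dt=w.get("dt", 1e-3), k_lvet=w.get("k_lvet", 0.293),
                         m=w.get("m", 1.0), skew=w.get("skew", 1.0))

    def bounds(self) -> ExclusionBounds:
        return ExclusionBounds(**self.exclusions)

    # ------------------------------------------------------------------
    def to_dict(self) -> Dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()
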