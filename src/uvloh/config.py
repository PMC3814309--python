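"""Run configuration: one YAML document drives the whole pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .caller import CallThresholds
from .simulate import SimulationConfig


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    ``genome`` is either "default" (the built-in synthetic genome, generated
    from ``seed``) or a mapping with ``snp_map`` / ``annotations`` paths.
    All randomness flows from the single ``seed``.
    """

    genome: str | dict = "default"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    min_run: int = 2
    independence_gap_kb: float = 15.0
    boundary_tol_snps: int = 1
    n_perm: int = 1000
    n_bins: int = 4
    ci_level: float = 0.95
    seed: int = 0
    output_dir: str = "uvloh-run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = CallThresholds(**d["thresholds"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
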