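"""Pipeline configuration: strict YAML schema, seed fan-out, config hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


def _from_mapping(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys in '{where}': {sorted(unknown)}")
    return cls(**data)


@dataclass
class SyntheticConfig:
    grid_shape: list[int] = field(default_factory=lambda: [60, 80])
    cell_area_ha: float = 900.0
    years: list[int] = field(default_factory=lambda: [1995, 2000, 2005, 2010, 2015, 2018])
    class_fractions: list[float] = field(
        default_factory=lambda: [0.28, 0.24, 0.22, 0.06, 0.05, 0.01, 0.11, 0.03])
    trend_rates: list[float] = field(
        default_factory=lambda: [0.995, 0.996, 1.001, 0.998, 1.003, 0.995, 1.012, 0.97])
    autocorrelation_scale: float = 4.0
    area_noise_sd: float = 0.005
    change_fraction: float = 0.03   # share of cells perturbed between the two dates


@dataclass
class CAConfig:
    neighborhood_size: int = 3
    max_iterations: int = 60
    demand_tolerance: int | None = None
    inertia_floor: float = 1e-3
    candidate_mode: str = "all"


@dataclass
class ANNConfig:
    hidden_units: int = 12
    epochs: int = 300
    sample_fraction: float = 0.02
    sampling_strategy: str = "uniform"


@dataclass
class DemandConfig:
    fold_unused_into_built_up: bool = True
    protection_floor_km2: float | None = None
    horizon: int = 2


@dataclass
class ESVConfig:
    unit_divisor: float = 1e7

    def __post_init__(self) -> None:
        # YAML 1.1 reads exponent literals without a sign ("1.0e7") as strings
        self.unit_divisor = float(self.unit_divisor)


@dataclass
class PipelineConfig:
    scenario: str = "toy"
    seed: int = 0
    output_dir: str = "results/toy"
    rules_path: str | None = None   # None -> packaged ecological-optimization fixture
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    ca: CAConfig = field(default_factory=CAConfig)
    ann: ANNConfig = field(default_factory=ANNConfig)
    demand: DemandConfig = field(default_factory=DemandConfig)
    esv: ESVConfig = field(default_factory=ESVConfig)

    #: fixed per-stage seed offsets so stages stay independent under one seed
    STAGE_OFFSETS = {"landscape": 0, "evolve": 11, "areas": 23, "socio": 37,
                     "factors": 43, "sampling": 53, "ann": 67, "screen": 79,
                     "ca": 97, "assess": 113}

    def child_seed(self, stage: str) -> int:
        return (self.seed * 1000 + self.STAGE_OFFSETS[stage]) % (2 ** 31)

    def hash(self) -> str:
        """Digest of the scientific configuration (output location excluded)."""
        def enc(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {f.name: enc(getattr(obj, f.name)) for f in fields(obj)
                        if f.name != "output_dir"}
            return obj
        return hashlib.sha256(json.dumps(enc(self), sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration (unknown keys error)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    sections = {"synthetic": SyntheticConfig, "ca": CAConfig, "ann": ANNConfig,
                "demand": DemandConfig, "esv": ESVConfig}
    kwargs = {}
    for key, value in raw.items():
        if key in sections:
            if not isinstance(value, dict):
                raise ConfigError(f"section '{key}' must be a mapping")
            kwargs[key] = _from_mapping(sections[key], value, key)
        elif key in {"scenario", "seed", "output_dir", "rules_path"}:
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown config keys in root: ['{key}']")
    cfg = PipelineConfig(**kwargs)
    if cfg.rules_path is not None and not Path(cfg.rules_path).exists():
        raise ConfigError(f"rules file not found: {cfg.rules_path}")
    return cfg
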