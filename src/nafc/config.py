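"""Run configuration: YAML key-value files with validation and defaults."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

_VALID_FAMILIES = ("flat", "curve", "power", "oscil")


@dataclass
class ModelConfig:
    n: int = 3
    delta_mu: float = 1.0
    sigma: float = 1.0


@dataclass
class BoundaryConfig:
    family: str = "flat"
    theta: float = 0.6
    alpha: float = 0.0
    beta: float = 0.0
    # grid overrides for landscape sweeps; None -> default_axes()
    theta_axis: list | None = None
    alpha_axis: list | None = None
    beta_axis: list | None = None


@dataclass
class CostConfig:
    W: float = 1.0
    c: float | None = None
    cost_ratios: list = field(default_factory=lambda: [0.001, 0.04, 0.1])


@dataclass
class MCConfig:
    n_trials: int = 5_000
    max_steps: int = 10_000
    master_seed: int = 0


@dataclass
class AnalysisConfig:
    delta: float = 0.02
    spread: str = "std"
    min_count: int = 5
    classifier_z: float = 2.0
    hicks_ns: list = field(default_factory=lambda: [2, 3, 4])


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    boundary: BoundaryConfig = field(default_factory=BoundaryConfig)
    costs: CostConfig = field(default_factory=CostConfig)
    mc: MCConfig = field(default_factory=MCConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    source: str | None = None  # provenance: path the config was loaded from

    def validate(self) -> "RunConfig":
        errors = []
        if self.model.n < 2:
            errors.append(f"model.n must be >= 2 (got {self.model.n})")
        if not self.model.delta_mu > 0:
            errors.append(f"model.delta_mu must be positive (got {self.model.delta_mu})")
        if not self.model.sigma > 0:
            errors.append(f"model.sigma must be positive (got {self.model.sigma})")
        if self.boundary.family not in _VALID_FAMILIES:
            errors.append(
                f"boundary.family must be one of {_VALID_FAMILIES} (got {self.boundary.family!r})"
            )
        if not (0.0 < self.boundary.theta < 1.0):
            errors.append(f"boundary.theta must lie in (0, 1) (got {self.boundary.theta})")
        if not self.costs.W > 0:
            errors.append(f"costs.W must be positive (got {self.costs.W})")
        if self.costs.c is not None and self.costs.c < 0:
            errors.append(f"costs.c must be nonnegative (got {self.costs.c})")
        for r in self.costs.cost_ratios:
            if r < 0:
                errors.append(f"costs.cost_ratios entries must be nonnegative (got {r})")
        if self.mc.n_trials < 1:
            errors.append(f"mc.n_trials must be >= 1 (got {self.mc.n_trials})")
        if self.mc.max_steps < 1:
            errors.append(f"mc.max_steps must be >= 1 (got {self.mc.max_steps})")
        if self.analysis.delta < 0:
            errors.append(f"analysis.delta must be nonnegative (got {self.analysis.delta})")
        if self.analysis.spread not in ("std", "sem"):
            errors.append(f"analysis.spread must be 'std' or 'sem' (got {self.analysis.spread!r})")
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
        return self

    def cost_ratio(self) -> float:
        """Single c/W for subcommands that need one operating point."""
        if self.costs.c is not None:
            return self.costs.c / self.costs.W
        return float(self.costs.cost_ratios[0])

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("source", None)
        return d


_BLOCKS = {
    "model": ModelConfig,
    "boundary": BoundaryConfig,
    "costs": CostConfig,
    "mc": MCConfig,
    "analysis": AnalysisConfig,
}


def _build(data: dict, path: str | None) -> RunConfig:
    unknown = set(data) - set(_BLOCKS)
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _BLOCKS.items():
        block = data.get(name, {}) or {}
        if not isinstance(block, dict):
            raise ValueError(f"config block {name!r} must be a mapping")
        valid = {f for f in cls.__dataclass_fields__}
        bad = set(block) - valid
        if bad:
            raise ValueError(f"unknown keys in config block {name!r}: {sorted(bad)}")
        kwargs[name] = cls(**block)
    return RunConfig(**kwargs, source=path).validate()


def load_config(path) -> RunConfig:
    """Load and validate a YAML config, applying defaults for absent keys."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    data = yaml.safe_load(p.read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {p} must contain a key-value mapping")
    return _build(data, str(p))


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable digest of the semantic config content."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
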