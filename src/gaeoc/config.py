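"""Run configuration: YAML loading, validation and seed management.

All defaults are the study's standard settings: 10 folds, population size
from min(5k, 12·2^k), crossover rate 0.60, mutation rate max(0.01, 1/n),
tournament size 10, single-elite promotion, termination at 1000
generations / 50 stagnant generations / fitness 1.0.

A single global seed is expanded into named per-component streams
(balancing, folds, model training, GA, tie-breaking) so any stage can be
replayed in isolation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ga_search import GAConfig


class ConfigError(ValueError):
    """Raised for malformed or invalid run configuration files."""


_COMPONENT_OFFSETS = {"balancing": 11, "folds": 13, "train": 17, "ga": 19,
                      "ties": 23}


def component_seed(global_seed: int, component: str) -> int:
    """Deterministic per-component seed derived from the global seed."""
    if component not in _COMPONENT_OFFSETS:
        raise ConfigError(f"unknown seed component {component!r}")
    ss = np.random.SeedSequence([global_seed, _COMPONENT_OFFSETS[component]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Parameters for an end-to-end run, with study defaults."""

    label_column: str = "class"
    positive_label: str | None = None
    n_folds: int = 10
    pool_size: int = 20
    population_size: int | None = None
    crossover_rate: float = 0.60
    mutation_rate: float | None = None
    tournament_size: int = 10
    elite_count: int = 1
    max_generations: int = 1000
    stagnation_limit: int = 50
    optimum_fitness: float = 1.0
    crossover_mode: str = "per_mating"
    feature_mode: str = "none"          # none|plain|uab|iab|ueab
    alpha: int = 1
    beta: int = 0
    seed: int = 0
    version: str = "gaeoc-0.1.0"

    def ga_config(self, pool_size: int | None = None,
                  seed: int | None = None) -> GAConfig:
        return GAConfig(
            pool_size=pool_size if pool_size is not None else self.pool_size,
            population_size=self.population_size,
            crossover_rate=self.crossover_rate,
            mutation_rate_value=self.mutation_rate,
            tournament_size=self.tournament_size,
            elite_count=self.elite_count,
            max_generations=self.max_generations,
            stagnation_limit=self.stagnation_limit,
            optimum_fitness=self.optimum_fitness,
            seed=seed if seed is not None else component_seed(self.seed, "ga"),
            crossover_mode=self.crossover_mode,
        )

    def as_dict(self) -> dict:
        return asdict(self)


_VALIDATORS = {
    "crossover_rate": lambda v: 0.0 <= v <= 1.0,
    "mutation_rate": lambda v: v is None or 0.0 <= v <= 1.0,
    "n_folds": lambda v: v >= 2,
    "pool_size": lambda v: v >= 1,
    "elite_count": lambda v: v >= 0,
    "tournament_size": lambda v: v >= 1,
    "max_generations": lambda v: v >= 1,
    "stagnation_limit": lambda v: v >= 1,
    "alpha": lambda v: v >= 1,
    "beta": lambda v: v >= 0,
    "feature_mode": lambda v: v in ("none", "plain", "uab", "iab", "ueab"),
    "crossover_mode": lambda v: v in ("per_mating", "per_gene"),
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields all defaults.  Unknown keys and out-of-range
    values are rejected with field-level messages.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a YAML mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    config = RunConfig(**raw)
    errors = []
    for name, check in _VALIDATORS.items():
        value = getattr(config, name)
        if not check(value):
            errors.append(f"{name}={value!r} is out of range")
    if errors:
        raise ConfigError("; ".join(errors))
    return config


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.as_dict(), sort_keys=True))
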