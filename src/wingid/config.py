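"""Run configuration, persisted as a plain-text ``config.txt`` (key=value)."""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

from .errors import ConfigError


@dataclass(frozen=True)
class RunConfig:
    """Every knob of the train/validate pipeline, with the shipped defaults.

    ``n_harmonics=30`` gives the 117-feature descriptor; ``n_runs=5``
    repeated random 1:1 splits; 5-fold stratified CV drives the GA fitness.
    ``ce_formula`` selects the per-harmonic invariant ('granlund' or
    'power'); ``misid_denominator`` selects how the misidentification-rate
    divisor is interpreted ('per_species' or 'global').
    """

    n_harmonics: int = 30
    n_runs: int = 5
    split_ratio: float = 0.5
    cv_folds: int = 5
    ga_population: int = 20
    ga_generations: int = 30
    ga_crossover: float = 0.8
    ga_mutation: float = 0.1
    ga_log2c_min: float = -5.0
    ga_log2c_max: float = 15.0
    ga_log2gamma_min: float = -15.0
    ga_log2gamma_max: float = 3.0
    seed: int = 0
    ce_formula: str = "granlund"
    misid_denominator: str = "per_species"

    def __post_init__(self):
        if self.n_harmonics < 1:
            raise ConfigError("n_harmonics must be >= 1")
        if not (0.0 < self.split_ratio < 1.0):
            raise ConfigError("split_ratio must be in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        if self.n_runs < 1:
            raise ConfigError("n_runs must be >= 1")
        if self.ce_formula not in ("granlund", "power"):
            raise ConfigError("ce_formula must be 'granlund' or 'power'")
        if self.misid_denominator not in ("per_species", "global"):
            raise ConfigError("misid_denominator must be 'per_species' or 'global'")

    @property
    def n_features(self) -> int:
        return 4 * self.n_harmonics - 3


def save_config(cfg: RunConfig, path) -> None:
    """Write the configuration as sorted ``key=value`` lines."""
    lines = [f"{f.name}={getattr(cfg, f.name)}" for f in fields(cfg)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path, base: RunConfig | None = None) -> RunConfig:
    """Read ``key=value`` lines; unknown keys are rejected, missing keys default.

    Round-trips losslessly through :func:`save_config`.
    """
    base = base if base is not None else RunConfig()
    types = {f.name: f.type for f in fields(RunConfig)}
    casts = {"int": int, "float": float, "str": str}
    updates = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in types:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        try:
            updates[key] = casts[types[key]](value)
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for {key}: {value!r}") from exc
    return replace(base, **updates)
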