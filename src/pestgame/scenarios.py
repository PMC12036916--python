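"""Scenario configuration, seeded scenario generation and report batches."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .model import GameParameters, ParameterValidationError, validate_parameters

__all__ = [
    "Scenario",
    "ScenarioBatch",
    "BASELINE_VALUES",
    "baseline_parameters",
    "baseline_scenario",
    "default_ranges",
    "generate_scenarios",
    "load_scenario",
]

#: Baseline numerical scenario (unit costs default to 2; a 4-variant is
#: produced by ``baseline_scenario(c=4)``).  The gain parameters b1, b2 are
#: swept in the comparisons and default to 1 here.
BASELINE_VALUES: dict[str, float] = {
    "rho": 0.9,
    "delta": 0.1,
    "l": 1.0,
    "b1": 1.0,
    "b2": 1.0,
    "c1": 2.0,
    "c2": 2.0,
    "CO": 10.0,
    "a1": 2.0,
    "a2": 2.0,
    "cS": 3.0,
    "betaS": 1.5,
    "aS": 1.2,
    "bI": 2.5,
    "CI": 3.0,
    "x0_gov": 1.0,
    "x0_ent": 1.0,
}

OUTPUT_KINDS = ("equilibria", "trajectories", "comparisons", "regions")


class Scenario(BaseModel):
    """A named parameter set with optional sweeps and requested outputs."""

    model_config = ConfigDict(extra="forbid")

    name: str
    params: GameParameters
    sweep: Optional[dict[str, list[float]]] = None
    outputs: list[str] = Field(default_factory=lambda: ["equilibria", "comparisons"])
    notes: list[str] = Field(default_factory=list)

    @field_validator("outputs")
    @classmethod
    def _known_outputs(cls, v: list[str]) -> list[str]:
        unknown = set(v) - set(OUTPUT_KINDS)
        if unknown:
            raise ValueError(f"unknown outputs {sorted(unknown)}; allowed: {OUTPUT_KINDS}")
        return v

    @field_validator("sweep")
    @classmethod
    def _check_sweep(cls, v):
        if v is None:
            return v
        if not 1 <= len(v) <= 2:
            raise ValueError("sweep must name one or two parameters")
        fields = set(GameParameters.model_fields)
        for key, grid in v.items():
            if key not in fields:
                raise ValueError(f"swept parameter {key!r} is not a model parameter")
            if len(grid) == 0 or any(not np.isfinite(g) for g in grid):
                raise ValueError(f"sweep grid for {key!r} must be finite and non-empty")
            if not key.startswith("x0") and any(g <= 0 for g in grid):
                raise ValueError(f"sweep grid for {key!r} must be positive")
        return v


class ScenarioBatch(BaseModel):
    """Deterministic sampling request: identical (seed, n, ranges) give an
    identical batch."""

    model_config = ConfigDict(extra="forbid")

    seed: int
    n: int = Field(gt=0)
    ranges: Optional[dict[str, tuple[float, float]]] = None

    @field_validator("ranges")
    @classmethod
    def _check_ranges(cls, v):
        if v is None:
            return v
        fields = set(GameParameters.model_fields)
        for key, (lo, hi) in v.items():
            if key not in fields:
                raise ValueError(f"unknown parameter {key!r} in ranges")
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
                raise ValueError(f"range for {key!r} must be finite with lo <= hi")
            floor = 0.0 if key.startswith("x0") else None
            if floor is None and lo <= 0:
                raise ValueError(f"range for {key!r} must have a positive lower bound")
            if floor is not None and lo < floor:
                raise ValueError(f"range for {key!r} must have lower bound >= 0")
        return v


def baseline_parameters(c: float = 2.0) -> GameParameters:
    """Baseline parameter set with both unit costs set to ``c``."""
    values = dict(BASELINE_VALUES, c1=float(c), c2=float(c))
    return validate_parameters(values)


def baseline_scenario(c: float = 2.0) -> Scenario:
    return Scenario(name=f"baseline-c{c:g}", params=baseline_parameters(c))


def default_ranges() -> dict[str, tuple[float, float]]:
    """Per-parameter sampling intervals bracketing the baseline by [0.5x, 2x];
    the discount rate is capped at 1."""
    ranges = {k: (0.5 * v, 2.0 * v) for k, v in BASELINE_VALUES.items()}
    lo, hi = ranges["rho"]
    ranges["rho"] = (lo, min(hi, 1.0))
    return ranges


def generate_scenarios(batch: ScenarioBatch) -> list[Scenario]:
    """Sample ``batch.n`` valid scenarios, deterministically in the seed.

    Scenarios where the information-sharing gain reaches its cost
    (``bI >= CI``) are annotated, not rejected: the baseline has bI < CI but
    the model does not require it.
    """
    ranges = batch.ranges if batch.ranges is not None else default_ranges()
    ranges = dict(default_ranges(), **ranges)
    rng = np.random.default_rng(batch.seed)
    names = sorted(GameParameters.model_fields)  # stable draw order
    scenarios = []
    for i in range(batch.n):
        values = {name: float(rng.uniform(*ranges[name])) for name in names}
        params = validate_parameters(values)
        notes = []
        if params.bI >= params.CI:
            notes.append("bI >= CI: information-sharing gain exceeds its cost")
        scenarios.append(
            Scenario(name=f"seed{batch.seed}-{i:03d}", params=params, notes=notes)
        )
    return scenarios


def load_scenario(path: Union[str, Path]) -> Scenario:
    """Load a scenario from JSON or YAML (strict schema, unknown keys rejected)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterValidationError([f"{path}: expected a mapping"])
    if "params" not in data:  # bare parameter files are promoted to scenarios
        data = {"name": path.stem, "params": data}
    return Scenario(**data)
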