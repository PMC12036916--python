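"""Core model types: validated game parameters and the canonical reduction.

Two players (government, enterprise) manage forest pests and diseases under
one of three cooperation modes:

* ``A`` — individual action,
* ``S`` — scarce-resource sharing,
* ``I`` — information sharing.

Within each mode the two players' problems are decoupled: neither player's
state or control enters the other's payoff, so each (mode, player) pair
reduces to an independent infinite-horizon optimal-control problem with

* instantaneous payoff  ``(w*b + u0)*F - (c_eff/2)*F**2 + k + l*x``
* reputation dynamics   ``x' = a_eff*F - delta*x``

where ``F`` is the player's effort, ``b`` its own per-unit gain parameter
and ``x`` its reputation.  :func:`reduce_mode` produces the effective
coefficients ``(w, u0, c_eff, a_eff, k)`` for every pair.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "Mode",
    "Player",
    "GameParameters",
    "EffortProblem",
    "ParameterValidationError",
    "validate_parameters",
    "reduce_mode",
    "load_parameters",
]


class Mode(str, enum.Enum):
    """Cooperation mode: individual action, resource sharing, info sharing."""

    A = "A"
    S = "S"
    I = "I"


class Player(str, enum.Enum):
    GOVERNMENT = "government"
    ENTERPRISE = "enterprise"


class ParameterValidationError(ValueError):
    """Raised when a parameter set violates its sign/range constraints.

    Collects *every* violated constraint, one message per field.
    """

    def __init__(self, messages: list[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class GameParameters(BaseModel):
    """All model constants plus each player's initial reputation.

    Field names follow the model's symbols: ``b1/c1/a1`` belong to the
    government, ``b2/c2/a2`` to the enterprise; ``CO`` is the carbon-offset
    flow paid by the government to the enterprise; ``cS``/``betaS``/``aS``
    parameterize scarce-resource sharing and ``bI``/``CI`` information
    sharing.  All rates and flows are per unit time.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    rho: float = Field(gt=0, description="discount rate")
    delta: float = Field(gt=0, description="reputation decay rate")
    l: float = Field(gt=0, description="marginal long-run benefit of reputation")
    b1: float = Field(gt=0, description="government per-unit-effort gain")
    b2: float = Field(gt=0, description="enterprise per-unit-effort gain")
    c1: float = Field(gt=0, description="government quadratic cost coefficient")
    c2: float = Field(gt=0, description="enterprise quadratic cost coefficient")
    CO: float = Field(gt=0, description="carbon-offset flow, government to enterprise")
    a1: float = Field(gt=0, description="government per-unit-effort reputation gain")
    a2: float = Field(gt=0, description="enterprise per-unit-effort reputation gain")
    cS: float = Field(gt=0, description="extra government cost for resource sharing")
    betaS: float = Field(gt=0, description="scarce-resource helpfulness to enterprise")
    aS: float = Field(gt=0, description="extra government reputation from sharing")
    bI: float = Field(gt=0, description="gain increment from information sharing")
    CI: float = Field(gt=0, description="information-sharing cost flow")
    x0_gov: float = Field(ge=0, description="government initial reputation")
    x0_ent: float = Field(ge=0, description="enterprise initial reputation")

    @model_validator(mode="after")
    def _warn_large_discount(self) -> "GameParameters":
        # rho <= 1 is a modelling convention, not a mathematical requirement:
        # warn rather than reject.
        if self.rho > 1:
            warnings.warn(
                f"rho={self.rho} exceeds 1; values are still well defined "
                "but outside the model's stated range",
                stacklevel=2,
            )
        return self

    def x0(self, player: Player) -> float:
        return self.x0_gov if Player(player) is Player.GOVERNMENT else self.x0_ent

    def own_gain(self, player: Player) -> float:
        return self.b1 if Player(player) is Player.GOVERNMENT else self.b2

    def own_cost(self, player: Player) -> float:
        return self.c1 if Player(player) is Player.GOVERNMENT else self.c2

    def replace(self, **changes: float) -> "GameParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return validate_parameters(self.model_dump() | changes)


@dataclass(frozen=True)
class EffortProblem:
    """Canonical reduction of one (mode, player) pair.

    Attributes
    ----------
    w : float
        Multiplier on the player's own gain parameter ``b``.
    u0 : float
        Additive gain offset independent of ``b`` (carries ``bI``).
    c_eff : float
        Effective quadratic cost coefficient.
    a_eff : float
        Effective per-unit-effort reputation gain.
    k : float
        Fixed net transfer flow; negative means an outflow.
    """

    w: float
    u0: float
    c_eff: float
    a_eff: float
    k: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.c_eff > 0 and self.a_eff > 0):
            raise ParameterValidationError(
                ["EffortProblem requires w > 0, c_eff > 0 and a_eff > 0"]
            )

    def gain(self, b: float) -> float:
        """Effective linear gain coefficient ``w*b + u0``."""
        return self.w * b + self.u0

    def payoff_rate(self, F: float, x: float, b: float, l: float) -> float:
        """Instantaneous payoff at effort ``F`` and reputation ``x``."""
        return self.gain(b) * F - 0.5 * self.c_eff * F * F + self.k + l * x

    def drift(self, F: float, x: float, delta: float) -> float:
        """Reputation time-derivative ``a_eff*F - delta*x``."""
        return self.a_eff * F - delta * x


def validate_parameters(raw: Union[GameParameters, dict[str, Any]]) -> GameParameters:
    """Validate a parameter set, reporting every violated constraint.

    Accepts either an already-built :class:`GameParameters` (returned as-is,
    since construction validates) or a mapping of field names.  Unknown keys
    are rejected.
    """
    if isinstance(raw, GameParameters):
        return raw
    try:
        return GameParameters(**raw)
    except ValidationError as exc:
        messages = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<model>"
            messages.append(f"{loc}: {err['msg']}")
        raise ParameterValidationError(messages) from exc


def load_parameters(path: Union[str, Path]) -> GameParameters:
    """Load a parameter set from a JSON or YAML file (strict schema)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterValidationError([f"{path}: expected a mapping of fields"])
    return validate_parameters(data)


def reduce_mode(
    mode: Union[Mode, str], player: Union[Player, str], params: GameParameters
) -> EffortProblem:
    """Reduce a (mode, player) pair to its canonical effort problem.

    ============  =============  ====  ==========  ==========  =========
    pair          w              u0    c_eff       a_eff       k
    ============  =============  ====  ==========  ==========  =========
    A,gov         1              0     c1          a1          -CO
    A,ent         1              0     c2          a2          +CO
    S,gov         1              0     c1+cS       a1+aS       -CO
    S,ent         ln(e+betaS)    0     c2          a2          +CO
    I,gov         1              bI    c1          a1          -CI-CO
    I,ent         1              bI    c2          a2          -CI+CO
    ============  =============  ====  ==========  ==========  =========

    The carbon offset ``CO`` is a pure transfer (cancels across players);
    the information-sharing cost ``CI`` is borne by both.
    """
    mode = Mode(mode)
    player = Player(player)
    p = params

    if player is Player.GOVERNMENT:
        if mode is Mode.A:
            return EffortProblem(w=1.0, u0=0.0, c_eff=p.c1, a_eff=p.a1, k=-p.CO)
        if mode is Mode.S:
            return EffortProblem(
                w=1.0, u0=0.0, c_eff=p.c1 + p.cS, a_eff=p.a1 + p.aS, k=-p.CO
            )
        return EffortProblem(w=1.0, u0=p.bI, c_eff=p.c1, a_eff=p.a1, k=-p.CI - p.CO)

    if mode is Mode.A:
        return EffortProblem(w=1.0, u0=0.0, c_eff=p.c2, a_eff=p.a2, k=p.CO)
    if mode is Mode.S:
        return EffortProblem(
            w=math.log(math.e + p.betaS), u0=0.0, c_eff=p.c2, a_eff=p.a2, k=p.CO
        )
    return EffortProblem(w=1.0, u0=p.bI, c_eff=p.c2, a_eff=p.a2, k=-p.CI + p.CO)
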