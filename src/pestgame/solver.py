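"""Closed-form feedback equilibria via the linear value-function ansatz.

For each reduced problem the stationary optimality condition is

    rho*V(x) = max_F [ g*F - (c_eff/2)*F**2 + k + l*x + V'(x)*(a_eff*F - delta*x) ]

with effective gain ``g = w*b + u0``.  Payoff and dynamics are linear in the
reputation ``x``, so ``V(x) = m*x + n`` solves it exactly with

    m  = l / (rho + delta)
    F* = (g + a_eff*m) / c_eff            (constant, state-independent)
    n  = c_eff*F*^2 / (2*rho) + k / rho

Equivalently ``V = K + Q*(w*b + u)**2`` with ``K = m*x + k/rho``,
``Q = 1/(2*rho*c_eff)`` and ``u = u0 + a_eff*m`` — the value is a quadratic
in the player's own gain parameter, which is what the mode-comparison
analytics exploit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Union

from .model import EffortProblem, GameParameters, Mode, Player, reduce_mode

__all__ = [
    "EquilibriumSolution",
    "HJBResidual",
    "value_slope",
    "optimal_effort",
    "solve_value",
    "hjb_residual",
    "solve_pair",
]


@dataclass(frozen=True)
class EquilibriumSolution:
    """Closed-form equilibrium for one reduced problem at a given (b, x).

    ``value`` equals both ``m*x + n`` and ``K + Q*(w*b + u)**2`` identically.
    """

    F_star: float
    m: float
    n: float
    K: float
    Q: float
    w: float
    u: float
    b: float
    x: float

    @property
    def value(self) -> float:
        return self.K + self.Q * (self.w * self.b + self.u) ** 2

    def to_record(
        self, mode: Optional[Union[Mode, str]] = None, player: Optional[Union[Player, str]] = None
    ) -> dict:
        rec = {}
        if mode is not None:
            rec["mode"] = Mode(mode).value
        if player is not None:
            rec["player"] = Player(player).value
        rec.update(asdict(self))
        rec["value"] = self.value
        return rec


@dataclass(frozen=True)
class HJBResidual:
    """Residuals of the stationary optimality condition at a candidate (m, n, F)."""

    slope_residual: float
    const_residual: float


def value_slope(params: GameParameters) -> float:
    """Reputation-slope of the value function: l/(rho+delta), mode-independent."""
    return params.l / (params.rho + params.delta)


def optimal_effort(p: EffortProblem, b: float, params: GameParameters) -> float:
    """Optimal constant effort (g + a_eff*m)/c_eff with g = w*b + u0."""
    return (p.gain(b) + p.a_eff * value_slope(params)) / p.c_eff


def solve_value(
    p: EffortProblem, b: float, x: float, params: GameParameters
) -> EquilibriumSolution:
    """Solve the reduced problem, returning value coefficients and decomposition."""
    m = value_slope(params)
    F = optimal_effort(p, b, params)
    rho = params.rho
    n = p.c_eff * F * F / (2.0 * rho) + p.k / rho
    K = m * x + p.k / rho
    Q = 1.0 / (2.0 * rho * p.c_eff)
    u = p.u0 + p.a_eff * m
    return EquilibriumSolution(F_star=F, m=m, n=n, K=K, Q=Q, w=p.w, u=u, b=b, x=x)


def hjb_residual(
    p: EffortProblem,
    b: float,
    m: float,
    n: float,
    F: float,
    params: GameParameters,
) -> HJBResidual:
    """Residuals of the stationary condition for an arbitrary candidate.

    ``slope_residual`` is the coefficient of x in rho*V - RHS, i.e.
    ``m*(rho+delta) - l``; ``const_residual`` is the constant part
    ``rho*n - [g*F - (c_eff/2)F^2 + k + m*a_eff*F]``.  Both vanish exactly
    at the solved equilibrium.
    """
    slope = m * (params.rho + params.delta) - params.l
    hamiltonian = (
        p.gain(b) * F - 0.5 * p.c_eff * F * F + p.k + m * p.a_eff * F
    )
    const = params.rho * n - hamiltonian
    return HJBResidual(slope_residual=slope, const_residual=const)


def solve_pair(
    mode: Union[Mode, str],
    player: Union[Player, str],
    params: GameParameters,
    b: Optional[float] = None,
    x: Optional[float] = None,
) -> EquilibriumSolution:
    """Reduce and solve a (mode, player) pair in one step.

    ``b`` and ``x`` default to the player's own gain parameter and initial
    reputation from ``params``.
    """
    player = Player(player)
    p = reduce_mode(mode, player, params)
    if b is None:
        b = params.own_gain(player)
    if x is None:
        x = params.x0(player)
    return solve_value(p, b, x, params)
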