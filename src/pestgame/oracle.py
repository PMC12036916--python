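"""Brute-force numerical verification of the closed-form equilibria.

Under a constant effort ``F`` the reputation ODE is linear with the explicit
solution

    x(t) = a_eff*F/delta + (x0 - a_eff*F/delta) * exp(-delta*t)

so the discounted payoff integral can be evaluated by straight quadrature on
a uniform grid, independently of the HJB machinery.  A grid search over
constant efforts then provides an optimality check on F*.  Only constant
policies are searched: the solved feedback equilibrium is state-independent,
so the restriction is without loss for verification purposes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .model import EffortProblem, GameParameters

__all__ = [
    "Trajectory",
    "PayoffEstimate",
    "reputation_trajectory",
    "simulate",
    "discounted_payoff",
    "best_constant_effort_grid",
]

DEFAULT_DT = 1e-3


@dataclass(frozen=True)
class Trajectory:
    """Reputation path and (optionally) cumulative discounted payoff."""

    times: np.ndarray
    x_values: np.ndarray
    discounted_payoff: Optional[np.ndarray] = None

    def to_frame(self):
        import pandas as pd

        data = {"time": self.times, "x": self.x_values}
        if self.discounted_payoff is not None:
            data["discounted_payoff"] = self.discounted_payoff
        return pd.DataFrame(data)


@dataclass(frozen=True)
class PayoffEstimate:
    """Quadrature value of the discounted payoff with its tail bound."""

    value: float
    truncation_bound: float


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if times[0] != 0.0:
        raise ValueError("times must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


def reputation_trajectory(
    x0: float, F: float, a_eff: float, delta: float, times: Sequence[float]
) -> Trajectory:
    """Closed-form reputation path under constant effort.

    ``x(t) = xbar + (x0 - xbar)*exp(-delta*t)`` with steady state
    ``xbar = a_eff*F/delta``.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if F < 0:
        raise ValueError("F must be >= 0")
    times = _check_times(times)
    xbar = a_eff * F / delta
    x = xbar + (x0 - xbar) * np.exp(-delta * times)
    return Trajectory(times=times, x_values=x)


def _grid(T: float, dt: float) -> np.ndarray:
    n = int(np.ceil(T / dt))
    return np.linspace(0.0, T, n + 1)


def simulate(
    p: EffortProblem,
    b: float,
    x0: float,
    F: float,
    params: GameParameters,
    T: Optional[float] = None,
    dt: float = DEFAULT_DT,
) -> Trajectory:
    """Reputation path plus cumulative discounted payoff on a uniform grid."""
    from scipy.integrate import cumulative_trapezoid

    T, dt = _check_horizon(params, T, dt)
    times = _grid(T, dt)
    traj = reputation_trajectory(x0, F, p.a_eff, params.delta, times)
    integrand = np.exp(-params.rho * times) * (
        p.gain(b) * F - 0.5 * p.c_eff * F * F + p.k + params.l * traj.x_values
    )
    cum = cumulative_trapezoid(integrand, times, initial=0.0)
    return Trajectory(times=times, x_values=traj.x_values, discounted_payoff=cum)


def _check_horizon(
    params: GameParameters, T: Optional[float], dt: float, tail_tol: float = 1e-9
) -> tuple[float, float]:
    if T is None:
        T = 50.0 / params.rho
    if T <= 0 or np.exp(-params.rho * T) >= tail_tol:
        raise ValueError(
            f"horizon T={T} leaves discount tail exp(-rho*T) >= {tail_tol}; "
            "increase T"
        )
    if dt <= 0 or dt > 0.1 / (params.rho + params.delta):
        raise ValueError(
            f"step dt={dt} too coarse; require dt <= 0.1/(rho+delta)"
        )
    return float(T), float(dt)


def discounted_payoff(
    p: EffortProblem,
    b: float,
    x0: float,
    F: float,
    params: GameParameters,
    T: Optional[float] = None,
    dt: float = DEFAULT_DT,
) -> PayoffEstimate:
    """Trapezoid quadrature of the discounted payoff under constant effort.

    The tail beyond T is bounded by the maximum absolute integrand times the
    remaining discount mass exp(-rho*T)/rho.
    """
    T, dt = _check_horizon(params, T, dt)
    traj = simulate(p, b, x0, F, params, T=T, dt=dt)
    value = float(traj.discounted_payoff[-1])
    xbar = p.a_eff * F / params.delta
    x_max = max(abs(x0), abs(xbar))
    bound = (
        (abs(p.gain(b) * F) + 0.5 * p.c_eff * F * F + abs(p.k) + params.l * x_max)
        * np.exp(-params.rho * T)
        / params.rho
    )
    return PayoffEstimate(value=value, truncation_bound=float(bound))


def best_constant_effort_grid(
    p: EffortProblem,
    b: float,
    x0: float,
    params: GameParameters,
    grid: Sequence[float],
    T: Optional[float] = None,
    dt: float = 1e-2,
) -> float:
    """Grid effort maximizing the numerically integrated discounted payoff."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("effort grid must be non-empty")
    T, dt = _check_horizon(params, T, dt)
    times = _grid(T, dt)
    disc = np.exp(-params.rho * times)
    decay = np.exp(-params.delta * times)
    # vectorized over the grid: x(t; F) = xbar + (x0 - xbar) e^{-delta t}
    xbar = p.a_eff * grid / params.delta  # (nF,)
    x = xbar[:, None] + (x0 - xbar)[:, None] * decay[None, :]  # (nF, nt)
    flow = (
        (p.gain(b) * grid - 0.5 * p.c_eff * grid**2 + p.k)[:, None]
        + params.l * x
    )
    payoffs = np.trapezoid(disc[None, :] * flow, times, axis=1)
    return float(grid[int(np.argmax(payoffs))])
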