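"""Two-population growth/decay model of a confluent cell culture.

A small responsive sub-population P2 grows exponentially at rate ``r`` while
the large unresponsive pool P1 shrinks at the same rate:

    dP1/dt = -r P1,   dP2/dt = r P2,   dN/dt = (P2 - P1) r

with ``N = P1 + P2``.  When ``P1(0) > P2(0)`` the total size dips, reaches
its unique minimum at ``t = ln(P1₀/P2₀) / (2r)`` and recovers to its initial
value at ``t* = ln(P1₀/P2₀) / r``; the confluence constraint is expressed by
choosing ``r`` so that the recovery happens within a set period (two days by
default).  Times are in hours throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TwoPopParams",
    "Trajectory",
    "solve_trajectory",
    "recovery_time",
    "solve_rate",
    "n_minimum_time",
]


@dataclass(frozen=True)
class TwoPopParams:
    """Initial sizes of the two sub-populations and the shared rate (per hour)."""

    p1_0: float
    p2_0: float
    r: float

    def __post_init__(self) -> None:
        if self.p1_0 < 0 or self.p2_0 < 0:
            raise ValueError("initial sizes must be non-negative")
        if self.p1_0 + self.p2_0 <= 0:
            raise ValueError("at least one population must start non-empty")
        if self.r < 0:
            raise ValueError("rate must be non-negative")


@dataclass
class Trajectory:
    times: np.ndarray
    p1: np.ndarray
    p2: np.ndarray

    @property
    def n(self) -> np.ndarray:
        return self.p1 + self.p2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, "p1": self.p1, "p2": self.p2, "n": self.n})


def _rhs(state: np.ndarray, r: float) -> np.ndarray:
    return np.array([-r * state[0], r * state[1]])


def solve_trajectory(
    params: TwoPopParams,
    times: Sequence[float],
    method: str = "analytic",
    step_h: float = 0.01,
) -> Trajectory:
    """Evaluate the model at the requested times.

    ``analytic`` uses the closed forms ``P1(t) = P1₀ e^{-rt}``,
    ``P2(t) = P2₀ e^{rt}``; ``rk4`` integrates the system with the classical
    fourth-order Runge–Kutta scheme at step ``step_h`` (the step is shortened
    to land exactly on each requested time).
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(np.diff(t) < 0) or t[0] < 0:
        raise ValueError("times must be sorted ascending and start at or after 0")
    if method == "analytic":
        p1 = params.p1_0 * np.exp(-params.r * t)
        p2 = params.p2_0 * np.exp(params.r * t)
        return Trajectory(times=t, p1=p1, p2=p2)
    if method != "rk4":
        raise ValueError(f"unknown method {method!r}")
    if step_h <= 0:
        raise ValueError("step_h must be positive")
    state = np.array([params.p1_0, params.p2_0], dtype=float)
    now = 0.0
    p1_out, p2_out = [], []
    for target in t:
        span = target - now
        n_steps = max(int(np.ceil(span / step_h)), 0)
        h = span / n_steps if n_steps else 0.0
        for _ in range(n_steps):
            k1 = _rhs(state, params.r)
            k2 = _rhs(state + 0.5 * h * k1, params.r)
            k3 = _rhs(state + 0.5 * h * k2, params.r)
            k4 = _rhs(state + h * k3, params.r)
            state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        now = target
        p1_out.append(state[0])
        p2_out.append(state[1])
    return Trajectory(times=t, p1=np.array(p1_out), p2=np.array(p2_out))


def recovery_time(params: TwoPopParams) -> float | None:
    """Time ``t* > 0`` at which the total size returns to its initial value.

    With ``x = e^{r t*}``, ``N(t*) = N(0)`` reduces to
    ``P2₀ x² - (P1₀ + P2₀) x + P1₀ = 0`` which factors as
    ``(x - 1)(P2₀ x - P1₀)``; the root above one is ``x = P1₀/P2₀``, so
    ``t* = ln(P1₀/P2₀)/r``.  Returns ``None`` when ``P1₀ <= P2₀`` (the total
    never dips).
    """
    if params.r == 0:
        raise ValueError("recovery time is undefined for r = 0")
    if params.p1_0 <= params.p2_0 or params.p2_0 == 0:
        return None
    return float(np.log(params.p1_0 / params.p2_0) / params.r)


def solve_rate(p1_0: float, p2_0: float, target_recovery_h: float) -> float:
    """Rate at which the total size recovers exactly at ``target_recovery_h``."""
    if target_recovery_h <= 0:
        raise ValueError("target recovery time must be positive")
    if not (p1_0 > p2_0 > 0):
        raise ValueError("need p1_0 > p2_0 > 0: otherwise there is no dip to recover from")
    return float(np.log(p1_0 / p2_0) / target_recovery_h)


def n_minimum_time(params: TwoPopParams) -> float:
    """Location of the unique interior minimum of N(t) when P1₀ > P2₀.

    Setting ``dN/dt = r(P2 - P1) = 0`` gives
    ``t_min = ln(P1₀/P2₀)/(2r)`` — half the recovery time.
    """
    if params.r == 0:
        raise ValueError("t_min is undefined for r = 0")
    if params.p1_0 <= params.p2_0 or params.p2_0 == 0:
        raise ValueError("N(t) has no interior minimum unless p1_0 > p2_0 > 0")
    return float(np.log(params.p1_0 / params.p2_0) / (2.0 * params.r))
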