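"""Deterministic equilibrium and stability analysis of the binary models.

In the noiseless limit (infinite decision precision, no attitude
noise), a population splits into a class of actors (x = 1, e.g.
sharers) and non-actors (x = 0) at frequency p.  Each class's attitude
settles at the stationary point of the linear update given its constant
action, so the two classes separate by exactly alpha / (alpha + beta +
gamma F) — the relative weight of cognitive dissonance in attitude
formation.  Because p itself is free, the model possesses a line of
equilibria: a continuum of (p, attitude-distribution) states, each
stationary but only neutrally so (such structures are structurally
unstable, which is why the stochastic simulators relax around rather
than onto them).  This module reports stationarity under the
deterministic idealisation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Authority, ParameterError, PsychParams, action_utility_gap

__all__ = [
    "class_attitudes",
    "attitude_gap",
    "CornerStability",
    "corner_stability",
    "interior_equilibrium_set",
    "corner_perturbation_returns",
]


def _abgF(par: PsychParams, auth: Authority) -> float:
    denom = float(par.alpha + par.beta + par.gamma * auth.F)
    if denom <= 0.0:
        raise ParameterError("alpha + beta + gamma*F must be positive")
    return denom


def class_attitudes(
    p: float, par: PsychParams, auth: Authority
) -> tuple[float, float]:
    """Stationary attitudes of the actor and non-actor classes at frequency p.

    y_share = (alpha + beta p + gamma F G) / (alpha + beta + gamma F)
    y_not   = (beta p + gamma F G) / (alpha + beta + gamma F)

    Their difference is alpha / (alpha + beta + gamma F), independent
    of p and G.
    """
    denom = _abgF(par, auth)
    base = float(par.beta) * p + float(par.gamma) * auth.F * auth.G
    return (float(par.alpha) + base) / denom, base / denom


def attitude_gap(par: PsychParams, auth: Authority) -> float:
    """Stationary attitude difference between actors and non-actors."""
    return float(par.alpha) / _abgF(par, auth)


@dataclass(frozen=True)
class CornerStability:
    all_share_stable: bool
    none_share_stable: bool


def corner_stability(
    par: PsychParams, c: float, auth: Authority
) -> CornerStability:
    """Local stability of the two corner states (strict inequalities).

    Universal action (p = 1, attitudes at 1 for G = 1) is stable iff the
    joint pull of normative value, dissonance, and both conformities
    beats the material cost: the utility gap at (y = y_share(1), xbar=1)
    is positive, i.e. v + k1 + k2 + k3 F > c when G = 1.  Universal
    inaction is stable iff the gap at the non-actor stationary attitude
    with xbar = 0 is negative — it fails when the authority's grip on
    decisions (k3) or attitudes (gamma) is too strong.
    """
    y_share_1, _ = class_attitudes(1.0, par, auth)
    gap_at_one = float(action_utility_gap(y_share_1, 1.0, c, par, auth))
    _, y_not_0 = class_attitudes(0.0, par, auth)
    gap_at_zero = float(action_utility_gap(y_not_0, 0.0, c, par, auth))
    return CornerStability(
        all_share_stable=gap_at_one > 0.0,
        none_share_stable=gap_at_zero < 0.0,
    )


def interior_equilibrium_set(
    par: PsychParams,
    c: float,
    auth: Authority,
    grid: int = 1001,
) -> np.ndarray:
    """Grid approximation of the line of equilibria in p.

    A frequency p is (weakly) stationary when actors at their class
    attitude are content to act (gap >= 0) and non-actors content not to
    (gap <= 0).  At the endpoints only the class that exists is
    checked.  Returns the sorted grid values satisfying the conditions;
    the result is a union of grid intervals, possibly empty.
    """
    if grid < 2:
        raise ParameterError("grid must be >= 2")
    p = np.linspace(0.0, 1.0, grid)
    denom = _abgF(par, auth)
    base = float(par.beta) * p + float(par.gamma) * auth.F * auth.G
    y_share = (float(par.alpha) + base) / denom
    y_not = base / denom
    gap_share = np.asarray(action_utility_gap(y_share, p, c, par, auth))
    gap_not = np.asarray(action_utility_gap(y_not, p, c, par, auth))
    ok = (gap_share >= 0.0) & (gap_not <= 0.0)
    ok[0] = gap_not[0] <= 0.0
    ok[-1] = gap_share[-1] >= 0.0
    return p[ok]


def corner_perturbation_returns(
    par: PsychParams,
    c: float,
    auth: Authority,
    n: int = 200,
    rounds: int = 200,
    delta: float = 1e-3,
) -> bool:
    """Deterministic check that the universal-action corner is attracting.

    A homogeneous group of ``n`` agents starts at the corner (all act,
    attitudes at the corner's stationary value); one agent's attitude is
    nudged down by ``delta``.  Dynamics run with infinite decision
    precision and deterministic attitude updates (ties at a zero gap
    counted as not acting).  Returns True when the population is back at
    the corner (everyone acting, attitudes within delta of stationary)
    after ``rounds`` rounds.

    The perturbation is kept small because the model's line of
    equilibria passes near the corner: a large kick (e.g. forcing one
    agent's action) can legitimately strand the system on a nearby
    interior equilibrium even when the corner itself is locally stable.
    """
    y_corner, _ = class_attitudes(1.0, par, auth)
    y = np.full(n, y_corner)
    y[0] -= delta
    x = np.ones(n)
    p = 1.0
    denom = _abgF(par, auth)
    for _ in range(rounds):
        gap = np.asarray(action_utility_gap(y, p, c, par, auth))
        x = (gap > 0.0).astype(float)
        p = float(x.mean())
        y = y + (
            float(par.alpha) * (x - y)
            + float(par.beta) * (p - y)
            + float(par.gamma) * auth.F * (auth.G - y)
        )
        y = np.clip(y, 0.0, 1.0)
    return bool(p == 1.0 and np.all(np.abs(y - y_corner) <= delta))
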