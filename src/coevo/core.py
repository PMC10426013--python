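"""Core decision and attitude-update rules.

Individuals carry an action ``x`` and an attitude (personal norm) ``y``,
both on [0, 1].  In each round an individual chooses the action that
trades material payoff against three quadratic psychological costs:
cognitive dissonance (mismatch with the own attitude), conformity with
peers (mismatch with the mean peer action), and conformity with an
authority promoting action ``G`` with messaging efficiency ``F``:

    u(x) = pi(x) + v * V(x, y)
           - k1 (x - y)^2 - k2 (x - xbar)^2 - k3 F (x - G)^2

After acting, the attitude moves linearly toward the own action, the
peer mean, and the authority's message:

    y' = y + alpha (x - y) + beta (xbar - y) + gamma F (G - y) + eps

with eps ~ Normal(0, sigma^2), the whole update fired with probability
``u_y`` per round, and the result clipped back to [0, 1].

All functions broadcast over numpy arrays, so a whole population can be
advanced in one call.  The messaging efficiency ``F`` multiplies both
the decision weight ``k3`` and the attitude weight ``gamma``; the
published one-authority forms are recovered at ``F = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.special import expit

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "ParameterError",
    "AgentState",
    "PsychParams",
    "Authority",
    "NoiseSpec",
    "utility",
    "action_utility_gap",
    "choose_binary",
    "update_attitude",
    "update_attitude_detailed",
]


class ParameterError(ValueError):
    """A model parameter is outside its admissible domain."""


def _check_nonneg(name: str, value: ArrayLike) -> None:
    if np.any(np.asarray(value) < 0):
        raise ParameterError(f"{name} must be non-negative")


def _check_unit(name: str, value: ArrayLike) -> None:
    v = np.asarray(value)
    if np.any(v < 0) or np.any(v > 1):
        raise ParameterError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class AgentState:
    """One individual's current action and attitude, both on [0, 1]."""

    x: float
    y: float

    def __post_init__(self) -> None:
        _check_unit("x", self.x)
        _check_unit("y", self.y)


@dataclass(frozen=True)
class PsychParams:
    """Per-individual psychological sensitivities (all non-negative).

    ``v`` weights the normative value of the focal action; ``k1``-``k3``
    weight the quadratic decision costs (dissonance, peer conformity,
    authority conformity); ``alpha``-``gamma`` weight the linear
    attitude-update pulls toward own action, peer mean, and authority
    message.  Fields may be scalars or equally-shaped arrays, giving a
    heterogeneous population a single code path.
    """

    v: ArrayLike = 0.0
    k1: ArrayLike = 0.0
    k2: ArrayLike = 0.0
    k3: ArrayLike = 0.0
    alpha: ArrayLike = 0.0
    beta: ArrayLike = 0.0
    gamma: ArrayLike = 0.0

    def __post_init__(self) -> None:
        for name in ("v", "k1", "k2", "k3", "alpha", "beta", "gamma"):
            _check_nonneg(name, getattr(self, name))


@dataclass(frozen=True)
class Authority:
    """An authority promoting action ``G`` with messaging efficiency ``F``.

    The "authority" may be literal (elders, a propagandist) or a
    construct such as the stereotypical behaviour of an identity group;
    in the latter reading ``F`` is identity salience.
    """

    G: float = 1.0
    F: float = 1.0

    def __post_init__(self) -> None:
        _check_unit("G", self.G)
        _check_nonneg("F", self.F)


@dataclass(frozen=True)
class NoiseSpec:
    """Stochasticity of decisions and attitude updates.

    lam : decision precision of the logit choice rule (0 = coin flip,
        numpy.inf = deterministic best response).
    sigma : standard deviation of the Gaussian perturbation added to an
        attitude update.
    u_y : per-round probability that an individual's attitude update
        fires at all.
    """

    lam: float = 10.0
    sigma: float = 0.05
    u_y: float = 0.5

    def __post_init__(self) -> None:
        _check_nonneg("lam", self.lam)
        _check_nonneg("sigma", self.sigma)
        _check_unit("u_y", self.u_y)


def utility(
    x: ArrayLike,
    y: ArrayLike,
    xbar: ArrayLike,
    pi_x: ArrayLike,
    norm_x: ArrayLike,
    params: PsychParams,
    auth: Authority,
) -> ArrayLike:
    """Utility of taking action ``x``.

    ``pi_x`` is the material payoff of ``x`` and ``norm_x`` its
    normative value (weighted by ``params.v``); the three quadratic
    terms penalise mismatch with the own attitude ``y``, the peer mean
    ``xbar``, and the authority's promoted action.
    """
    x = np.asarray(x, dtype=float)
    return (
        pi_x
        + params.v * np.asarray(norm_x, dtype=float)
        - params.k1 * (x - y) ** 2
        - params.k2 * (x - xbar) ** 2
        - params.k3 * auth.F * (x - auth.G) ** 2
    )


def action_utility_gap(
    y: ArrayLike,
    xbar: ArrayLike,
    c: ArrayLike,
    params: PsychParams,
    auth: Authority,
) -> ArrayLike:
    """Utility difference u(x=1) - u(x=0) for a binary action.

    Acting (x=1) costs material value ``c`` and yields normative value
    ``v * y``; the quadratic costs collapse to the linear form

        du = -c + v y + k1 (2y - 1) + k2 (2 xbar - 1) + k3 F (2G - 1)

    whose sign is the deterministic best response.
    """
    y = np.asarray(y, dtype=float)
    xbar = np.asarray(xbar, dtype=float)
    return (
        -np.asarray(c, dtype=float)
        + params.v * y
        + params.k1 * (2.0 * y - 1.0)
        + params.k2 * (2.0 * xbar - 1.0)
        + params.k3 * auth.F * (2.0 * auth.G - 1.0)
    )


def choose_binary(
    delta_u: ArrayLike,
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> ArrayLike:
    """Stochastic (logit / quantal-response) binary choice.

    Returns 1 with probability ``1 / (1 + exp(-lam * delta_u))``.
    ``lam = 0`` is a fair coin; ``lam = inf`` is the deterministic sign
    of ``delta_u`` with exact ties resolved by a fair coin.  One uniform
    variate per element is consumed from ``rng``.
    """
    du = np.asarray(delta_u, dtype=float)
    if np.isinf(noise.lam):
        p = np.where(du > 0.0, 1.0, np.where(du < 0.0, 0.0, 0.5))
    else:
        p = expit(noise.lam * du)
    draw = rng.random(size=du.shape)
    out = (draw < p).astype(int)
    return out if du.shape else int(out)


def update_attitude_detailed(
    y: ArrayLike,
    x: ArrayLike | None,
    xbar: ArrayLike,
    params: PsychParams,
    auth: Authority,
    noise: NoiseSpec,
    rng: np.random.Generator,
    acted: ArrayLike | None = None,
):
    """Attitude update returning bookkeeping flags.

    Returns ``(y_next, updated, clipped)`` where ``updated`` marks the
    elements whose update gate (probability ``u_y``) fired and
    ``clipped`` marks updates that hit the [0, 1] boundary.

    The dissonance pull ``alpha (x - y)`` requires an action taken this
    round: pass ``x=None`` to drop it everywhere, or a boolean mask
    ``acted`` to drop it for individuals who faced no decision (their
    peer and authority pulls still apply).

    RNG contract: consumes one uniform (gate) then one normal (noise)
    variate per element, in that order, regardless of parameter values.
    """
    scalar = np.ndim(y) == 0
    y = np.atleast_1d(np.asarray(y, dtype=float))
    xbar = np.broadcast_to(np.asarray(xbar, dtype=float), y.shape)

    increment = params.beta * (xbar - y) + params.gamma * auth.F * (auth.G - y)
    if x is not None:
        x_arr = np.broadcast_to(np.asarray(x, dtype=float), y.shape)
        dissonance = params.alpha * (x_arr - y)
        if acted is not None:
            dissonance = np.where(np.broadcast_to(acted, y.shape), dissonance, 0.0)
        increment = increment + dissonance

    gate = rng.random(size=y.shape) < noise.u_y
    eps = rng.normal(0.0, 1.0, size=y.shape) * noise.sigma

    raw = y + increment + eps
    proposed = np.clip(raw, 0.0, 1.0)
    y_next = np.where(gate, proposed, y)
    clipped = gate & (raw != proposed)
    if scalar:
        return float(y_next[0]), bool(gate[0]), bool(clipped[0])
    return y_next, gate, clipped


def update_attitude(
    y: ArrayLike,
    x: ArrayLike | None,
    xbar: ArrayLike,
    params: PsychParams,
    auth: Authority,
    noise: NoiseSpec,
    rng: np.random.Generator,
    acted: ArrayLike | None = None,
) -> ArrayLike:
    """Linear attitude update toward own action, peer mean, and authority.

    Convenience wrapper over :func:`update_attitude_detailed` returning
    only the new attitude(s), clipped to [0, 1].
    """
    y_next, _, _ = update_attitude_detailed(y, x, xbar, params, auth, noise, rng, acted)
    return y_next
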