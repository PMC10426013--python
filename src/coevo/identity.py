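"""Social identity and altruism: the Dictator-game application.

The "authority" here is imaginary: the identity group of the decision
maker.  ``G`` is the stereotypical donation associated with that
identity and ``F`` its salience (e.g. raised by priming).  A dictator
splits an endowment of value ``b``, donating share ``x`` and keeping
material payoff b(1 - x); peers are absent (dyadic interactions, no
information about others), so the k2/beta conformity terms drop out.

Given attitude y, the quadratic utility has the interior best response

    x = eps_x * y + (1 - eps_x) * G - b_bar,      clipped to [0, 1],

with eps_x = k1 / (k1 + k3 F) the relative strength of cognitive
dissonance in decisions and b_bar = b / (2 (k1 + k3 F)) the strength of
the material pull.  Coupling this with the noiseless attitude update
(beta = 0) gives, for F > 0, the joint equilibrium

    x* = G - b_bar / (1 - eps_x eps_y),
    y* = G - eps_y * b_bar / (1 - eps_x eps_y),

with eps_y = alpha / (alpha + gamma F), so G - y* = eps_y (G - x*):
attitudes sit closer to the group standard than actions do, and both
move toward G as salience F rises.  Without priming (F = 0) the
attitude chases the action and both decay to zero — donations vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Authority, NoiseSpec, ParameterError, update_attitude_detailed, PsychParams

__all__ = [
    "DictatorParams",
    "DictatorEquilibrium",
    "best_response_donation",
    "priming_gradient",
    "dictator_equilibrium",
    "iterate_dictator",
]


@dataclass(frozen=True)
class DictatorParams:
    """Parameters of the Dictator application.

    b is the endowment value; k1, k3 the decision weights on dissonance
    and identity standard; alpha, gamma the corresponding attitude
    weights; auth carries the stereotypical donation G and salience F.
    """

    b: float = 1.0
    k1: float = 1.0
    k3: float = 1.0
    alpha: float = 1.0
    gamma: float = 1.0
    auth: Authority = field(default_factory=lambda: Authority(G=1.0, F=1.0))

    def __post_init__(self) -> None:
        for name in ("b", "k1", "k3", "alpha", "gamma"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @property
    def kx(self) -> float:
        """Total quadratic decision weight k1 + k3 F."""
        return self.k1 + self.k3 * self.auth.F

    @property
    def eps_x(self) -> float:
        if self.kx == 0:
            raise ParameterError("k1 + k3*F must be positive")
        return self.k1 / self.kx

    @property
    def eps_y(self) -> float:
        ky = self.alpha + self.gamma * self.auth.F
        if ky == 0:
            raise ParameterError("alpha + gamma*F must be positive")
        return self.alpha / ky

    @property
    def b_bar(self) -> float:
        if self.kx == 0:
            raise ParameterError("k1 + k3*F must be positive")
        return self.b / (2.0 * self.kx)

    def psych(self) -> PsychParams:
        """The equivalent general parameter set (k2 = beta = 0, v = 0)."""
        return PsychParams(
            k1=self.k1, k3=self.k3, alpha=self.alpha, gamma=self.gamma
        )


def best_response_donation(y, par: DictatorParams):
    """Utility-maximising donation share given attitude ``y``.

    Maximises b(1 - x) - k1 (x - y)^2 - k3 F (x - G)^2 over [0, 1];
    broadcasts over arrays of ``y``.  Raises if k1 + k3 F = 0 (utility
    linear in x, no interior optimum).
    """
    ex, bb, G = par.eps_x, par.b_bar, par.auth.G
    x = ex * np.asarray(y, dtype=float) + (1.0 - ex) * G - bb
    out = np.clip(x, 0.0, 1.0)
    return float(out) if np.ndim(y) == 0 else out


def priming_gradient(y: float, par: DictatorParams, with_flag: bool = False):
    """Derivative of the best-response donation with respect to salience F.

    At an interior optimum, dx/dF = k3 (k1 (G - y) + b/2) / (k1 + k3 F)^2:
    priming raises the donation iff the group standard G is large enough
    relative to the attitude (k1 (G - y) + b/2 > 0).  When the best
    response is clipped, 0.0 is returned and the boundary flag set.
    """
    ex, bb, G = par.eps_x, par.b_bar, par.auth.G
    interior_x = ex * y + (1.0 - ex) * G - bb
    boundary = not (0.0 < interior_x < 1.0)
    if boundary:
        grad = 0.0
    else:
        grad = par.k3 * (par.k1 * (G - y) + par.b / 2.0) / par.kx**2
    return (grad, boundary) if with_flag else grad


@dataclass(frozen=True)
class DictatorEquilibrium:
    """Joint action-attitude equilibrium and its composite parameters."""

    x_star: float
    y_star: float
    eps_x: float
    eps_y: float
    b_bar: float
    boundary: bool
    regime: str  # 'interior', 'boundary', or 'decay'


def dictator_equilibrium(par: DictatorParams) -> DictatorEquilibrium:
    """Closed-form fixed point of best response + noiseless attitude update.

    For F > 0 the interior equilibrium is x* = G - b_bar/(1 - eps_x eps_y)
    and y* = G - eps_y b_bar/(1 - eps_x eps_y); if it falls below 0 the
    donation is clipped and the attitude settles at (1 - eps_y) G (the
    stationary attitude over x = 0), flagged as a boundary case.  For
    F = 0 there is no interior equilibrium: with b > 0 the dynamics
    decay to (0, 0) ('decay' regime).
    """
    G, F = par.auth.G, par.auth.F
    if F == 0.0:
        if par.b > 0.0:
            return DictatorEquilibrium(0.0, 0.0, par.eps_x, 1.0, par.b_bar,
                                       boundary=True, regime="decay")
        # b = 0, no priming: x = y is neutrally stable wherever it starts
        return DictatorEquilibrium(np.nan, np.nan, par.eps_x, 1.0, 0.0,
                                   boundary=False, regime="decay")
    ex, ey, bb = par.eps_x, par.eps_y, par.b_bar
    denom = 1.0 - ex * ey
    x_star = G - bb / denom
    y_star = G - ey * bb / denom
    if x_star < 0.0:
        return DictatorEquilibrium(0.0, (1.0 - ey) * G, ex, ey, bb,
                                   boundary=True, regime="boundary")
    return DictatorEquilibrium(x_star, y_star, ex, ey, bb,
                               boundary=False, regime="interior")


def iterate_dictator(
    y0: float,
    par: DictatorParams,
    noise: Optional[NoiseSpec] = None,
    T: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Iterate best response and attitude update for ``T`` rounds.

    Actions are deterministic best responses (no logit noise in this
    application); stochasticity enters only through the attitude noise
    sd and update gate of ``noise`` (default: deterministic, sigma = 0,
    u_y = 1).  Returns an array of shape (T, 2) with columns (x, y).
    With sigma = 0 and F > 0 the pair converges to
    :func:`dictator_equilibrium`; with F = 0 and b > 0 the attitude
    decays monotonically to 0.
    """
    if noise is None:
        noise = NoiseSpec(lam=np.inf, sigma=0.0, u_y=1.0)
    if rng is None:
        rng = np.random.default_rng(0)
    psych = par.psych()
    out = np.empty((T, 2))
    y = float(y0)
    for t in range(T):
        x = best_response_donation(y, par)
        y = float(
            update_attitude_detailed(
                y, x, 0.0, psych, par.auth, noise, rng
            )[0]
        )
        out[t] = (x, y)
    return out
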