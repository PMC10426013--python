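"""Population construction: heterogeneous parameters and initial attitudes.

Between-individual variation in psychological sensitivities is drawn
from the parameter-free "broken-stick" distribution: break the unit
interval at two independent Uniform(0,1) points and use the three
segment lengths.  One draw assigns the decision weights (k1, k2, k3),
an independent draw assigns the attitude weights (alpha, beta, gamma),
so each triple sums to one and each component has mean 1/3.

Initial attitudes default to a log-normal distribution parameterised by
its mean and standard deviation on the attitude scale (moment-matched,
then clipped to [0, 1]); uniform and point-mass alternatives are
provided for controlled experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import ParameterError, PsychParams

__all__ = [
    "InitAttitudes",
    "PopulationSpec",
    "broken_stick",
    "draw_agent_params",
    "initial_attitudes",
    "agent_table",
]


@dataclass(frozen=True)
class InitAttitudes:
    """Initial-attitude distribution: 'lognormal', 'uniform' or 'point'.

    For 'lognormal', ``mean`` and ``sd`` are the moments of the attitude
    itself (before clipping to [0, 1]), not of its logarithm.  'uniform'
    ignores both; 'point' uses ``value``.
    """

    dist: str = "lognormal"
    mean: float = 0.2
    sd: float = 0.1
    value: float = 0.2

    def __post_init__(self) -> None:
        if self.dist not in ("lognormal", "uniform", "point"):
            raise ParameterError(f"unknown attitude distribution {self.dist!r}")
        if self.dist == "lognormal" and (self.mean <= 0 or self.sd <= 0):
            raise ParameterError("lognormal mean and sd must be positive")
        if self.dist == "point" and not 0.0 <= self.value <= 1.0:
            raise ParameterError("point-mass attitude must lie in [0, 1]")


@dataclass(frozen=True)
class PopulationSpec:
    """Structure and sampling scheme of the agent population.

    ``param_scheme`` is 'broken_stick' (heterogeneous, parameter-free)
    or 'fixed' (homogeneous at ``fixed``).  ``v`` is the normative-value
    weight, held constant across agents in either scheme.
    """

    n_groups: int = 100
    group_size: int = 10
    init_attitude: InitAttitudes = field(default_factory=InitAttitudes)
    param_scheme: str = "broken_stick"
    v: float = 1.0
    fixed: Optional[PsychParams] = None

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.group_size < 1:
            raise ParameterError("n_groups and group_size must be >= 1")
        if self.param_scheme not in ("broken_stick", "fixed"):
            raise ParameterError(f"unknown param_scheme {self.param_scheme!r}")
        if self.param_scheme == "fixed" and self.fixed is None:
            raise ParameterError("param_scheme 'fixed' requires fixed parameter values")
        _ = PsychParams(v=self.v)  # validates v >= 0

    @property
    def n(self) -> int:
        return self.n_groups * self.group_size

    def to_dict(self) -> dict:
        init = self.init_attitude
        d: dict = {
            "n_groups": self.n_groups,
            "group_size": self.group_size,
            "param_scheme": self.param_scheme,
            "v": self.v,
            "init_attitude": {
                "dist": init.dist, "mean": init.mean,
                "sd": init.sd, "value": init.value,
            },
        }
        if self.fixed is not None:
            f = self.fixed
            d["fixed"] = {
                "k1": float(f.k1), "k2": float(f.k2), "k3": float(f.k3),
                "alpha": float(f.alpha), "beta": float(f.beta),
                "gamma": float(f.gamma),
            }
        return d


def broken_stick(rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Segment lengths of the unit interval broken at two uniform points.

    Returns shape (3,) for ``size=None`` else (size, 3); segments are in
    left-to-right order, non-negative, and sum to 1.  Each component is
    exchangeable with marginal mean 1/3.
    """
    n = 1 if size is None else size
    cuts = np.sort(rng.random(size=(n, 2)), axis=1)
    parts = np.column_stack([cuts[:, 0], cuts[:, 1] - cuts[:, 0], 1.0 - cuts[:, 1]])
    return parts[0] if size is None else parts


def draw_agent_params(
    spec: PopulationSpec,
    rng: np.random.Generator,
    n: int | None = None,
) -> PsychParams:
    """Draw sensitivities for ``n`` agents (default: the spec's population).

    Under 'broken_stick', (k1, k2, k3) and (alpha, beta, gamma) come
    from independent broken-stick draws per agent, so each triple sums
    to exactly 1; ``v`` is constant at ``spec.v``.  Under 'fixed', every
    agent gets ``spec.fixed`` (with ``v`` taken from the spec).
    """
    n = spec.n if n is None else n
    if spec.param_scheme == "fixed":
        f = spec.fixed
        ones = np.ones(n)
        return PsychParams(
            v=spec.v * ones,
            k1=f.k1 * ones, k2=f.k2 * ones, k3=f.k3 * ones,
            alpha=f.alpha * ones, beta=f.beta * ones, gamma=f.gamma * ones,
        )
    ks = broken_stick(rng, size=n)
    abg = broken_stick(rng, size=n)
    return PsychParams(
        v=spec.v * np.ones(n),
        k1=ks[:, 0], k2=ks[:, 1], k3=ks[:, 2],
        alpha=abg[:, 0], beta=abg[:, 1], gamma=abg[:, 2],
    )


def initial_attitudes(
    n: int,
    spec: PopulationSpec | InitAttitudes,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample ``n`` initial attitudes in [0, 1].

    The log-normal is parameterised so that the *unclipped* draw has the
    requested mean and standard deviation: with m, s the requested
    moments, sigma^2 = log(1 + s^2/m^2) and mu = log(m) - sigma^2 / 2.
    Draws above 1 are clipped.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    init = spec.init_attitude if isinstance(spec, PopulationSpec) else spec
    if init.dist == "point":
        return np.full(n, init.value)
    if init.dist == "uniform":
        return rng.random(n)
    s2 = np.log1p((init.sd / init.mean) ** 2)
    mu = np.log(init.mean) - s2 / 2.0
    return np.clip(rng.lognormal(mean=mu, sigma=np.sqrt(s2), size=n), 0.0, 1.0)


def agent_table(spec: PopulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Fixture generator: a full agent table as a tidy DataFrame.

    Columns: agent_id, group_id, v, k1, k2, k3, alpha, beta, gamma, y0.
    Consumes parameter draws first, then attitude draws.
    """
    n = spec.n
    params = draw_agent_params(spec, rng, n)
    y0 = initial_attitudes(n, spec, rng)
    group = np.repeat(np.arange(spec.n_groups), spec.group_size)
    return pd.DataFrame(
        {
            "agent_id": np.arange(n),
            "group_id": group,
            "v": np.broadcast_to(params.v, (n,)),
            "k1": params.k1, "k2": params.k2, "k3": params.k3,
            "alpha": params.alpha, "beta": params.beta, "gamma": params.gamma,
            "y0": y0,
        }
    )
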