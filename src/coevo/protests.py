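"""Well-mixed model of political protest under propaganda.

Extends the classical preference-falsification account of unanticipated
revolutions, in which a public action can diverge from a private
preference: each individual either joins the protest (x = 1) or
acquiesces (x = 0).  Material
payoffs and normative value are absent; the decision trades cognitive
dissonance (integrity), conformity with the observed frequency of
protesters (reputation), and psychological pressure from one or more
authorities — a revolutionary leader promotes G = 1, the government
G = 0, each with its own propaganda efficiency F_i.

Two departures from the classical model:

* attitudes are dynamic — after acting and observing peers, individuals
  update ``y`` — unless ``attitudes_fixed`` is set, which recovers the
  constant-attitude classic as the alpha = beta = gamma = 0 limit of
  the same code path;
* several authorities act at once.  Because both the quadratic decision
  costs and the linear attitude pulls are additive, a list of
  authorities is mathematically equivalent to the single authority
  G* = sum(F_i G_i) / sum(F_i), F* = sum(F_i); the simulator composes
  the list at setup, so a multi-authority run and its composed
  single-authority counterpart consume identical random draws and are
  bit-identical.

Everyone starts acquiescent (p0 = 0).  Decisions use the previous
round's protest frequency; attitude updates use the frequency realised
this round.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    Authority,
    NoiseSpec,
    ParameterError,
    PsychParams,
    action_utility_gap,
    choose_binary,
    update_attitude_detailed,
)
from .sampling import InitAttitudes, PopulationSpec, draw_agent_params, initial_attitudes
from .trajectory import Trajectory

__all__ = [
    "ProtestConfig",
    "ProtestState",
    "compose_authorities",
    "protest_step",
    "run_protests",
]


def compose_authorities(auths: Sequence[Authority]) -> Authority:
    """Collapse several authorities into the equivalent single one.

    G* = sum(F_i G_i) / sum(F_i) and F* = sum(F_i): completing the
    square in the summed quadratic costs shows the two formulations
    differ only by an x-independent constant, and the summed linear
    attitude pulls are identical.  A single authority is returned
    unchanged; an empty list (or all-zero efficiencies) composes to the
    inert Authority(G=0, F=0).
    """
    auths = list(auths)
    if len(auths) == 1:
        return auths[0]
    F_total = float(sum(a.F for a in auths))
    if F_total == 0.0:
        return Authority(G=0.0, F=0.0)
    G_star = float(sum(a.F * a.G for a in auths)) / F_total
    return Authority(G=G_star, F=F_total)


@dataclass(frozen=True)
class ProtestConfig:
    """Configuration of a protest run.

    Defaults follow the reference configuration: n = 1000, logit
    precision 10, attitude noise sd 0.05, update probability 0.5,
    lognormal initial attitudes (mean 0.2, sd 0.1), broken-stick
    sensitivities.  ``v`` defaults to 0 (no normative value of
    protesting) and the material cost is 0, the classical reduction.
    """

    n: int = 1000
    auths: tuple[Authority, ...] = (Authority(G=1.0, F=1.0),)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    pop: PopulationSpec = field(
        default_factory=lambda: PopulationSpec(n_groups=1, group_size=1000, v=0.0)
    )
    attitudes_fixed: bool = False
    T: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError("n must be >= 1")
        if self.T < 1:
            raise ParameterError("T must be >= 1")
        if len(self.auths) == 0:
            raise ParameterError("at least one authority required (use F=0 for none)")

    def to_dict(self) -> dict:
        return {
            "model": "protests",
            "n": self.n,
            "T": self.T,
            "seed": self.seed,
            "attitudes_fixed": self.attitudes_fixed,
            "authorities": [{"G": a.G, "F": a.F} for a in self.auths],
            "noise": {
                "lam": self.noise.lam, "sigma": self.noise.sigma,
                "u_y": self.noise.u_y,
            },
            "population": self.pop.to_dict(),
        }


@dataclass
class ProtestState:
    """Population state: attitudes, last actions, current frequency."""

    y: np.ndarray
    x: np.ndarray
    p: float
    params: PsychParams


def init_protest_state(
    cfg: ProtestConfig,
    rng: np.random.Generator,
    y0: Optional[np.ndarray] = None,
) -> ProtestState:
    """Everyone acquiescent (x = 0, p = 0) with sampled attitudes."""
    params = draw_agent_params(cfg.pop, rng, cfg.n)
    if y0 is None:
        y0 = initial_attitudes(cfg.n, cfg.pop, rng)
    return ProtestState(
        y=np.asarray(y0, dtype=float).copy(),
        x=np.zeros(cfg.n, dtype=int),
        p=0.0,
        params=params,
    )


def protest_step(
    state: ProtestState,
    cfg: ProtestConfig,
    rng: np.random.Generator,
    _auth: Optional[Authority] = None,
    _record: Optional[list] = None,
) -> ProtestState:
    """One round: all decide against last round's p, then update attitudes.

    The utility gap is k1(2y-1) + k2(2p-1) + k3 F*(2G*-1) (plus v·y if a
    nonzero normative weight is configured); everyone acts, so the
    dissonance pull uses the own fresh action.  With ``attitudes_fixed``
    the update is skipped entirely and no gate/noise draws are consumed.
    """
    auth = compose_authorities(cfg.auths) if _auth is None else _auth
    p_prev = state.p
    du = action_utility_gap(state.y, p_prev, 0.0, state.params, auth)
    x_new = choose_binary(du, cfg.noise, rng)
    p_new = float(np.mean(x_new))

    if cfg.attitudes_fixed:
        y_new = state.y
    else:
        y_new, updated, clipped = update_attitude_detailed(
            state.y, x_new, p_new, state.params, auth, cfg.noise, rng
        )
        if _record is not None:
            _record.append((state.y, x_new, p_prev, p_new, y_new, updated, clipped))
    return ProtestState(y=y_new, x=x_new, p=p_new, params=state.params)


def run_protests(cfg: ProtestConfig, record: Optional[list] = None) -> Trajectory:
    """Simulate ``cfg.T`` rounds of the protest model.

    ``record``, if given, collects per-round tuples used by the panel
    builder in :mod:`coevo.inference`.  Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    auth = compose_authorities(cfg.auths)
    state = init_protest_state(cfg, rng)

    records = np.empty((cfg.T, 4))
    for t in range(cfg.T):
        state = protest_step(state, cfg, rng, _auth=auth, _record=record)
        records[t] = (t, state.p, state.y.mean(), state.y.std())

    data = pd.DataFrame(records, columns=["t", "p", "y_mean", "y_sd"])
    data["t"] = data["t"].astype(int)
    n = cfg.n
    final = pd.DataFrame(
        {
            "agent_id": np.arange(n),
            "group_id": np.zeros(n, dtype=int),
            "x": state.x,
            "y": state.y,
            "v": np.broadcast_to(state.params.v, (n,)),
            "k1": state.params.k1, "k2": state.params.k2, "k3": state.params.k3,
            "alpha": state.params.alpha, "beta": state.params.beta,
            "gamma": state.params.gamma,
        }
    )
    meta = {"model": "protests", "seed": cfg.seed, "config": cfg.to_dict()}
    return Trajectory(data=data, final=final, meta=meta)
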