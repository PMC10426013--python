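"""Metapopulation model of food sharing in small-scale societies.

A large number of small hunter-gatherer groups exchange migrants at
rate ``m`` (island model).  Each round, every individual succeeds in
hunting with probability ``s``; successful hunters decide whether to
share the kill (x = 1, losing food of value ``c``, gaining normative
value ``v * y``) or keep it (x = 0), by a logit choice over the binary
utility gap.  Peers who share are assumed to disapprove of non-sharers,
which enters through the conformity weight ``k2`` — sharers bear no
extra cost of expressing disapproval.  An informal authority (elders,
prestigious figures) inculcates sharing: G = 1 with efficiency ``F``.

The per-group sharing frequency ``p`` observed by agents is the
fraction of sharers among the most recent round's successful hunters in
their own group (initialised to 0: nobody shares at the start).  After
decisions, every agent may update its attitude; hunters feel dissonance
toward their own action while non-hunters are moved only by peers and
authority.

Round order: hunt -> decide -> refresh group p -> update attitudes ->
migrate.  One seeded generator drives all draws in the fixed order
hunting, choice, update gate, attitude noise, migration, so runs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

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
from .sampling import PopulationSpec, draw_agent_params, initial_attitudes
from .trajectory import Trajectory

__all__ = [
    "Metapopulation",
    "SharingConfig",
    "init_metapopulation",
    "sharing_step",
    "migrate",
    "run_sharing",
]


@dataclass
class Metapopulation:
    """State of all agents: attitudes, group labels, last actions, group p."""

    y: np.ndarray            # (n,) attitudes
    group: np.ndarray        # (n,) int group labels
    params: PsychParams      # array-valued fields, shape (n,)
    p_group: np.ndarray      # (n_groups,) last observed sharing frequency
    x: np.ndarray            # (n,) last action taken (0/1), init 0

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_groups(self) -> int:
        return self.p_group.size

    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.group, minlength=self.n_groups)


@dataclass(frozen=True)
class SharingConfig:
    """Full configuration of a food-sharing run.

    Defaults are the reference configuration used throughout: c = 1,
    s = 0.15, m = 0.1, 100 groups of 10, lognormal initial attitudes
    (mean 0.2, sd 0.1), broken-stick sensitivities with v = 1, logit
    precision 10, attitude noise sd 0.05, update probability 0.5, and
    an authority promoting sharing (G = 1).
    """

    c: float = 1.0
    s: float = 0.15
    m: float = 0.1
    auth: Authority = field(default_factory=lambda: Authority(G=1.0, F=1.0))
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    pop: PopulationSpec = field(default_factory=PopulationSpec)
    T: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ParameterError("c must be >= 0")
        if not 0.0 <= self.s <= 1.0:
            raise ParameterError("s must lie in [0, 1]")
        if not 0.0 <= self.m <= 1.0:
            raise ParameterError("m must lie in [0, 1]")
        if self.T < 1:
            raise ParameterError("T must be >= 1")

    def to_dict(self) -> dict:
        return {
            "model": "foodsharing",
            "c": self.c, "s": self.s, "m": self.m,
            "T": self.T, "seed": self.seed,
            "authority": {"G": self.auth.G, "F": self.auth.F},
            "noise": {
                "lam": self.noise.lam, "sigma": self.noise.sigma,
                "u_y": self.noise.u_y,
            },
            "population": self.pop.to_dict(),
        }


def init_metapopulation(
    cfg: SharingConfig,
    rng: np.random.Generator,
    y0: Optional[np.ndarray] = None,
    p0: float = 0.0,
) -> Metapopulation:
    """Build the initial state: parameters, attitudes, group labels.

    ``y0`` overrides the sampled initial attitudes; ``p0`` sets the
    initial observed sharing frequency in every group (default 0).
    """
    n = cfg.pop.n
    params = draw_agent_params(cfg.pop, rng, n)
    if y0 is None:
        y0 = initial_attitudes(n, cfg.pop, rng)
    group = np.repeat(np.arange(cfg.pop.n_groups), cfg.pop.group_size)
    return Metapopulation(
        y=np.asarray(y0, dtype=float).copy(),
        group=group,
        params=params,
        p_group=np.full(cfg.pop.n_groups, float(p0)),
        x=np.zeros(n, dtype=int),
    )


def _sharing_round(
    pop: Metapopulation,
    cfg: SharingConfig,
    rng: np.random.Generator,
) -> tuple[Metapopulation, np.ndarray, np.ndarray]:
    """One round's state transition plus the hunter mask and decisions."""
    if np.any(pop.group_sizes() == 0):
        raise ParameterError("empty groups are not allowed")
    n = pop.n
    hunters = rng.random(n) < cfg.s

    du = action_utility_gap(pop.y, pop.p_group[pop.group], cfg.c, pop.params, cfg.auth)
    decisions = choose_binary(du, cfg.noise, rng)
    x_new = np.where(hunters, decisions, pop.x)

    n_hunt = np.bincount(pop.group[hunters], minlength=pop.n_groups)
    n_share = np.bincount(
        pop.group[hunters],
        weights=decisions[hunters].astype(float),
        minlength=pop.n_groups,
    )
    p_new = np.where(n_hunt > 0, n_share / np.maximum(n_hunt, 1), pop.p_group)

    y_new, _, _ = update_attitude_detailed(
        pop.y, decisions, p_new[pop.group], pop.params, cfg.auth, cfg.noise, rng,
        acted=hunters,
    )
    new_pop = Metapopulation(
        y=y_new, group=pop.group, params=pop.params, p_group=p_new, x=x_new
    )
    return new_pop, hunters, decisions


def sharing_step(
    pop: Metapopulation,
    cfg: SharingConfig,
    rng: np.random.Generator,
) -> Metapopulation:
    """One round: hunt, decide, refresh group frequencies, update attitudes.

    Groups whose hunters all failed keep their previous observed
    frequency.  Draw order per round: n hunting uniforms, n choice
    uniforms (only hunters' draws matter but all are consumed, keeping
    the stream layout independent of outcomes), then the attitude
    update's gate and noise draws.
    """
    new_pop, _, _ = _sharing_round(pop, cfg, rng)
    return new_pop


def migrate(
    pop: Metapopulation,
    m: float,
    rng: np.random.Generator,
) -> Metapopulation:
    """Island-model dispersal as size-preserving pairwise swaps.

    Each agent is selected with probability ``m``; the selected agents
    are shuffled and consecutive pairs exchange group labels (an odd
    leftover stays put).  Group sizes are exactly conserved.
    """
    if not 0.0 <= m <= 1.0:
        raise ParameterError("m must lie in [0, 1]")
    selected = np.flatnonzero(rng.random(pop.n) < m)
    if selected.size < 2:
        return pop
    order = rng.permutation(selected)
    a = order[0 : 2 * (order.size // 2) : 2]
    b = order[1 : 2 * (order.size // 2) : 2]
    group = pop.group.copy()
    group[a], group[b] = pop.group[b], pop.group[a]
    return replace(pop, group=group)


def _snapshot(pop: Metapopulation) -> pd.DataFrame:
    n = pop.n
    return pd.DataFrame(
        {
            "agent_id": np.arange(n),
            "group_id": pop.group,
            "x": pop.x,
            "y": pop.y,
            "v": np.broadcast_to(pop.params.v, (n,)),
            "k1": pop.params.k1, "k2": pop.params.k2, "k3": pop.params.k3,
            "alpha": pop.params.alpha, "beta": pop.params.beta,
            "gamma": pop.params.gamma,
        }
    )


def run_sharing(
    cfg: SharingConfig,
    init: Optional[Metapopulation] = None,
    return_state: bool = False,
):
    """Simulate ``cfg.T`` rounds and record population summaries.

    The recorded ``p`` is the frequency of sharers among the round's
    successful hunters pooled across all groups (carried forward when no
    hunt succeeds anywhere; starts at 0).  Deterministic given the seed.
    ``init`` continues from an existing state (e.g. to withdraw the
    authority's messaging after convergence); with ``return_state`` the
    final :class:`Metapopulation` is returned alongside the trajectory.
    """
    rng = np.random.default_rng(cfg.seed)
    pop = init_metapopulation(cfg, rng) if init is None else init

    records = np.empty((cfg.T, 4))
    p_global = 0.0
    for t in range(cfg.T):
        pop, hunters, decisions = _sharing_round(pop, cfg, rng)
        if np.any(hunters):
            p_global = float(decisions[hunters].mean())
        records[t] = (t, p_global, pop.y.mean(), pop.y.std())
        pop = migrate(pop, cfg.m, rng)

    data = pd.DataFrame(records, columns=["t", "p", "y_mean", "y_sd"])
    data["t"] = data["t"].astype(int)
    meta = {"model": "foodsharing", "seed": cfg.seed, "config": cfg.to_dict()}
    traj = Trajectory(data=data, final=_snapshot(pop), meta=meta)
    return (traj, pop) if return_state else traj
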