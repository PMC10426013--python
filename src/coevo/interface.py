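"""Configuration loading and tabular run output shared by all models.

Config files are YAML with a top-level ``model`` key (``foodsharing``,
``protests`` or ``dictator``); every other key is optional and defaults
to the model's reference configuration.  Unknown keys and out-of-range
values raise :class:`ConfigError` naming the offending keys, so typos
fail loudly instead of silently running the default.

Outputs of a run are plain text: ``trajectory.csv`` (t, p, y_mean,
y_sd), ``final_state.csv`` (per-agent snapshot), ``run.json`` (config
echo + seed, sufficient to re-run bit-exactly) and
``attitude_histogram.csv`` (final attitudes in 20 right-closed bins on
[0, 1]).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .core import Authority, NoiseSpec, PsychParams
from .food_sharing import SharingConfig
from .identity import DictatorParams
from .protests import ProtestConfig
from .sampling import InitAttitudes, PopulationSpec
from .trajectory import Trajectory

__all__ = ["ConfigError", "load_config", "config_from_dict", "write_outputs"]


class ConfigError(ValueError):
    """A config file failed validation."""


def _take(d: dict, allowed: dict[str, Any], context: str) -> dict:
    unknown = sorted(set(d) - set(allowed))
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {', '.join(unknown)}")
    out = dict(allowed)
    out.update(d)
    return out


def _noise(d: dict) -> NoiseSpec:
    vals = _take(d, {"lam": 10.0, "sigma": 0.05, "u_y": 0.5}, "noise")
    lam = np.inf if vals["lam"] in ("inf", "infinity") else float(vals["lam"])
    try:
        return NoiseSpec(lam=lam, sigma=float(vals["sigma"]), u_y=float(vals["u_y"]))
    except ValueError as e:
        raise ConfigError(f"noise: {e}") from e


def _population(d: dict, default_v: float, n_groups: int, group_size: int) -> PopulationSpec:
    vals = _take(
        d,
        {
            "n_groups": n_groups,
            "group_size": group_size,
            "param_scheme": "broken_stick",
            "v": default_v,
            "init_attitude": {},
            "fixed": None,
        },
        "population",
    )
    init_vals = _take(
        vals["init_attitude"] or {},
        {"dist": "lognormal", "mean": 0.2, "sd": 0.1, "value": 0.2},
        "population.init_attitude",
    )
    fixed = None
    if vals["fixed"] is not None:
        fvals = _take(
            vals["fixed"],
            {"k1": 0.0, "k2": 0.0, "k3": 0.0, "alpha": 0.0, "beta": 0.0, "gamma": 0.0},
            "population.fixed",
        )
        fixed = PsychParams(**{k: float(v) for k, v in fvals.items()})
    try:
        return PopulationSpec(
            n_groups=int(vals["n_groups"]),
            group_size=int(vals["group_size"]),
            param_scheme=str(vals["param_scheme"]),
            v=float(vals["v"]),
            init_attitude=InitAttitudes(
                dist=str(init_vals["dist"]),
                mean=float(init_vals["mean"]),
                sd=float(init_vals["sd"]),
                value=float(init_vals["value"]),
            ),
            fixed=fixed,
        )
    except ValueError as e:
        raise ConfigError(f"population: {e}") from e


def _authority(d: dict, context: str = "authority") -> Authority:
    vals = _take(d, {"G": 1.0, "F": 1.0}, context)
    try:
        return Authority(G=float(vals["G"]), F=float(vals["F"]))
    except ValueError as e:
        raise ConfigError(f"{context}: {e}") from e


def config_from_dict(raw: dict):
    """Build a validated model config from a plain dictionary."""
    if "model" not in raw:
        raise ConfigError("config must declare a 'model' key")
    model = raw["model"]
    body = {k: v for k, v in raw.items() if k != "model"}

    if model == "foodsharing":
        vals = _take(
            body,
            {
                "c": 1.0, "s": 0.15, "m": 0.1, "T": 400, "seed": 0,
                "authority": {}, "noise": {}, "population": {},
            },
            "foodsharing config",
        )
        try:
            return SharingConfig(
                c=float(vals["c"]), s=float(vals["s"]), m=float(vals["m"]),
                T=int(vals["T"]), seed=int(vals["seed"]),
                auth=_authority(vals["authority"] or {}),
                noise=_noise(vals["noise"] or {}),
                pop=_population(vals["population"] or {}, default_v=1.0,
                                n_groups=100, group_size=10),
            )
        except ValueError as e:
            raise ConfigError(str(e)) from e

    if model == "protests":
        vals = _take(
            body,
            {
                "n": 1000, "T": 300, "seed": 0, "attitudes_fixed": False,
                "authorities": [{"G": 1.0, "F": 1.0}], "noise": {},
                "population": {},
            },
            "protests config",
        )
        auths = tuple(
            _authority(a or {}, f"authorities[{i}]")
            for i, a in enumerate(vals["authorities"])
        )
        try:
            n = int(vals["n"])
            return ProtestConfig(
                n=n, T=int(vals["T"]), seed=int(vals["seed"]),
                attitudes_fixed=bool(vals["attitudes_fixed"]),
                auths=auths,
                noise=_noise(vals["noise"] or {}),
                pop=_population(vals["population"] or {}, default_v=0.0,
                                n_groups=1, group_size=n),
            )
        except ValueError as e:
            raise ConfigError(str(e)) from e

    if model == "dictator":
        vals = _take(
            body,
            {
                "b": 1.0, "k1": 1.0, "k3": 1.0, "alpha": 1.0, "gamma": 1.0,
                "authority": {}, "y0": 0.5, "T": 200, "sigma": 0.0, "u_y": 1.0,
                "seed": 0,
            },
            "dictator config",
        )
        try:
            par = DictatorParams(
                b=float(vals["b"]), k1=float(vals["k1"]), k3=float(vals["k3"]),
                alpha=float(vals["alpha"]), gamma=float(vals["gamma"]),
                auth=_authority(vals["authority"] or {}),
            )
        except ValueError as e:
            raise ConfigError(str(e)) from e
        return {
            "params": par,
            "y0": float(vals["y0"]),
            "T": int(vals["T"]),
            "sigma": float(vals["sigma"]),
            "u_y": float(vals["u_y"]),
            "seed": int(vals["seed"]),
        }

    raise ConfigError(f"unknown model {model!r}")


def load_config(path: str | Path):
    """Load and validate a YAML config file; defaults applied per model."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise ConfigError(f"{path}: empty config")
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return config_from_dict(raw)


def _histogram(y: np.ndarray, bins: int = 20) -> "pd.DataFrame":
    """Right-closed equal bins on [0, 1]: (a, b] except the first, [0, b]."""
    import pandas as pd

    idx = np.clip(np.ceil(np.asarray(y) * bins).astype(int) - 1, 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    edges = np.linspace(0.0, 1.0, bins + 1)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def write_outputs(traj: Trajectory, out_dir: str | Path) -> dict[str, Path]:
    """Write trajectory, final state, metadata and attitude histogram.

    Returns the mapping of logical names to the files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory": out / "trajectory.csv",
        "final_state": out / "final_state.csv",
        "run": out / "run.json",
        "histogram": out / "attitude_histogram.csv",
    }
    traj.data.to_csv(paths["trajectory"], index=False)
    traj.final.to_csv(paths["final_state"], index=False)
    with open(paths["run"], "w") as fh:
        json.dump(traj.meta, fh, indent=2, default=float)
        fh.write("\n")
    _histogram(traj.final["y"].to_numpy()).to_csv(paths["histogram"], index=False)
    return paths
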