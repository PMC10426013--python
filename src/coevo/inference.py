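"""Parameter recovery from simulated action/attitude panel data.

Because both the attitude update and the best responses are linear in
the model's sensitivities, the coefficients can be estimated from panel
data that records actions simultaneously with elicited attitudes:

* attitude side — OLS (no intercept) of the attitude change
  y_{t+1} - y_t on (x - y), (xbar - y) and (G - y) recovers alpha, beta
  and the composite gamma*F.  Only rounds where the update actually
  fired are informative, and rounds where clipping bound the update are
  excluded (censoring would bias the fit).
* action side — for the binary models, logistic regression of x on
  (2y - 1) and (2 xbar - 1) with an intercept recovers lambda*k1,
  lambda*k2 and the composite intercept lambda*(k3 F (2G - 1) - c)
  (normative value, when present, folds into the y coefficient as
  lambda*v/2 per unit of (2y-1) plus lambda*v/2 in the intercept); for
  the Dictator model, OLS of the donation on y recovers eps_x as the
  slope and (1 - eps_x) G - b_bar as the intercept.

Raw (gamma, F) and (k3, F) enter only as products and are never split:
estimates report the composites.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import Authority, ParameterError
from .identity import DictatorParams, best_response_donation
from .protests import ProtestConfig, compose_authorities, run_protests

__all__ = [
    "IdentifiabilityError",
    "Estimate",
    "FitResult",
    "simulate_panel",
    "simulate_dictator_panel",
    "recover_attitude_params",
    "recover_action_params",
]

PANEL_COLUMNS = [
    "agent_id", "t", "y", "x", "xbar_prev", "xbar", "y_next", "updated", "clipped",
]


class IdentifiabilityError(ValueError):
    """The requested parameters are not identifiable from this panel."""


@dataclass(frozen=True)
class Estimate:
    value: float
    se: float


@dataclass(frozen=True)
class FitResult:
    """Point estimates keyed by (composite) parameter name, plus notes."""

    estimates: dict[str, Estimate]
    nobs: int
    notes: tuple[str, ...] = ()

    def __getitem__(self, key: str) -> Estimate:
        return self.estimates[key]


def simulate_panel(cfg: ProtestConfig) -> pd.DataFrame:
    """Run the protest model recording one row per agent-round.

    Columns: agent_id, t, y (pre-update attitude), x (action taken),
    xbar_prev (the frequency the decision was conditioned on — the
    previous round's), xbar (realised frequency used in the attitude
    update), y_next, updated (u_y gate fired), clipped (update hit the
    [0, 1] boundary).  The two peer columns matter for estimation: the
    action regression must condition on the predetermined xbar_prev,
    because the realised frequency contains the actions themselves.
    Requires dynamic attitudes (the panel records their updates).
    """
    if cfg.attitudes_fixed:
        raise ParameterError("panel simulation requires updating attitudes")
    rec: list = []
    run_protests(cfg, record=rec)
    n = cfg.n
    frames = []
    for t, (y, x, p_prev, p, y_next, updated, clipped) in enumerate(rec):
        frames.append(
            pd.DataFrame(
                {
                    "agent_id": np.arange(n),
                    "t": t,
                    "y": y,
                    "x": x,
                    "xbar_prev": p_prev,
                    "xbar": p,
                    "y_next": y_next,
                    "updated": updated,
                    "clipped": clipped,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[PANEL_COLUMNS]


def simulate_dictator_panel(
    par: DictatorParams,
    n: int,
    rng: np.random.Generator,
    y_low: float = 0.0,
    y_high: float = 1.0,
) -> pd.DataFrame:
    """Cross-section of dictators with uniform attitudes and best responses.

    One row per agent: attitude y ~ Uniform(y_low, y_high), donation x
    the deterministic best response, and a flag for clipped donations.
    """
    y = y_low + (y_high - y_low) * rng.random(n)
    x = best_response_donation(y, par)
    interior = par.eps_x * y + (1.0 - par.eps_x) * par.auth.G - par.b_bar
    clipped = (interior < 0.0) | (interior > 1.0)
    return pd.DataFrame(
        {"agent_id": np.arange(n), "y": y, "x": x, "clipped": clipped}
    )


def _column_check(design: pd.DataFrame, names: list[str]) -> None:
    for name in names:
        col = design[name].to_numpy()
        if np.allclose(col, 0.0) or np.allclose(col, col[0]) and np.std(col) == 0:
            raise IdentifiabilityError(
                f"regressor {name!r} has no variation; its coefficient is "
                "not identifiable from this panel"
            )
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise IdentifiabilityError(
            f"collinear regressors among {names}; the corresponding "
            "parameters are confounded"
        )


def recover_attitude_params(panel: pd.DataFrame, G: float = 1.0) -> FitResult:
    """OLS recovery of (alpha, beta, gamma*F) from attitude changes.

    Fits y_{t+1} - y_t on (x - y), (xbar - y), (G - y) with no
    intercept, over rounds where the update fired and was not clipped.
    Exact on noiseless panels; consistent with the usual OLS standard
    errors when attitude noise is present.
    """
    rows = panel[panel["updated"] & ~panel["clipped"]]
    if len(rows) < 3:
        raise IdentifiabilityError("need at least 3 updated, unclipped records")
    design = pd.DataFrame(
        {
            "alpha": rows["x"] - rows["y"],
            "beta": rows["xbar"] - rows["y"],
            "gamma_F": G - rows["y"],
        }
    )
    _column_check(design, list(design.columns))
    dy = rows["y_next"] - rows["y"]
    fit = sm.OLS(dy.to_numpy(), design.to_numpy()).fit()
    est = {
        name: Estimate(float(fit.params[i]), float(fit.bse[i]))
        for i, name in enumerate(design.columns)
    }
    return FitResult(
        estimates=est,
        nobs=int(fit.nobs),
        notes=("gamma_F is the product gamma*F; gamma and F are not separately identifiable",),
    )


def recover_action_params(panel: pd.DataFrame, model: str = "protests") -> FitResult:
    """Recover decision-side composites from recorded actions.

    model='protests' or 'sharing': logistic regression of the binary
    action on (2y - 1) and (2 xbar - 1) plus an intercept.  The slopes
    estimate lambda*k1 and lambda*k2 (for the sharing model the y slope
    is lambda*(k1 + v/2)); the intercept absorbs
    lambda*(k3 F (2G - 1) - c) (plus lambda*v/2 under sharing).

    model='dictator': OLS of the donation on y over unclipped rows;
    slope = eps_x, intercept = (1 - eps_x) G - b_bar.
    """
    if model == "dictator":
        rows = panel[~panel["clipped"]] if "clipped" in panel else panel
        if len(rows) < 3:
            raise IdentifiabilityError("need at least 3 interior donations")
        if np.std(rows["y"].to_numpy()) == 0.0:
            raise IdentifiabilityError("no variation in attitudes y")
        X = sm.add_constant(rows["y"].to_numpy())
        fit = sm.OLS(rows["x"].to_numpy(), X).fit()
        est = {
            "intercept": Estimate(float(fit.params[0]), float(fit.bse[0])),
            "eps_x": Estimate(float(fit.params[1]), float(fit.bse[1])),
        }
        return FitResult(
            estimates=est,
            nobs=int(fit.nobs),
            notes=("intercept is the composite (1 - eps_x)*G - b_bar",),
        )

    if model not in ("protests", "sharing"):
        raise ParameterError(f"unknown model tag {model!r}")
    x = panel["x"].to_numpy().astype(float)
    if np.all(x == x[0]):
        raise IdentifiabilityError(
            "all actions identical (complete separation); decision "
            "parameters are not identifiable"
        )
    peer = panel["xbar_prev"] if "xbar_prev" in panel else panel["xbar"]
    design = pd.DataFrame(
        {
            "lambda_k1": 2.0 * panel["y"] - 1.0,
            "lambda_k2": 2.0 * peer - 1.0,
        }
    )
    _column_check(design, list(design.columns))
    X = sm.add_constant(design.to_numpy())
    fit = sm.Logit(x, X).fit(disp=False, maxiter=200)
    names = ["intercept", "lambda_k1", "lambda_k2"]
    est = {
        name: Estimate(float(fit.params[i]), float(fit.bse[i]))
        for i, name in enumerate(names)
    }
    notes = [
        "intercept is the composite lambda*(k3*F*(2G - 1) - c)",
        "slopes are lambda*k1 and lambda*k2; lambda is not separately identifiable",
    ]
    if model == "sharing":
        notes[0] += " + lambda*v/2"
        notes.append("under sharing the y slope is lambda*(k1 + v/2)")
    return FitResult(estimates=est, nobs=int(fit.nobs), notes=tuple(notes))
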