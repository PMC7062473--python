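"""Logistic choice models and derived behavioral parameters.

Choice patterns in the two-juice task are summarized by fitting, per
session, logistic models of the probability of choosing juice B::

    P(choice B) = 1 / (1 + exp(-X)),   X = a0 + a1 * log(qB / qA) + ...

by unpenalized binomial maximum likelihood. The basic model yields the
relative value rho = exp(-a0/a1) (the amount of juice B that makes the
animal indifferent against 1A) and the sigmoid steepness eta = a1 (inverse
temperature; inversely related to choice variability). Three one-regressor
extensions quantify, via -a2/a1:

* ``side_bias`` (epsilon) — regressor ``delta(A right) - delta(B right)``;
  epsilon > 0 means the animal favors whichever juice is on the right.
* ``choice_hyst`` (xi) — regressor ``delta(prev chose A) - delta(prev chose B)``;
  xi > 0 means the animal tends to repeat the previously chosen juice.
* ``direction_hyst`` (theta) — regressor ``delta(A on prev-chosen side) -
  delta(B on prev-chosen side)``; theta > 0 means the animal tends to repeat
  the previously chosen side.

Stimulation-split models duplicate every term of a base model, once for
stim-OFF and once for stim-ON trials, which is algebraically identical to
two independent fits on the condition partitions.

Natural logarithms are used throughout: rho is invariant to the base of the
quantity-ratio logarithm, while eta scales with it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .session_data import Session, Trial

BASE_MODELS = ("basic", "side_bias", "choice_hyst", "direction_hyst")

#: |a1| beyond this is treated as (quasi-)separation and flagged
SEPARATION_SLOPE = 50.0
MAX_ITER = 200
LL_TOL = 1e-8


class InsufficientDataError(ValueError):
    """The session does not contain the trials a model needs."""


@dataclass
class ChoiceFit:
    """Fitted coefficients and derived behavioral parameters for one model.

    ``coefficients`` maps design-column names (``a0``..``a5``) to MLEs.
    Derived parameters are NaN when undefined (non-convergent or separated
    fits, or parameters the model does not have). ``log_rho_ci`` is the
    delta-method 95% confidence interval for log(rho) (basic model only).
    """

    model: str
    coefficients: dict[str, float]
    cov: np.ndarray | None
    converged: bool
    n_trials_used: int
    rho: float = math.nan
    eta: float = math.nan
    epsilon: float = math.nan
    xi: float = math.nan
    theta: float = math.nan
    rho_OFF: float = math.nan
    rho_ON: float = math.nan
    eta_OFF: float = math.nan
    eta_ON: float = math.nan
    epsilon_OFF: float = math.nan
    epsilon_ON: float = math.nan
    xi_OFF: float = math.nan
    xi_ON: float = math.nan
    theta_OFF: float = math.nan
    theta_ON: float = math.nan
    log_rho_se: float = math.nan
    log_rho_ci: tuple[float, float] = (math.nan, math.nan)

    def as_dict(self) -> dict:
        out = {
            "model": self.model,
            "coefficients": dict(self.coefficients),
            "converged": self.converged,
            "n_trials_used": self.n_trials_used,
        }
        for name in ("rho", "eta", "epsilon", "xi", "theta",
                     "rho_OFF", "rho_ON", "eta_OFF", "eta_ON",
                     "epsilon_OFF", "epsilon_ON", "xi_OFF", "xi_ON",
                     "theta_OFF", "theta_ON", "log_rho_se"):
            v = getattr(self, name)
            if not math.isnan(v):
                out[name] = v
        if not math.isnan(self.log_rho_ci[0]):
            out["log_rho_ci"] = list(self.log_rho_ci)
        return out


# ---------------------------------------------------------------------------
# trial selection and regressors


def select_choice_trials(session: Session) -> list[Trial]:
    """Completed, non-forced, non-error trials with both quantities positive.

    Raises :class:`InsufficientDataError` if fewer than two distinct offer
    types remain, in which case no sigmoid can be fit.
    """
    kept = [
        tr for tr in session.trials
        if tr.completed and not tr.is_error and tr.qA > 0 and tr.qB > 0
    ]
    if len({(tr.qA, tr.qB) for tr in kept}) < 2:
        raise InsufficientDataError(
            "fewer than 2 distinct non-forced offer types with responses"
        )
    return kept


def resolve_predecessors(session: Session) -> dict[int, Trial | None]:
    """Most recent completed (non-aborted) trial preceding each trial.

    Forced choices and forced-choice errors qualify as predecessors: both
    yield a realized chosen juice and side, which is all the hysteresis
    regressors need. Returns None where no completed trial precedes.
    """
    out: dict[int, Trial | None] = {}
    last: Trial | None = None
    for tr in session.trials:
        out[tr.trial_index] = last
        if tr.completed:
            last = tr
    return out


def _choice_hyst_regressor(prev: Trial) -> float:
    # +1 if the previous choice was juice A, -1 if juice B
    return 1.0 if prev.chosen_juice == "A" else -1.0


def _direction_hyst_regressor(tr: Trial, prev: Trial) -> float:
    # +1 if juice A now occupies the previously chosen side, else -1
    return 1.0 if tr.side_of_A == prev.chosen_side else -1.0


def _side_bias_regressor(tr: Trial) -> float:
    # delta(A right) - delta(B right) = +1 if A is right, -1 if B is right
    return 1.0 if tr.side_of_A == "right" else -1.0


def _base_design(
    session: Session, trials: Sequence[Trial], model: str
) -> tuple[np.ndarray, np.ndarray, list[Trial]]:
    """Response vector, design matrix, and the trials actually used."""
    if model == "basic":
        used = list(trials)
        X = np.column_stack([
            np.ones(len(used)),
            [math.log(tr.qB / tr.qA) for tr in used],
        ])
    elif model == "side_bias":
        used = list(trials)
        regs = [_side_bias_regressor(tr) for tr in used]
        if len(set(regs)) < 2:
            raise InsufficientDataError(
                "both spatial configurations must occur among used trials"
            )
        X = np.column_stack([
            np.ones(len(used)),
            [math.log(tr.qB / tr.qA) for tr in used],
            regs,
        ])
    elif model in ("choice_hyst", "direction_hyst"):
        pred = resolve_predecessors(session)
        used, regs = [], []
        for tr in trials:
            prev = pred[tr.trial_index]
            if prev is None:
                continue
            used.append(tr)
            if model == "choice_hyst":
                regs.append(_choice_hyst_regressor(prev))
            else:
                regs.append(_direction_hyst_regressor(tr, prev))
        if len(used) < 2:
            raise InsufficientDataError(
                "too few trials with a resolvable previous choice"
            )
        X = np.column_stack([
            np.ones(len(used)),
            [math.log(tr.qB / tr.qA) for tr in used],
            regs,
        ])
    else:
        raise ValueError(f"unknown model {model!r}")
    y = np.array([1.0 if tr.chosen_juice == "B" else 0.0 for tr in used])
    return y, X, used


# ---------------------------------------------------------------------------
# maximum likelihood core


def _ml_logit(y: np.ndarray, X: np.ndarray):
    """Newton MLE; returns (params, cov, converged) with separation flagged."""
    if len(set(y.tolist())) < 2:
        # the animal chose the same juice on every usable trial
        return np.full(X.shape[1], math.nan), None, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=PerfectSeparationWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=MAX_ITER, tol=LL_TOL)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return np.full(X.shape[1], math.nan), None, False
    params = np.asarray(res.params, float)
    converged = bool(res.mle_retvals.get("converged", False))
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > SEPARATION_SLOPE:
        converged = False
    try:
        cov = np.asarray(res.cov_params(), float)
        if not np.all(np.isfinite(cov)):
            cov = None
    except Exception:
        cov = None
    return params, cov, converged


def _derive(a0: float, a1: float) -> tuple[float, float]:
    """(rho, eta) from an intercept/slope pair; NaN if a1 is not positive."""
    if not (np.isfinite(a0) and np.isfinite(a1)) or a1 <= 0:
        return math.nan, a1 if np.isfinite(a1) else math.nan
    return math.exp(-a0 / a1), a1


def _log_rho_se(a0: float, a1: float, cov: np.ndarray | None,
                i0: int = 0, i1: int = 1) -> float:
    """Delta-method SE of log(rho) = -a0/a1."""
    if cov is None or not np.isfinite(a1) or a1 == 0:
        return math.nan
    g = np.zeros(cov.shape[0])
    g[i0] = -1.0 / a1
    g[i1] = a0 / a1**2
    var = float(g @ cov @ g)
    return math.sqrt(var) if var >= 0 else math.nan


def _ratio_param(a2: float, a1: float) -> float:
    if not (np.isfinite(a2) and np.isfinite(a1)) or a1 == 0:
        return math.nan
    return -a2 / a1


# ---------------------------------------------------------------------------
# public fitting interface


def _fit_base(session: Session, model: str) -> ChoiceFit:
    trials = select_choice_trials(session)
    y, X, used = _base_design(session, trials, model)
    params, cov, converged = _ml_logit(y, X)
    names = [f"a{i}" for i in range(X.shape[1])]
    fit = ChoiceFit(
        model=model,
        coefficients={n: float(p) for n, p in zip(names, params)},
        cov=cov, converged=converged, n_trials_used=len(used),
    )
    if converged:
        a0, a1 = params[0], params[1]
        fit.rho, fit.eta = _derive(a0, a1)
        fit.log_rho_se = _log_rho_se(a0, a1, cov)
        if np.isfinite(fit.log_rho_se) and np.isfinite(fit.rho):
            z = stats.norm.ppf(0.975)
            lr = math.log(fit.rho)
            fit.log_rho_ci = (lr - z * fit.log_rho_se, lr + z * fit.log_rho_se)
        if model == "side_bias":
            fit.epsilon = _ratio_param(params[2], a1)
        elif model == "choice_hyst":
            fit.xi = _ratio_param(params[2], a1)
        elif model == "direction_hyst":
            fit.theta = _ratio_param(params[2], a1)
    return fit


def fit_basic(session: Session) -> ChoiceFit:
    """Basic logistic fit; derives relative value rho and steepness eta."""
    return _fit_base(session, "basic")


def fit_side_bias(session: Session) -> ChoiceFit:
    """Side-bias model; epsilon > 0 means a rightward bias."""
    return _fit_base(session, "side_bias")


def fit_choice_hysteresis(session: Session) -> ChoiceFit:
    """Choice-hysteresis model; xi > 0 means repeating the previous juice."""
    return _fit_base(session, "choice_hyst")


def fit_direction_hysteresis(session: Session) -> ChoiceFit:
    """Direction-hysteresis model; theta > 0 means repeating the previous side."""
    return _fit_base(session, "direction_hyst")


def fit_stim_model(session: Session, base_model: str = "basic") -> ChoiceFit:
    """Stimulation-split fit: every base-model term duplicated per condition.

    The design has no shared terms across conditions, so the joint MLE equals
    two independent fits on the OFF and ON partitions; the joint form is kept
    because it is how the per-condition parameters are defined and reported.
    """
    if base_model not in BASE_MODELS:
        raise ValueError(f"unknown base model {base_model!r}")
    trials = select_choice_trials(session)
    y, Xb, used = _base_design(session, trials, base_model)
    on = np.array([1.0 if tr.stim == "ON" else 0.0 for tr in used])
    if on.min() == on.max():
        raise InsufficientDataError("session lacks one stimulation condition")
    X = np.column_stack([Xb * (1.0 - on)[:, None], Xb * on[:, None]])
    params, cov, converged = _ml_logit(y, X)
    k = Xb.shape[1]
    names = [f"a{i}" for i in range(2 * k)]
    fit = ChoiceFit(
        model=f"stim_{base_model}",
        coefficients={n: float(p) for n, p in zip(names, params)},
        cov=cov, converged=converged, n_trials_used=len(used),
    )
    if converged:
        a_off, a_on = params[:k], params[k:]
        fit.rho_OFF, fit.eta_OFF = _derive(a_off[0], a_off[1])
        fit.rho_ON, fit.eta_ON = _derive(a_on[0], a_on[1])
        if base_model == "side_bias":
            fit.epsilon_OFF = _ratio_param(a_off[2], a_off[1])
            fit.epsilon_ON = _ratio_param(a_on[2], a_on[1])
        elif base_model == "choice_hyst":
            fit.xi_OFF = _ratio_param(a_off[2], a_off[1])
            fit.xi_ON = _ratio_param(a_on[2], a_on[1])
        elif base_model == "direction_hyst":
            fit.theta_OFF = _ratio_param(a_off[2], a_off[1])
            fit.theta_ON = _ratio_param(a_on[2], a_on[1])
    return fit


def split_by_stim(session: Session) -> tuple[Session, Session]:
    """Two sub-sessions holding the stim-OFF and stim-ON trials."""
    off = Session(
        mouse_id=session.mouse_id,
        trials=[tr for tr in session.trials if tr.stim == "OFF"],
        licks=[lk for lk in session.licks
               if session.trial_by_index(lk[0]).stim == "OFF"],
        hemisphere_of_recording=session.hemisphere_of_recording,
        group=session.group,
    )
    on = Session(
        mouse_id=session.mouse_id,
        trials=[tr for tr in session.trials if tr.stim == "ON"],
        licks=[lk for lk in session.licks
               if session.trial_by_index(lk[0]).stim == "ON"],
        hemisphere_of_recording=session.hemisphere_of_recording,
        group=session.group,
    )
    return off, on


FITTERS = {
    "basic": fit_basic,
    "side_bias": fit_side_bias,
    "choice_hyst": fit_choice_hysteresis,
    "direction_hyst": fit_direction_hysteresis,
}
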