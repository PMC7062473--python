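"""Quantification of optogenetic-inactivation effects and lesion mapping.

The primary behavioral effect of orbital-cortex inactivation is a drop in
sigmoid steepness; per session it is summarized by the steepness
stimulation index::

    SSI = 2 * (eta_ON - eta_OFF) / (eta_ON + eta_OFF)

and the corresponding effect on licking by the lick stimulation index,
the same normalized contrast applied to mean licks per trial in the
1.5-4.5 s window after trial start. Per mouse, the choice deficit is
CD = -mean(SSI) across sessions (larger CD = more severe impairment).

The module also provides the session-distribution tests used to establish
the effects (two-sided F test on the spread of log relative value, paired t
test on steepness), the SSI-LSI correlation with explicit robust-outlier
handling, and an L1-penalized (LASSO) map from per-area viral-infection
volumes to choice deficit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV, lasso_path
from sklearn.model_selection import LeaveOneOut

from .session_data import Session

LICK_WINDOW = (1.5, 4.5)


class DegenerateDataError(ValueError):
    """Inputs make the requested statistic undefined."""


class InsufficientDataError(ValueError):
    pass


@dataclass
class StimEffect:
    """Per-session inactivation summary (indices bounded in (-2, 2))."""

    session_id: str
    rho_OFF: float
    rho_ON: float
    eta_OFF: float
    eta_ON: float
    SSI: float
    LSI: float = math.nan


def compute_SSI(eta_OFF: float, eta_ON: float) -> float:
    """Steepness stimulation index 2*(eta_ON - eta_OFF)/(eta_ON + eta_OFF).

    Antisymmetric under swapping conditions and bounded in (-2, 2) for
    positive steepnesses.
    """
    if not (eta_OFF > 0 and eta_ON > 0) or not (
        np.isfinite(eta_OFF) and np.isfinite(eta_ON)
    ):
        raise DegenerateDataError("steepnesses must be finite and positive")
    return 2.0 * (eta_ON - eta_OFF) / (eta_ON + eta_OFF)


def lick_stimulation_index(nlicks_OFF: float, nlicks_ON: float) -> float:
    """LSI = 2*(nlicks_ON - nlicks_OFF)/(nlicks_ON + nlicks_OFF)."""
    denom = nlicks_ON + nlicks_OFF
    if denom == 0:
        raise DegenerateDataError("no licks in either condition")
    return 2.0 * (nlicks_ON - nlicks_OFF) / denom


def compute_LSI(session: Session) -> float:
    """LSI from a session's lick trains (1.5-4.5 s window, all trials)."""
    counts = session.lick_counts(*LICK_WINDOW)
    stim = session.stim_of_trial()
    means = {}
    for cond in ("OFF", "ON"):
        idx = stim.index[stim == cond]
        if len(idx) == 0:
            raise InsufficientDataError(f"session has no {cond} trials")
        means[cond] = float(counts.loc[idx].mean())
    return lick_stimulation_index(means["OFF"], means["ON"])


def choice_deficits(effects: list[StimEffect],
                    mouse_of_session: dict[str, str]) -> pd.Series:
    """CD = -mean(SSI) per mouse, across that mouse's stim sessions."""
    by_mouse: dict[str, list[float]] = {}
    for eff in effects:
        by_mouse.setdefault(mouse_of_session[eff.session_id], []).append(eff.SSI)
    return pd.Series(
        {m: -float(np.mean(v)) for m, v in sorted(by_mouse.items())}, name="CD"
    )


# ---------------------------------------------------------------------------
# distribution tests


def variance_broadening_test(log_rho_OFF, log_rho_ON) -> tuple[float, float]:
    """Two-sided F test for equality of variance of log relative value.

    The ON-condition variance sits in the numerator, so F > 1 indicates a
    broader spread of log(rho) under inactivation.
    """
    off = np.asarray(log_rho_OFF, float)
    on = np.asarray(log_rho_ON, float)
    if len(off) < 3 or len(on) < 3:
        raise InsufficientDataError("need at least 3 sessions per condition")
    v_off = off.var(ddof=1)
    v_on = on.var(ddof=1)
    if v_off == 0 or v_on == 0:
        raise DegenerateDataError("zero variance in one condition")
    F = v_on / v_off
    dfn, dfd = len(on) - 1, len(off) - 1
    p = 2.0 * min(stats.f.cdf(F, dfn, dfd), stats.f.sf(F, dfn, dfd))
    return float(F), float(min(p, 1.0))


def steepness_reduction_test(eta_OFF, eta_ON) -> tuple[float, float]:
    """Paired t test on eta_ON - eta_OFF (two-sided).

    t < 0 indicates the steepness is consistently lower under inactivation.
    """
    off = np.asarray(eta_OFF, float)
    on = np.asarray(eta_ON, float)
    if len(off) != len(on):
        raise ValueError("paired samples must have equal length")
    if len(off) < 3:
        raise InsufficientDataError("need at least 3 paired sessions")
    diff = on - off
    if diff.std(ddof=1) == 0:
        # constant differences: no evidence against the null when all zero,
        # overwhelming evidence otherwise
        if diff[0] == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff[0]), 0.0
    res = stats.ttest_rel(on, off)
    return float(res.statistic), float(res.pvalue)


def robust_outliers(x, n_sd: float = 3.0) -> np.ndarray:
    """Boolean mask of points beyond ``n_sd`` robust SDs (1.4826*MAD) of the median."""
    x = np.asarray(x, float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros(len(x), bool)
    return np.abs(x - med) > n_sd * 1.4826 * mad


def ssi_lsi_correlation(
    effects: list[StimEffect], exclude: set[str] | None = None
) -> dict:
    """Pearson correlation of SSI and LSI across sessions.

    ``exclude`` names sessions the caller treats as outliers (e.g., from
    :func:`robust_outliers`); they are listed in the report, never silently
    dropped.
    """
    exclude = exclude or set()
    pairs = [
        (e.session_id, e.SSI, e.LSI)
        for e in effects
        if e.session_id not in exclude and np.isfinite(e.LSI)
    ]
    if len(pairs) < 3:
        raise InsufficientDataError("need at least 3 sessions with both indices")
    ssi = np.array([p[1] for p in pairs])
    lsi = np.array([p[2] for p in pairs])
    r, p = stats.pearsonr(ssi, lsi)
    return {
        "r": float(r), "p": float(p), "n": len(pairs),
        "excluded_sessions": sorted(exclude),
    }


# ---------------------------------------------------------------------------
# lesion-volume -> deficit LASSO map


@dataclass
class LassoDeficitResult:
    """Sparse lesion-to-deficit map with the full penalty path for auditing."""

    coefficients: pd.Series  # standardized scale, indexed by area
    intercept: float
    alpha: float  # penalty selected by leave-one-out CV
    alphas: np.ndarray  # descending penalty path
    support_path: pd.DataFrame  # bool, path point x area: coefficient non-zero
    dropped_areas: list[str] = field(default_factory=list)

    @property
    def support(self) -> list[str]:
        return [a for a, c in self.coefficients.items() if c != 0.0]


def lasso_deficit_map(
    infection: pd.DataFrame,
    deficit: pd.Series,
    n_alphas: int = 50,
    alpha_min_ratio: float = 1e-3,
) -> LassoDeficitResult:
    """L1-penalized regression of choice deficit on per-area infection volume.

    Predictors (one column per area, rows = mice) are standardized to zero
    mean and unit SD before penalization; coefficients are reported on that
    standardized scale, so a positive coefficient means more infection in
    the area predicts a larger choice deficit. The penalty is chosen by
    leave-one-out cross-validation over a logarithmic path, and the sparsity
    pattern along the whole path is returned so the sign conclusion can be
    audited at every penalty.
    """
    if len(infection) < 3:
        raise InsufficientDataError("need at least 3 mice")
    X = infection.loc[deficit.index].astype(float)
    if (X < 0).any().any():
        raise ValueError("infection volumes must be non-negative")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero infection row")
    sd = X.std(axis=0, ddof=0)
    dropped = sorted(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"dropping constant infection columns: {dropped}")
    keep = [c for c in X.columns if c not in dropped]
    Xz = (X[keep] - X[keep].mean(axis=0)) / sd[keep]
    y = deficit.to_numpy(float)
    n = len(y)

    alpha_max = float(np.max(np.abs(Xz.to_numpy().T @ (y - y.mean())))) / n
    if alpha_max == 0:
        # deficit carries no linear signal (e.g., all-zero): everything shrinks out
        coefs = pd.Series(0.0, index=pd.Index(keep, name="area"))
        alphas = np.array([1.0])
        support = pd.DataFrame(False, index=alphas, columns=keep)
        return LassoDeficitResult(coefs, float(y.mean()), 1.0, alphas, support, dropped)

    alphas = np.logspace(
        math.log10(alpha_max), math.log10(alpha_max * alpha_min_ratio), n_alphas
    )
    model = LassoCV(alphas=alphas, cv=LeaveOneOut(), fit_intercept=True,
                    max_iter=50_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xz.to_numpy(), y)
    path_alphas, path_coefs, _ = lasso_path(Xz.to_numpy(), y, alphas=alphas)
    support = pd.DataFrame(
        (path_coefs != 0.0).T, index=path_alphas, columns=keep
    )
    coefs = pd.Series(model.coef_, index=pd.Index(keep, name="area"))
    return LassoDeficitResult(
        coefficients=coefs,
        intercept=float(model.intercept_),
        alpha=float(model.alpha_),
        alphas=path_alphas,
        support_path=support,
        dropped_areas=dropped,
    )
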