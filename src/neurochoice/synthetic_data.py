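"""Synthetic behavioral sessions, spike populations, and lesion datasets.

Every generator is the exact inverse of the model its downstream analysis
fits, with known ground truth, so that generate-then-fit round trips are
consistent by construction:

* :func:`gen_session` draws trials from the full logistic choice model
  (relative value rho, steepness eta, side bias epsilon, choice hysteresis
  xi, direction hysteresis theta), sequentially so hysteresis terms depend
  on the realized history, with optional interleaved stimulation trials
  governed by their own (rho_ON, eta_ON), Poisson lick trains, ~40% forced
  choices (split evenly per juice), and offer menus of 10-12 offer types.
* :func:`gen_population` emits spike trains whose rate is baseline +
  gain * v(trial) for a chosen decision variable v, piecewise-constant in
  time so that the count in each analysis window is Poisson with mean
  rate x duration.
* :func:`gen_lesion_dataset` draws log-normal per-area infection volumes
  and a choice deficit linear in the standardized volumes plus noise.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .session_data import Session, SpikeTable, Trial, opposite_side
from .neural_encoding import VARIABLES, compute_variables, trial_type_of

#: 12 offer types: 4 forced anchors + 8 binary offers, quantities matching
#: the 0-6 drop range of the task (qA up to 3, qB up to 6)
DEFAULT_OFFER_MENU = (
    (0, 1), (0, 2), (1, 0), (2, 0),
    (1, 1), (1, 2), (1, 3), (1, 4), (1, 6),
    (2, 1), (2, 3), (3, 1),
)

#: per-area infection columns; PrL/MO/VO/LO are measured at two AP coordinates
DEFAULT_AREAS = (
    "FrA", "PrL_a1", "PrL_a2", "MO_a1", "MO_a2", "VO_a1", "VO_a2",
    "LO_a1", "LO_a2", "DLO", "OB", "M1", "M2", "CgI", "AI", "EX",
)

OFFER_ON_S = 0.5
GO_S = 3.3  # offer onset + 2.8 s offer period
JUICE_ON_S = 3.6


@dataclass(frozen=True)
class StimGenParams:
    """Stimulation condition: its own sigmoid plus the interleaving rate."""

    rho_ON: float
    eta_ON: float
    p_stim: float = 0.5
    epsilon_ON: float | None = None  # None: inherit the OFF-condition value
    xi_ON: float | None = None
    theta_ON: float | None = None


@dataclass(frozen=True)
class BehaviorGenParams:
    """Ground-truth behavioral parameters for one generated session."""

    rho: float = 2.4
    eta: float = 1.2
    epsilon: float = 0.0
    xi: float = 0.0
    theta: float = 0.0
    n_trials: int = 300
    offer_menu: Sequence[tuple[int, int]] = DEFAULT_OFFER_MENU
    forced_fraction: float = 0.4  # split evenly between forced-A and forced-B
    stim: StimGenParams | None = None
    lick_rate_OFF: float = 4.3  # Hz within the 1.5-4.5 s lick window
    lick_rate_ON: float = 4.3
    error_rate: float = 0.05  # wrong-spout licks on forced choices
    abort_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if not self.offer_menu:
            raise ValueError("offer menu must be non-empty")
        for qA, qB in self.offer_menu:
            if qA < 0 or qB < 0 or (qA == 0 and qB == 0):
                raise ValueError(f"invalid offer ({qA}, {qB})")
        for p in (self.forced_fraction, self.error_rate, self.abort_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.stim is not None and not 0.0 <= self.stim.p_stim <= 1.0:
            raise ValueError("p_stim must lie in [0, 1]")
        if self.rho <= 0 or self.eta <= 0:
            raise ValueError("rho and eta must be positive")


def _choice_prob_B(
    params: BehaviorGenParams,
    stim_on: bool,
    qA: int,
    qB: int,
    side_of_A: str,
    prev: Trial | None,
) -> float:
    """P(choose B) under the full logistic model for one trial."""
    if stim_on and params.stim is not None:
        rho, eta = params.stim.rho_ON, params.stim.eta_ON
        eps = params.stim.epsilon_ON
        xi = params.stim.xi_ON
        theta = params.stim.theta_ON
        eps = params.epsilon if eps is None else eps
        xi = params.xi if xi is None else xi
        theta = params.theta if theta is None else theta
    else:
        rho, eta = params.rho, params.eta
        eps, xi, theta = params.epsilon, params.xi, params.theta
    x = eta * (math.log(qB / qA) - math.log(rho))
    # side bias: a2 = -eps * eta, regressor +1 when A is on the right
    x += -eps * eta * (1.0 if side_of_A == "right" else -1.0)
    if prev is not None:
        x += -xi * eta * (1.0 if prev.chosen_juice == "A" else -1.0)
        x += -theta * eta * (1.0 if side_of_A == prev.chosen_side else -1.0)
    return 1.0 / (1.0 + math.exp(-x))


def gen_session(params: BehaviorGenParams, mouse_id: str = "sim") -> Session:
    """Draw one synthetic session; deterministic given ``params.seed``.

    Trials are generated sequentially: hysteresis terms on trial t use the
    most recent completed trial before t, i.e. the same predecessor rule the
    fitting side applies, so the fitted models are correctly specified for
    this generator. Forced-choice errors trigger a repeat of the same offer
    on the next trial, as in the task.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    forced_A = [o for o in params.offer_menu if o[1] == 0]
    forced_B = [o for o in params.offer_menu if o[0] == 0]
    free = [o for o in params.offer_menu if o[0] > 0 and o[1] > 0]
    if params.forced_fraction > 0 and not (forced_A and forced_B):
        raise ValueError("forced_fraction > 0 requires forced offers of each juice")

    trials: list[Trial] = []
    licks: list[tuple[int, str, float]] = []
    prev_completed: Trial | None = None
    repeat_offer: tuple[int, int] | None = None

    for i in range(params.n_trials):
        if repeat_offer is not None:
            qA, qB = repeat_offer
            repeat_offer = None
        else:
            u = rng.random()
            if free and u >= params.forced_fraction:
                qA, qB = free[rng.integers(len(free))]
            elif u < params.forced_fraction / 2.0 and forced_A:
                qA, qB = forced_A[rng.integers(len(forced_A))]
            else:
                qA, qB = forced_B[rng.integers(len(forced_B))]
        side_of_A = "left" if rng.random() < 0.5 else "right"
        stim_on = params.stim is not None and rng.random() < params.stim.p_stim
        stim = "ON" if stim_on else "OFF"

        if rng.random() < params.abort_rate:
            trials.append(Trial(i, qA, qB, side_of_A, stim, "none", "none",
                                False, OFFER_ON_S, GO_S, math.nan))
            continue

        is_error = False
        if qA == 0 or qB == 0:
            offered = "A" if qB == 0 else "B"
            if rng.random() < params.error_rate:
                is_error = True
                chosen_juice = "B" if offered == "A" else "A"
                repeat_offer = (qA, qB)
            else:
                chosen_juice = offered
        else:
            pB = _choice_prob_B(params, stim_on, qA, qB, side_of_A, prev_completed)
            chosen_juice = "B" if rng.random() < pB else "A"
        chosen_side = side_of_A if chosen_juice == "A" else opposite_side(side_of_A)
        tr = Trial(i, qA, qB, side_of_A, stim, chosen_juice, chosen_side,
                   is_error, OFFER_ON_S, GO_S, JUICE_ON_S)
        trials.append(tr)
        prev_completed = tr

        rate = params.lick_rate_ON if stim_on else params.lick_rate_OFF
        n_licks = rng.poisson(rate * 3.0)
        for t in np.sort(rng.uniform(1.5, 4.5, size=n_licks)):
            licks.append((i, chosen_side, float(t)))

    session = Session(mouse_id=mouse_id, trials=trials, licks=licks)
    session.validate()
    return session


# ---------------------------------------------------------------------------
# spike populations


@dataclass(frozen=True)
class NeuronGenParams:
    """Tuning of one simulated cell (linear in one decision variable)."""

    cell_id: str
    encoded_variable: str  # one of VARIABLES or "untuned"
    baseline: float  # Hz
    gain: float  # Hz per unit of the encoded variable
    hemisphere: str  # "left" | "right"
    seed: int = 0

    def validate(self) -> None:
        if self.encoded_variable != "untuned" and self.encoded_variable not in VARIABLES:
            raise ValueError(f"unknown encoded variable {self.encoded_variable!r}")
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")


def gen_population(
    session: Session,
    cells: Sequence[NeuronGenParams],
    rho: float,
    return_clip_report: bool = False,
) -> SpikeTable | tuple[SpikeTable, dict[str, int]]:
    """Poisson spike trains tuned to the cells' decision variables.

    The firing rate is piecewise constant over the trial: ``baseline``
    before 0.2 s after offer onset and after 0.6 s past juice delivery, and
    ``max(0, baseline + gain * v)`` in between, where v is the cell's
    encoded variable evaluated on the trial (hemisphere-relative, values in
    units of juice B via ``rho``). Negative implied rates are clipped to 0
    and counted in the clip report. Aborted and forced-error trials emit
    baseline activity only.
    """
    usable = [tr for tr in session.trials if tr.completed and not tr.is_error]
    records: list[tuple[str, int, float]] = []
    hemispheres: dict[str, str] = {}
    clip_report: dict[str, int] = {}

    # variable values per hemisphere, computed once per distinct trial type
    values: dict[str, dict] = {}
    for hemi in ("left", "right"):
        tts = sorted({trial_type_of(tr, hemi) for tr in usable})
        table = compute_variables(tts, rho) if tts else None
        values[hemi] = (
            {var: table[var].to_dict() for var in table.columns}
            if table is not None else {}
        )

    for cell in cells:
        cell.validate()
        hemispheres[cell.cell_id] = cell.hemisphere
        rng = np.random.default_rng(cell.seed)
        clips = 0
        table = values[cell.hemisphere]
        for tr in session.trials:
            offer_on = tr.offer_on_s
            if tr.completed and not tr.is_error:
                juice_on = tr.juice_on_s
                if cell.encoded_variable == "untuned":
                    driven = cell.baseline
                else:
                    v = table[cell.encoded_variable][trial_type_of(tr, cell.hemisphere)]
                    driven = cell.baseline + cell.gain * v
                    if driven < 0:
                        driven = 0.0
                        clips += 1
                segments = [
                    (offer_on - 1.0, offer_on + 0.2, cell.baseline),
                    (offer_on + 0.2, juice_on + 0.6, driven),
                    (juice_on + 0.6, juice_on + 1.0, cell.baseline),
                ]
            else:
                segments = [(offer_on - 1.0, GO_S + 1.0, cell.baseline)]
            for t0, t1, rate in segments:
                n = rng.poisson(rate * (t1 - t0))
                for t in np.sort(rng.uniform(t0, t1, size=n)):
                    records.append((cell.cell_id, tr.trial_index, float(t)))
        clip_report[cell.cell_id] = clips

    events = pd.DataFrame(records, columns=["cell_id", "trial_index", "time_s"])
    table_out = SpikeTable(events=events, hemispheres=hemispheres)
    table_out.validate(known_trials=[tr.trial_index for tr in session.trials])
    if return_clip_report:
        return table_out, clip_report
    return table_out


#: composition of the reference simulated population: (variable, n_cells, gain)
#: gains give a few-fold rate modulation over each variable's range, the
#: regime real value/binary cells occupy; saturating the SNR would make
#: correlated variables cross-explain nearly every response
POPULATION_DESIGN = (
    ("offer_value_ipsi", 60, 0.8),
    ("chosen_side", 60, 5.0),
    ("position_of_A", 30, 5.0),
    ("chosen_value", 40, 0.8),
    ("untuned", 110, 0.0),
)


def design_population(
    seed: int,
    design: Sequence[tuple[str, int, float]] = POPULATION_DESIGN,
    baseline: float = 4.0,
) -> list[NeuronGenParams]:
    """The reference 300-cell population: four tuned groups plus untuned cells.

    Gains follow the nearly-binary / few-fold-rate-range character of the
    recorded example cells; hemispheres alternate so ipsi/contra variables
    are exercised on both sides.
    """
    rng = np.random.default_rng(seed)
    cells = []
    idx = 0
    for var, n, gain in design:
        for _ in range(n):
            cells.append(NeuronGenParams(
                cell_id=f"c{idx:03d}",
                encoded_variable=var,
                baseline=baseline,
                gain=gain,
                hemisphere="left" if idx % 2 == 0 else "right",
                seed=int(rng.integers(2**31)),
            ))
            idx += 1
    return cells


# ---------------------------------------------------------------------------
# lesion datasets


def gen_lesion_dataset(
    n_mice: int,
    areas: Sequence[str] = DEFAULT_AREAS,
    beta: dict[str, float] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Infection matrix (stained-pixel counts) and choice-deficit vector.

    Volumes are log-normal per area; the deficit is
    ``CD = sum_a beta[a] * z(vol_a) + N(0, noise_sd)`` where z standardizes
    each area column across mice. ``beta`` is the ground truth the LASSO
    map should recover.
    """
    if n_mice < 3:
        raise ValueError("need at least 3 mice")
    beta = beta or {}
    unknown = set(beta) - set(areas)
    if unknown:
        raise ValueError(f"beta references unknown areas {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    mice = [f"m{i:02d}" for i in range(n_mice)]
    vols = pd.DataFrame(
        rng.lognormal(mean=10.0, sigma=0.6, size=(n_mice, len(areas))),
        index=pd.Index(mice, name="mouse_id"),
        columns=pd.Index(list(areas), name="area"),
    ).round()
    z = (vols - vols.mean(axis=0)) / vols.std(axis=0, ddof=0)
    cd = pd.Series(0.0, index=vols.index, name="CD")
    for area, b in beta.items():
        cd += b * z[area]
    cd += rng.normal(0.0, noise_sd, size=n_mice)
    return vols, cd


# ---------------------------------------------------------------------------
# per-session parameter draws for test calibration/power studies


def gen_stim_parameter_sets(
    n_sessions: int,
    seed: int,
    effect: bool = False,
    eta_base: float = 1.19,
    sd_log_eta: float = 0.3,
    log_rho_mean: float = math.log(2.39),
    sd_log_rho: float = 0.25,
    eta_ratio: float = 0.7,
    eta_jitter: float = 0.1,
    rho_spread_factor: float = 3.0,
) -> pd.DataFrame:
    """Session-level (eta, log rho) pairs for one simulated mouse.

    Under the null, ON draws are independent replicates of the OFF
    distribution. Under the effect, eta_ON = eta_ratio * eta_OFF with
    lognormal jitter and log rho_ON is drawn with its SD inflated by
    ``rho_spread_factor`` — the steepness-reduction and distribution-
    broadening signatures of the inactivation.
    """
    rng = np.random.default_rng(seed)
    eta_off = eta_base * np.exp(rng.normal(0.0, sd_log_eta, n_sessions))
    log_rho_off = rng.normal(log_rho_mean, sd_log_rho, n_sessions)
    if effect:
        eta_on = eta_ratio * eta_off * np.exp(rng.normal(0.0, eta_jitter, n_sessions))
        log_rho_on = rng.normal(log_rho_mean, rho_spread_factor * sd_log_rho,
                                n_sessions)
    else:
        eta_on = eta_base * np.exp(rng.normal(0.0, sd_log_eta, n_sessions))
        log_rho_on = rng.normal(log_rho_mean, sd_log_rho, n_sessions)
    return pd.DataFrame({
        "eta_OFF": eta_off, "eta_ON": eta_on,
        "log_rho_OFF": log_rho_off, "log_rho_ON": log_rho_on,
    })
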