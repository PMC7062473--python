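"""Neuronal decision-variable encoding and variable-selection analysis.

A *neuronal response* is the mean firing rate of one cell in one time window
as a function of *trial type* (offer type + spatial configuration + choice),
with sides expressed relative to the cell's recording hemisphere
(ipsi/contra). Responses are screened for task-relatedness with a 1-way
ANOVA over trial types (p < 0.001; a 3-way ANOVA over offer type, position
of A and chosen side is reported alongside), then each task-related response
is regressed separately against twelve candidate decision variables. A
variable *explains* a response when its regression slope differs from zero
at p < 0.05; non-explaining variables carry R^2 = 0 by convention. Two
selection procedures identify a minimal variable set accounting for the
population: a greedy stepwise procedure constrained so every selected
variable keeps >= 5% marginal explanatory power, and an exhaustive
best-subset search over all subsets of a given size.

Offer and chosen values are expressed in common units of juice B through
the session's fitted relative value rho (value of ``qA`` drops of A is
``rho * qA``; of ``qB`` drops of B is ``qB``).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .session_data import Session, SpikeTable, Trial, ValidationError

VARIABLES = (
    "position_of_A",
    "offer_value_A",
    "offer_value_B",
    "offer_value_ipsi",
    "offer_value_contra",
    "chosen_value",
    "chosen_value_A",
    "chosen_value_B",
    "chosen_value_ipsi",
    "chosen_value_contra",
    "chosen_juice",
    "chosen_side",
)

MIN_TRIALS_PER_TYPE = 3  # trial types with <= 2 trials are excluded
TASK_RELATED_P = 0.001
EXPLAIN_P = 0.05
MARGINAL_POWER_PCT = 5.0


@dataclass(frozen=True)
class TimeWindow:
    """Analysis window anchored to offer onset or juice delivery."""

    name: str
    anchor: str  # "offer_on" | "juice_on"
    start_s: float
    end_s: float

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


DEFAULT_WINDOWS = (
    TimeWindow("pre_offer", "offer_on", -0.6, 0.0),
    TimeWindow("post_offer", "offer_on", 0.2, 0.8),
    TimeWindow("late_delay", "offer_on", 0.6, 1.2),
    TimeWindow("pre_juice", "juice_on", -0.6, 0.0),
    TimeWindow("post_juice", "juice_on", 0.0, 0.6),
)


class TrialType(NamedTuple):
    """Offer type + hemisphere-relative configuration + choice."""

    qA: int
    qB: int
    position_of_A: str  # "ipsi" | "contra"
    chosen_side: str  # "ipsi" | "contra"

    @property
    def offer_type(self) -> tuple[int, int]:
        return (self.qA, self.qB)

    @property
    def chosen_juice(self) -> str:
        return "A" if self.chosen_side == self.position_of_A else "B"


def trial_type_of(trial: Trial, hemisphere: str) -> TrialType:
    """Map a completed trial to its hemisphere-relative trial type."""
    def rel(side: str) -> str:
        return "ipsi" if side == hemisphere else "contra"

    return TrialType(
        qA=trial.qA, qB=trial.qB,
        position_of_A=rel(trial.side_of_A),
        chosen_side=rel(trial.chosen_side),
    )


@dataclass
class NeuronalResponse:
    """One cell x one time window: rates per trial type plus screening state."""

    cell_id: str
    hemisphere: str
    window: str
    rates: dict[TrialType, tuple[float, int, float]]  # mean Hz, n, SEM
    trial_rates: dict[TrialType, np.ndarray] = field(default_factory=dict, repr=False)
    task_related: bool | None = None
    anova_p: dict[str, float] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str]:
        return (self.cell_id, self.window)

    def trial_types(self) -> list[TrialType]:
        return sorted(self.rates)


def build_responses(
    session: Session,
    spikes: SpikeTable,
    windows: Sequence[TimeWindow] = DEFAULT_WINDOWS,
    min_trials: int = MIN_TRIALS_PER_TYPE,
) -> list[NeuronalResponse]:
    """Windowed firing rates per trial type for every cell.

    Aborted trials and forced-choice error trials are excluded; trial types
    with fewer than ``min_trials`` trials are dropped. Cells with no spikes
    anywhere are retained with zero rates.
    """
    from .session_data import SPIKE_TIME_RANGE

    usable = [tr for tr in session.trials if tr.completed and not tr.is_error]
    anchors = {
        tr.trial_index: {"offer_on": tr.offer_on_s, "juice_on": tr.juice_on_s}
        for tr in usable
    }
    for tr in usable:
        for w in windows:
            t0 = anchors[tr.trial_index][w.anchor] + w.start_s
            t1 = anchors[tr.trial_index][w.anchor] + w.end_s
            if t0 < SPIKE_TIME_RANGE[0] or t1 > SPIKE_TIME_RANGE[1]:
                raise ValidationError(
                    f"window {w.name} falls outside the recorded span on "
                    f"trial {tr.trial_index}"
                )

    times = spikes.times_by_cell_trial()
    responses: list[NeuronalResponse] = []
    for cell_id in spikes.cell_ids:
        hemi = spikes.hemispheres[cell_id]
        cell_times = times.get(cell_id, {})
        # per-trial rates in every window, grouped by trial type
        by_window: dict[str, dict[TrialType, list[float]]] = {
            w.name: {} for w in windows
        }
        for tr in usable:
            tt = trial_type_of(tr, hemi)
            st = cell_times.get(tr.trial_index, np.empty(0))
            for w in windows:
                t0 = anchors[tr.trial_index][w.anchor] + w.start_s
                t1 = t0 + w.duration
                n = int(np.searchsorted(st, t1) - np.searchsorted(st, t0))
                by_window[w.name].setdefault(tt, []).append(n / w.duration)
        for w in windows:
            rates: dict[TrialType, tuple[float, int, float]] = {}
            trial_rates: dict[TrialType, np.ndarray] = {}
            for tt, vals in by_window[w.name].items():
                if len(vals) < min_trials:
                    continue
                arr = np.asarray(vals, float)
                rates[tt] = (
                    float(arr.mean()), len(arr),
                    float(arr.std(ddof=1) / math.sqrt(len(arr))),
                )
                trial_rates[tt] = arr
            responses.append(NeuronalResponse(
                cell_id=cell_id, hemisphere=hemi, window=w.name,
                rates=rates, trial_rates=trial_rates,
            ))
    return responses


# ---------------------------------------------------------------------------
# ANOVA screening


def _one_way_p(groups: list[np.ndarray]) -> float:
    if len(groups) < 2:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.f_oneway(*groups)
    p = float(res.pvalue)
    return p if np.isfinite(p) else 1.0  # identical constant groups -> no evidence


def _three_way_p(response: NeuronalResponse) -> dict[str, float]:
    """Type-II main-effect p-values for offer type, position of A, chosen side.

    Factors with a single level are skipped with a warning.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rows = []
    for tt, arr in response.trial_rates.items():
        for v in arr:
            rows.append({
                "rate": v,
                "offer": f"{tt.qA}:{tt.qB}",
                "pos": tt.position_of_A,
                "side": tt.chosen_side,
            })
    df = pd.DataFrame(rows)
    factors = {"offer_type": "offer", "position_of_A": "pos", "chosen_side": "side"}
    terms = []
    out: dict[str, float] = {}
    for name, col in factors.items():
        if df[col].nunique() < 2:
            warnings.warn(
                f"{response.cell_id}/{response.window}: factor {name} has a "
                "single level; skipped"
            )
            out[name] = math.nan
        else:
            terms.append((name, col))
    if not terms or df["rate"].nunique() < 2:
        for name, _ in terms:
            out[name] = 1.0
        return out
    formula = "rate ~ " + " + ".join(f"C({c})" for _, c in terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.ols(formula, data=df).fit()
            table = anova_lm(model, typ=2)
        except Exception:
            for name, _ in terms:
                out[name] = math.nan
            return out
    for name, col in terms:
        p = float(table.loc[f"C({col})", "PR(>F)"])
        out[name] = p if np.isfinite(p) else 1.0
    return out


def anova_screen(
    responses: list[NeuronalResponse],
    alpha: float = TASK_RELATED_P,
    three_way: bool = True,
) -> list[NeuronalResponse]:
    """Annotate responses in place with ANOVA p-values and task-relatedness.

    ``task_related`` is True iff the 1-way trial-type ANOVA on per-trial
    rates gives p < ``alpha``. The 3-way main effects feed the summary
    tables but play no role in inclusion.
    """
    for resp in responses:
        groups = [resp.trial_rates[tt] for tt in resp.trial_types()]
        p1 = _one_way_p(groups)
        resp.anova_p = {"trial_type": p1}
        if three_way and resp.rates:
            resp.anova_p.update(_three_way_p(resp))
        resp.task_related = bool(p1 < alpha) and len(groups) >= 2
    return responses


def anova_count_table(
    responses: list[NeuronalResponse], alpha: float = TASK_RELATED_P
) -> pd.DataFrame:
    """Cells significantly modulated per factor and window (plus 'at_least_1')."""
    factors = ["offer_type", "position_of_A", "chosen_side", "trial_type"]
    windows = sorted({r.window for r in responses})
    counts = pd.DataFrame(0, index=windows + ["at_least_1"], columns=factors)
    sig_cells: dict[str, set[str]] = {f: set() for f in factors}
    for r in responses:
        for f in factors:
            p = r.anova_p.get(f, math.nan)
            if np.isfinite(p) and p < alpha:
                counts.loc[r.window, f] += 1
                sig_cells[f].add(r.cell_id)
    for f in factors:
        counts.loc["at_least_1", f] = len(sig_cells[f])
    return counts


# ---------------------------------------------------------------------------
# candidate decision variables


def compute_variables(trial_types: Iterable[TrialType], rho: float) -> pd.DataFrame:
    """Twelve candidate-variable values per trial type (units of juice B).

    Conditional variables (e.g. ``chosen_value_A``) equal ``chosen_value``
    when their condition holds and 0 otherwise; ``position_of_A``,
    ``chosen_juice`` and ``chosen_side`` are 0/1 indicators (A on ipsi side,
    A chosen, ipsi side chosen).
    """
    if not (np.isfinite(rho) and rho > 0):
        raise ValueError("rho must be finite and positive")
    rows = {}
    for tt in trial_types:
        v_A = rho * tt.qA
        v_B = float(tt.qB)
        a_ipsi = tt.position_of_A == "ipsi"
        chose_A = tt.chosen_juice == "A"
        chose_ipsi = tt.chosen_side == "ipsi"
        chosen_value = v_A if chose_A else v_B
        rows[tt] = {
            "position_of_A": 1.0 if a_ipsi else 0.0,
            "offer_value_A": v_A,
            "offer_value_B": v_B,
            "offer_value_ipsi": v_A if a_ipsi else v_B,
            "offer_value_contra": v_B if a_ipsi else v_A,
            "chosen_value": chosen_value,
            "chosen_value_A": chosen_value if chose_A else 0.0,
            "chosen_value_B": 0.0 if chose_A else chosen_value,
            "chosen_value_ipsi": chosen_value if chose_ipsi else 0.0,
            "chosen_value_contra": 0.0 if chose_ipsi else chosen_value,
            "chosen_juice": 1.0 if chose_A else 0.0,
            "chosen_side": 1.0 if chose_ipsi else 0.0,
        }
    tts = list(rows)
    # object index of TrialType tuples (avoid pandas' tuple->MultiIndex coercion)
    idx = np.empty(len(tts), dtype=object)
    for i, tt in enumerate(tts):
        idx[i] = tt
    df = pd.DataFrame([rows[tt] for tt in tts], columns=list(VARIABLES),
                      index=pd.Index(idx, name="trial_type"))
    return df


@dataclass(frozen=True)
class RegressionResult:
    cell_id: str
    window: str
    variable: str
    slope: float
    slope_p: float
    R2: float
    explains: bool
    constant_variable: bool = False

    @property
    def response_key(self) -> tuple[str, str]:
        return (self.cell_id, self.window)


def regress_variables(
    response: NeuronalResponse,
    variables: pd.DataFrame,
    explain_p: float = EXPLAIN_P,
) -> list[RegressionResult]:
    """OLS of trial-type mean rate on each candidate variable, separately.

    R^2 is recorded as 0 whenever the variable does not explain the
    response (slope p >= ``explain_p``), matching the population-analysis
    convention.
    """
    tts = response.trial_types()
    y = np.array([response.rates[tt][0] for tt in tts])
    out = []
    for var in variables.columns:
        col = variables[var].to_dict()
        x = np.array([col[tt] for tt in tts], float)
        if len(tts) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append(RegressionResult(
                response.cell_id, response.window, var,
                slope=math.nan, slope_p=1.0, R2=0.0, explains=False,
                constant_variable=bool(len(tts) > 0 and np.ptp(x) == 0),
            ))
            continue
        res = stats.linregress(x, y)
        explains = bool(res.pvalue < explain_p)
        out.append(RegressionResult(
            response.cell_id, response.window, var,
            slope=float(res.slope), slope_p=float(res.pvalue),
            R2=float(res.rvalue**2) if explains else 0.0,
            explains=explains,
        ))
    return out


def regress_population(
    responses: list[NeuronalResponse],
    rho: float,
    explain_p: float = EXPLAIN_P,
    task_related_only: bool = True,
) -> list[RegressionResult]:
    """Per-variable regressions for (by default) every task-related response."""
    results: list[RegressionResult] = []
    for resp in responses:
        if task_related_only and not resp.task_related:
            continue
        if not resp.rates:
            continue
        variables = compute_variables(resp.trial_types(), rho)
        results.extend(regress_variables(resp, variables, explain_p))
    return results


# ---------------------------------------------------------------------------
# population summaries and variable selection


def _group_results(
    results: Iterable[RegressionResult],
) -> dict[tuple[str, str], list[RegressionResult]]:
    grouped: dict[tuple[str, str], list[RegressionResult]] = {}
    for r in results:
        grouped.setdefault(r.response_key, []).append(r)
    return grouped


def _best_variable(rs: list[RegressionResult]) -> str | None:
    """Best-fit variable of one response; None if nothing explains it.

    Ties in R^2 break toward the smaller slope p-value, then alphabetically.
    """
    explaining = [r for r in rs if r.explains and r.R2 > 0.0]
    if not explaining:
        return None
    best = min(explaining, key=lambda r: (-r.R2, r.slope_p, r.variable))
    return best.variable


def best_fit_counts(results: Iterable[RegressionResult]) -> pd.DataFrame:
    """Responses best-fit per (window, variable); each response counts once."""
    grouped = _group_results(results)
    windows = sorted({k[1] for k in grouped})
    counts = pd.DataFrame(0, index=list(VARIABLES), columns=windows)
    for key, rs in grouped.items():
        var = _best_variable(rs)
        if var is not None:
            counts.loc[var, key[1]] += 1
    return counts


def explained_counts(results: Iterable[RegressionResult]) -> pd.DataFrame:
    """Responses explained per (window, variable); responses may count in many bins."""
    grouped = _group_results(results)
    windows = sorted({k[1] for k in grouped})
    counts = pd.DataFrame(0, index=list(VARIABLES), columns=windows)
    for key, rs in grouped.items():
        for r in rs:
            if r.explains:
                counts.loc[r.variable, key[1]] += 1
    return counts


@dataclass
class SelectionResult:
    method: str  # "stepwise" | "best_subset"
    selected: list[str]
    marginal_power: dict[str, float]  # percent of task-related responses
    n_explained_by_selected: int
    n_explained_by_all: int
    n_task_related: int
    trace: list[dict] = field(default_factory=list)
    ties: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def pct_of_all_explained(self) -> float:
        if self.n_explained_by_all == 0:
            return math.nan
        return 100.0 * self.n_explained_by_selected / self.n_explained_by_all


def explained_percentage(n_explained_by_selected: int, n_explained_by_all: int) -> float:
    """Percent of collectively-explained responses covered by a selected set."""
    if n_explained_by_all <= 0:
        raise ValueError("no responses are explained by any variable")
    return 100.0 * n_explained_by_selected / n_explained_by_all


def _explain_sets(
    results: Iterable[RegressionResult],
) -> tuple[dict[tuple[str, str], set[str]], dict[tuple[str, str], str | None]]:
    grouped = _group_results(results)
    expl = {k: {r.variable for r in rs if r.explains} for k, rs in grouped.items()}
    best = {k: _best_variable(rs) for k, rs in grouped.items()}
    return expl, best


def _marginal_power(
    variable: str,
    selected: Sequence[str],
    expl: dict[tuple[str, str], set[str]],
) -> float:
    """Percent of task-related responses explained by ``variable`` and by no
    other selected variable."""
    others = set(selected) - {variable}
    n = sum(
        1 for s in expl.values() if variable in s and not (s & others)
    )
    return 100.0 * n / len(expl) if expl else 0.0


def stepwise_select(
    results: Iterable[RegressionResult],
    power_threshold_pct: float = MARGINAL_POWER_PCT,
) -> SelectionResult:
    """Greedy variable selection constrained by marginal explanatory power.

    At each iteration the candidate is the variable with the highest number
    of best fits within any single time window (ties: more responses
    explained overall, then alphabetical). The candidate is retained only if
    its marginal explanatory power is >= the threshold and its addition does
    not push any previously selected variable below the threshold (in which
    case the candidate is rejected and the procedure stops); on retention,
    every response it explains leaves the pool.
    """
    expl, best = _explain_sets(results)
    n_task = len(expl)
    n_all = sum(1 for s in expl.values() if s)
    selected: list[str] = []
    trace: list[dict] = []
    remaining = set(expl)

    while remaining:
        # best-fit counts per (window, variable) over the remaining pool
        counts: dict[tuple[str, str], int] = {}
        totals: dict[str, int] = {}
        for key in remaining:
            var = best[key]
            if var is None:
                continue
            counts[(key[1], var)] = counts.get((key[1], var), 0) + 1
            totals[var] = totals.get(var, 0) + 1
        if not counts:
            break
        candidate = min(
            counts,
            key=lambda wv: (-counts[wv], -totals.get(wv[1], 0), wv[1], wv[0]),
        )[1]
        mp = _marginal_power(candidate, selected + [candidate], expl)
        entry = {"candidate": candidate, "marginal_power": mp}
        if mp < power_threshold_pct:
            entry["outcome"] = "rejected: below threshold"
            trace.append(entry)
            break
        demoted = [
            s for s in selected
            if _marginal_power(s, selected + [candidate], expl) < power_threshold_pct
        ]
        if demoted:
            entry["outcome"] = f"rejected: would demote {demoted}"
            trace.append(entry)
            break
        entry["outcome"] = "selected"
        trace.append(entry)
        selected.append(candidate)
        remaining = {k for k in remaining if candidate not in expl[k]}

    n_sel = sum(1 for s in expl.values() if s & set(selected))
    return SelectionResult(
        method="stepwise",
        selected=selected,
        marginal_power={v: _marginal_power(v, selected, expl) for v in selected},
        n_explained_by_selected=n_sel,
        n_explained_by_all=n_all,
        n_task_related=n_task,
        trace=trace,
    )


def best_subset_select(
    results: Iterable[RegressionResult],
    d: int,
    variables: Sequence[str] = VARIABLES,
) -> SelectionResult:
    """Exhaustive search for the size-``d`` subset explaining most responses.

    Responses are pooled across time windows; a response counts as explained
    by a subset when at least one member explains it. All maximizing subsets
    are reported in ``ties``; the primary pick is the alphabetically first.
    """
    if not (1 <= d <= len(variables)):
        raise ValueError(f"d must be in [1, {len(variables)}]")
    expl, _ = _explain_sets(results)
    n_task = len(expl)
    n_all = sum(1 for s in expl.values() if s)
    best_count = -1
    ties: list[tuple[str, ...]] = []
    for combo in itertools.combinations(sorted(variables), d):
        cs = set(combo)
        n = sum(1 for s in expl.values() if s & cs)
        if n > best_count:
            best_count, ties = n, [combo]
        elif n == best_count:
            ties.append(combo)
    selected = list(ties[0]) if ties else []
    return SelectionResult(
        method="best_subset",
        selected=selected,
        marginal_power={v: _marginal_power(v, selected, expl) for v in selected},
        n_explained_by_selected=max(best_count, 0),
        n_explained_by_all=n_all,
        n_task_related=n_task,
        ties=ties if len(ties) > 1 else [],
    )
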