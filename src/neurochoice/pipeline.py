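"""Orchestration of the three analyses into machine-readable reports.

Each report is a plain JSON-serializable dict that embeds the configuration
used, so reruns with the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from . import choice_models as cm
from . import neural_encoding as ne
from . import perturbation_effects as pe
from .session_data import Session, SpikeTable


@dataclass
class RunConfig:
    """Thresholds, window definitions and the seed a run is bound to."""

    anova_p: float = ne.TASK_RELATED_P
    explain_p: float = ne.EXPLAIN_P
    marginal_power_pct: float = ne.MARGINAL_POWER_PCT
    windows: tuple[ne.TimeWindow, ...] = ne.DEFAULT_WINDOWS
    include_pre_offer: bool = False  # in variable selection (screening uses all)
    best_subset_max_d: int = 6
    seed: int = 0

    def validate(self) -> None:
        for p in (self.anova_p, self.explain_p):
            if not 0.0 < p < 1.0:
                raise ValueError("significance thresholds must lie in (0, 1)")
        for w in self.windows:
            if w.anchor not in ("offer_on", "juice_on"):
                raise ValueError(f"bad window anchor {w.anchor!r}")
            if w.duration <= 0:
                raise ValueError(f"window {w.name} has non-positive duration")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = [dataclasses.asdict(w) for w in self.windows]
        return d


def _clean(x: float) -> float | None:
    return None if (x is None or not np.isfinite(x)) else float(x)


def run_behavior_report(sessions: list[Session], config: RunConfig | None = None) -> dict:
    """Per-session and per-mouse behavioral parameters with population summaries."""
    if not sessions:
        raise ValueError("no sessions given")
    config = config or RunConfig()
    config.validate()
    per_session = []
    warnings_list = []
    for i, session in enumerate(sessions):
        row: dict = {"session": i, "mouse_id": session.mouse_id}
        try:
            for name, fitter in cm.FITTERS.items():
                fit = fitter(session)
                row[name] = fit.as_dict()
            row["converged"] = all(row[m]["converged"] for m in cm.FITTERS)
        except (cm.InsufficientDataError, ValueError) as exc:
            row["error"] = str(exc)
            row["converged"] = False
            warnings_list.append(f"session {i} ({session.mouse_id}): {exc}")
        per_session.append(row)

    usable = [r for r in per_session if r.get("converged")]
    params = {
        "rho": [r["basic"].get("rho") for r in usable],
        "eta": [r["basic"].get("eta") for r in usable],
        "epsilon": [r["side_bias"].get("epsilon") for r in usable],
        "xi": [r["choice_hyst"].get("xi") for r in usable],
        "theta": [r["direction_hyst"].get("theta") for r in usable],
    }
    population = {}
    for name, vals in params.items():
        arr = np.array([v for v in vals if v is not None and np.isfinite(v)])
        if len(arr):
            population[name] = {
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if len(arr) > 1 else None,
                "sem": float(arr.std(ddof=1) / math.sqrt(len(arr)))
                if len(arr) > 1 else None,
                "n_sessions": int(len(arr)),
            }
    by_mouse: dict[str, list[dict]] = {}
    for r in usable:
        by_mouse.setdefault(r["mouse_id"], []).append(r)
    per_mouse = {
        m: {
            "n_sessions": len(rows),
            "mean_rho": float(np.mean([r["basic"]["rho"] for r in rows])),
            "mean_eta": float(np.mean([r["basic"]["eta"] for r in rows])),
        }
        for m, rows in sorted(by_mouse.items())
    }
    return {
        "config": config.as_dict(),
        "per_session": per_session,
        "per_mouse": per_mouse,
        "population": population,
        "n_sessions": len(sessions),
        "n_excluded": len(sessions) - len(usable),
        "warnings": warnings_list,
    }


def run_inactivation_report(
    sessions: list[Session], config: RunConfig | None = None
) -> dict:
    """Stimulation-effect report: per-session indices, per-mouse tests, CD."""
    config = config or RunConfig()
    config.validate()
    effects: list[pe.StimEffect] = []
    mouse_of_session: dict[str, str] = {}
    skipped = []
    for i, session in enumerate(sessions):
        sid = f"s{i:03d}"
        try:
            fit = cm.fit_stim_model(session, "basic")
        except (cm.InsufficientDataError, ValueError) as exc:
            skipped.append({"session": sid, "reason": str(exc)})
            continue
        if not fit.converged or not (fit.eta_OFF > 0 and fit.eta_ON > 0):
            skipped.append({"session": sid, "reason": "non-convergent stim fit"})
            continue
        ssi = pe.compute_SSI(fit.eta_OFF, fit.eta_ON)
        try:
            lsi = pe.compute_LSI(session)
        except (pe.InsufficientDataError, pe.DegenerateDataError):
            lsi = math.nan
        effects.append(pe.StimEffect(
            session_id=sid, rho_OFF=fit.rho_OFF, rho_ON=fit.rho_ON,
            eta_OFF=fit.eta_OFF, eta_ON=fit.eta_ON, SSI=ssi, LSI=lsi,
        ))
        mouse_of_session[sid] = session.mouse_id

    per_mouse: dict[str, dict] = {}
    groups: dict[str, list[pe.StimEffect]] = {}
    for eff in effects:
        groups.setdefault(mouse_of_session[eff.session_id], []).append(eff)
    for mouse, effs in sorted(groups.items()):
        entry: dict = {"n_sessions": len(effs), "mean_SSI": float(
            np.mean([e.SSI for e in effs]))}
        if len(effs) >= 3:
            log_rho_off = [math.log(e.rho_OFF) for e in effs
                           if np.isfinite(e.rho_OFF) and e.rho_OFF > 0]
            log_rho_on = [math.log(e.rho_ON) for e in effs
                          if np.isfinite(e.rho_ON) and e.rho_ON > 0]
            try:
                F, pF = pe.variance_broadening_test(log_rho_off, log_rho_on)
                entry["variance_F"] = {"F": F, "p": pF}
            except (pe.InsufficientDataError, pe.DegenerateDataError) as exc:
                entry["variance_F"] = {"error": str(exc)}
            t, pt = pe.steepness_reduction_test(
                [e.eta_OFF for e in effs], [e.eta_ON for e in effs]
            )
            entry["steepness_t"] = {"t": t, "p": pt}
            lsis = [e.LSI for e in effs if np.isfinite(e.LSI)]
            if len(lsis) >= 3:
                entry["mean_LSI"] = float(np.mean(lsis))
        per_mouse[mouse] = entry

    cd = pe.choice_deficits(effects, mouse_of_session) if effects else None
    return {
        "config": config.as_dict(),
        "group": sessions[0].group if sessions else None,
        "per_session": [
            {
                "session_id": e.session_id,
                "mouse_id": mouse_of_session[e.session_id],
                "rho_OFF": _clean(e.rho_OFF), "rho_ON": _clean(e.rho_ON),
                "eta_OFF": _clean(e.eta_OFF), "eta_ON": _clean(e.eta_ON),
                "SSI": _clean(e.SSI), "LSI": _clean(e.LSI),
            }
            for e in effects
        ],
        "per_mouse": per_mouse,
        "choice_deficit": cd.to_dict() if cd is not None else {},
        "skipped": skipped,
    }


def run_encoding_report(
    session: Session,
    spikes: SpikeTable,
    config: RunConfig | None = None,
    rho: float | None = None,
) -> dict:
    """Encoding report: ANOVA counts, explained/best-fit matrices, selections.

    ``rho`` defaults to the session's own basic-fit relative value; sessions
    whose fit does not converge are rejected, since candidate-variable values
    require a relative value to share units.
    """
    config = config or RunConfig()
    config.validate()
    if rho is None:
        fit = cm.fit_basic(session)
        if not fit.converged or not np.isfinite(fit.rho):
            raise ValueError("session relative value is undefined (flagged fit)")
        rho = fit.rho

    responses = ne.build_responses(session, spikes, windows=config.windows)
    ne.anova_screen(responses, alpha=config.anova_p)
    results = ne.regress_population(responses, rho, explain_p=config.explain_p)
    if config.include_pre_offer:
        selection_results = results
    else:
        selection_results = [r for r in results if r.window != "pre_offer"]

    report: dict = {
        "config": config.as_dict(),
        "rho": float(rho),
        "n_cells": len(spikes.cell_ids),
        "n_responses": len(responses),
        "n_task_related": sum(1 for r in responses if r.task_related),
        "anova_counts": ne.anova_count_table(responses, config.anova_p)
        .to_dict(),
        "explained_counts": ne.explained_counts(results).to_dict(),
        "best_fit_counts": ne.best_fit_counts(results).to_dict(),
        "selection_windows": "all" if config.include_pre_offer else "post_pre_offer_excluded",
    }
    if not any(r.task_related for r in responses):
        report["stepwise"] = None
        report["message"] = "no task-related responses"
        return report

    step = ne.stepwise_select(selection_results, config.marginal_power_pct)
    report["stepwise"] = {
        "selected": step.selected,
        "marginal_power": step.marginal_power,
        "n_explained_by_selected": step.n_explained_by_selected,
        "n_explained_by_all": step.n_explained_by_all,
        "n_task_related": step.n_task_related,
        "pct_of_all_explained": _clean(step.pct_of_all_explained),
        "trace": step.trace,
    }
    curve = []
    for d in range(1, config.best_subset_max_d + 1):
        bs = ne.best_subset_select(selection_results, d)
        curve.append({
            "d": d, "selected": bs.selected,
            "n_explained": bs.n_explained_by_selected,
        })
    report["best_subset_curve"] = curve
    return report
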