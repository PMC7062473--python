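"""Neuronal responses, ANOVA screening, regression, and variable selection."""

import itertools
import math

import numpy as np
import pytest

from neurochoice import neural_encoding as ne
from neurochoice import synthetic_data as sd
from neurochoice.neural_encoding import (
    RegressionResult,
    TrialType,
    NeuronalResponse,
)


def _session_and_population(cells, seed=5, n_trials=250, rho=2.4):
    params = sd.BehaviorGenParams(rho=rho, n_trials=n_trials, seed=seed)
    session = sd.gen_session(params)
    spikes = sd.gen_population(session, cells, rho=rho)
    return session, spikes, rho


def _cell(cid, var, gain, hemi="left", baseline=4.0, seed=0):
    return sd.NeuronGenParams(cell_id=cid, encoded_variable=var,
                              baseline=baseline, gain=gain,
                              hemisphere=hemi, seed=seed)


class TestBuildResponses:
    def test_constant_rate_cell_recovers_baseline(self):
        session, spikes, rho = _session_and_population(
            [_cell("c0", "untuned", 0.0, baseline=10.0)])
        responses = ne.build_responses(session, spikes)
        rates = [m for r in responses for (m, n, s) in r.rates.values()]
        assert np.mean(rates) == pytest.approx(10.0, rel=0.05)

    def test_small_trial_types_excluded(self):
        session, spikes, rho = _session_and_population(
            [_cell("c0", "untuned", 0.0)], n_trials=150)
        responses = ne.build_responses(session, spikes)
        for r in responses:
            for tt, (mean, n, sem) in r.rates.items():
                assert n >= 3

    def test_hemisphere_maps_sides_to_ipsi_contra(self):
        session, spikes, _ = _session_and_population(
            [_cell("cl", "untuned", 0.0, hemi="left"),
             _cell("cr", "untuned", 0.0, hemi="right")])
        responses = ne.build_responses(session, spikes)
        by_cell = {}
        for r in responses:
            by_cell.setdefault(r.cell_id, set()).update(
                tt.position_of_A for tt in r.rates)
        # a left trial is ipsi for the left-hemisphere cell, contra for the right
        assert by_cell["cl"] == {"ipsi", "contra"}
        assert by_cell["cr"] == {"ipsi", "contra"}

    def test_relabeling_invariance(self):
        """Flipping all hemispheres and all trial sides leaves results fixed."""
        from neurochoice.session_data import Session, Trial, opposite_side

        cells = [_cell("c0", "offer_value_ipsi", 0.8, hemi="left", seed=3)]
        session, spikes, rho = _session_and_population(cells, seed=6)
        resp = ne.build_responses(session, spikes)

        flipped_trials = [
            Trial(t.trial_index, t.qA, t.qB, opposite_side(t.side_of_A),
                  t.stim, t.chosen_juice,
                  t.chosen_side if t.chosen_side == "none"
                  else opposite_side(t.chosen_side),
                  t.is_error, t.offer_on_s, t.go_s, t.juice_on_s)
            for t in session.trials
        ]
        flipped_session = Session(mouse_id=session.mouse_id,
                                  trials=flipped_trials, licks=session.licks)
        flipped_spikes = type(spikes)(
            events=spikes.events,
            hemispheres={c: opposite_side(h)
                         for c, h in spikes.hemispheres.items()})
        resp_flipped = ne.build_responses(flipped_session, flipped_spikes)
        for a, b in zip(resp, resp_flipped):
            assert a.rates == b.rates


class TestAnovaScreen:
    def test_untuned_cells_rarely_task_related(self):
        cells = [_cell(f"c{i}", "untuned", 0.0, seed=100 + i)
                 for i in range(40)]
        session, spikes, rho = _session_and_population(cells, seed=7)
        responses = ne.anova_screen(
            ne.build_responses(session, spikes), three_way=False)
        fp = sum(1 for r in responses if r.task_related)
        assert fp / len(responses) < 0.02  # nominal rate is 0.1%

    def test_tuned_cell_detected_with_main_effect(self):
        cells = [_cell("c0", "chosen_side", 10.0, seed=8)]
        session, spikes, rho = _session_and_population(cells, seed=8)
        responses = ne.anova_screen(ne.build_responses(session, spikes))
        post = [r for r in responses if r.window == "late_delay"][0]
        assert post.task_related
        assert post.anova_p["chosen_side"] < 0.001

    def test_identical_constant_counts_degenerate_ok(self):
        tts = [TrialType(1, 2, "ipsi", "ipsi"), TrialType(1, 2, "ipsi", "contra"),
               TrialType(2, 1, "contra", "ipsi")]
        resp = NeuronalResponse(
            cell_id="c", hemisphere="left", window="post_offer",
            rates={tt: (5.0, 4, 0.0) for tt in tts},
            trial_rates={tt: np.full(4, 5.0) for tt in tts})
        ne.anova_screen([resp], three_way=True)
        assert resp.anova_p["trial_type"] == 1.0
        assert resp.task_related is False


class TestVariableTable:
    def test_values_in_units_of_juice_B(self):
        tts = [TrialType(2, 3, "ipsi", "contra")]
        tab = ne.compute_variables(tts, rho=2.5)
        row = tab.iloc[0]
        assert row["offer_value_A"] == 5.0
        assert row["offer_value_B"] == 3.0
        assert row["offer_value_ipsi"] == 5.0  # A sits ipsi
        assert row["offer_value_contra"] == 3.0
        # contra chosen while A is ipsi -> B chosen
        assert row["chosen_juice"] == 0.0
        assert row["chosen_value"] == 3.0
        assert row["chosen_value_B"] == 3.0
        assert row["chosen_value_A"] == 0.0
        assert row["chosen_value_contra"] == 3.0
        assert row["chosen_value_ipsi"] == 0.0
        assert row["position_of_A"] == 1.0
        assert row["chosen_side"] == 0.0

    def test_conditional_variables_zero_otherwise(self):
        tts = [TrialType(1, 0, "ipsi", "ipsi")]  # forced A, chosen ipsi=A
        row = ne.compute_variables(tts, rho=2.0).iloc[0]
        assert row["chosen_value"] == 2.0
        assert row["chosen_value_A"] == 2.0
        assert row["chosen_value_B"] == 0.0

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            ne.compute_variables([TrialType(1, 2, "ipsi", "ipsi")], rho=0.0)


def _response_from_rates(rates_by_tt):
    return NeuronalResponse(
        cell_id="c", hemisphere="left", window="post_offer",
        rates={tt: (v, 5, 0.1) for tt, v in rates_by_tt.items()},
        trial_rates={tt: np.full(5, v) for tt, v in rates_by_tt.items()},
        task_related=True)


class TestRegressVariables:
    def test_exact_linear_tuning(self):
        tts = [TrialType(q, b, pos, ch)
               for q, b, pos, ch in [(1, 1, "ipsi", "ipsi"),
                                     (1, 2, "ipsi", "contra"),
                                     (1, 3, "contra", "contra"),
                                     (2, 1, "contra", "ipsi"),
                                     (3, 2, "ipsi", "ipsi")]]
        tab = ne.compute_variables(tts, rho=2.0)
        col = tab["offer_value_ipsi"].to_dict()
        rates = {tt: 2.0 + 3.0 * col[tt] for tt in tts}
        resp = _response_from_rates(rates)
        results = ne.regress_variables(resp, tab)
        r = next(x for x in results if x.variable == "offer_value_ipsi")
        assert r.slope == pytest.approx(3.0)
        assert r.R2 == pytest.approx(1.0)
        assert r.explains

    def test_constant_variable_flagged(self):
        tts = [TrialType(1, b, "ipsi", "ipsi") for b in (1, 2, 3)]
        tab = ne.compute_variables(tts, rho=2.0)
        resp = _response_from_rates({tt: float(i) for i, tt in enumerate(tts)})
        results = ne.regress_variables(resp, tab)
        r = next(x for x in results if x.variable == "position_of_A")
        assert r.constant_variable and not r.explains and r.R2 == 0.0

    def test_nonexplaining_R2_forced_to_zero(self):
        rng = np.random.default_rng(11)
        tts = [TrialType(q, b, p, c)
               for q in (1, 2) for b in (1, 2, 3)
               for p in ("ipsi", "contra") for c in ("ipsi", "contra")]
        tab = ne.compute_variables(tts, rho=2.0)
        resp = _response_from_rates({tt: rng.normal(10, 0.3) for tt in tts})
        for r in ne.regress_variables(resp, tab):
            if not r.explains:
                assert r.R2 == 0.0


def _make_results(spec):
    """spec: list of (cell, window, {variable: (R2, p)}) response definitions."""
    out = []
    for cell, window, vars_ in spec:
        for var, (r2, p) in vars_.items():
            out.append(RegressionResult(
                cell_id=cell, window=window, variable=var,
                slope=1.0, slope_p=p, R2=r2 if p < 0.05 else 0.0,
                explains=p < 0.05))
    return out


def _toy_population():
    """100 responses: 40 only offer_value_ipsi, 40 only chosen_side, 20 none."""
    spec = []
    for i in range(40):
        spec.append((f"a{i}", "post_offer",
                     {"offer_value_ipsi": (0.8, 0.001), "chosen_side": (0.0, 0.5)}))
    for i in range(40):
        spec.append((f"b{i}", "late_delay",
                     {"chosen_side": (0.7, 0.001), "offer_value_ipsi": (0.0, 0.5)}))
    for i in range(20):
        spec.append((f"n{i}", "post_juice", {"chosen_value": (0.0, 0.9)}))
    return _make_results(spec)


class TestBestFitCounts:
    def test_single_response_single_bin(self):
        results = _make_results(
            [("c0", "post_offer", {"chosen_side": (0.5, 0.01),
                                   "chosen_juice": (0.0, 0.6)})])
        counts = ne.best_fit_counts(results)
        assert counts.loc["chosen_side", "post_offer"] == 1
        assert counts.to_numpy().sum() == 1

    def test_tie_broken_by_p_then_alphabetical_deterministic(self):
        results = _make_results(
            [("c0", "post_offer", {"chosen_side": (0.5, 0.01),
                                   "chosen_juice": (0.5, 0.01)})])
        counts = ne.best_fit_counts(results)
        assert counts.loc["chosen_juice", "post_offer"] == 1
        counts2 = ne.best_fit_counts(list(reversed(results)))
        assert counts.equals(counts2)

    def test_unexplained_responses_contribute_nowhere(self):
        counts = ne.best_fit_counts(_toy_population())
        assert counts.to_numpy().sum() == 80


class TestStepwise:
    def test_empty_selection_when_nothing_explained(self):
        results = _make_results(
            [(f"c{i}", "post_offer", {"chosen_side": (0.0, 0.9)})
             for i in range(10)])
        sel = ne.stepwise_select(results)
        assert sel.selected == []
        assert sel.n_explained_by_all == 0

    def test_toy_population_both_selected_with_power_40(self):
        sel = ne.stepwise_select(_toy_population())
        assert set(sel.selected) == {"offer_value_ipsi", "chosen_side"}
        # tie on best-fit counts (40 vs 40) resolves alphabetically
        assert sel.selected[0] == "chosen_side"
        assert sel.marginal_power["offer_value_ipsi"] == pytest.approx(40.0)
        assert sel.marginal_power["chosen_side"] == pytest.approx(40.0)
        assert sel.n_explained_by_selected == 80
        assert sel.n_task_related == 100

    def test_candidate_below_threshold_rejected(self):
        spec = [(f"c{i}", "post_offer", {"chosen_side": (0.5, 0.01)})
                for i in range(96)]
        spec += [(f"d{i}", "post_offer", {"chosen_value": (0.5, 0.01)})
                 for i in range(4)]  # 4% marginal power
        sel = ne.stepwise_select(_make_results(spec))
        assert sel.selected == ["chosen_side"]
        assert sel.trace[-1]["outcome"].startswith("rejected")


class TestBestSubset:
    def test_full_set_explains_everything_explained(self):
        results = _toy_population()
        sel = ne.best_subset_select(results, 12)
        assert sel.n_explained_by_selected == sel.n_explained_by_all == 80

    def test_d1_on_toy_population(self):
        sel = ne.best_subset_select(_toy_population(), 1)
        assert sel.n_explained_by_selected == 40
        assert sel.selected[0] in {"offer_value_ipsi", "chosen_side"}
        flat = {v for tie in sel.ties for v in tie}
        assert flat == {"offer_value_ipsi", "chosen_side"}

    def test_monotone_in_d_and_dominates_stepwise(self):
        rng = np.random.default_rng(21)
        spec = []
        for i in range(60):
            vars_ = {}
            for var in rng.choice(ne.VARIABLES, size=3, replace=False):
                vars_[var] = (rng.uniform(0.2, 0.9),
                              0.01 if rng.random() < 0.6 else 0.5)
            if not vars_:
                vars_["chosen_side"] = (0.0, 0.9)
            spec.append((f"c{i}", "post_offer", vars_))
        results = _make_results(spec)
        counts = [ne.best_subset_select(results, d).n_explained_by_selected
                  for d in range(1, 7)]
        assert counts == sorted(counts)
        step = ne.stepwise_select(results, power_threshold_pct=0.0)
        for d in range(1, min(6, len(step.selected)) + 1):
            expl, _ = ne._explain_sets(results)
            first_d = set(step.selected[:d])
            n_step = sum(1 for s in expl.values() if s & first_d)
            assert ne.best_subset_select(results, d).n_explained_by_selected >= n_step

    def test_invalid_d_rejected(self):
        with pytest.raises(ValueError):
            ne.best_subset_select([], 0)


def test_explained_percentage_convention():
    assert ne.explained_percentage(457, 501) == pytest.approx(91.2, abs=0.1)
    with pytest.raises(ValueError):
        ne.explained_percentage(0, 0)
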