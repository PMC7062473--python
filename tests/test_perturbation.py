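"""Stimulation-effect indices, distribution tests, and the lesion LASSO map."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurochoice import perturbation_effects as pe
from neurochoice import synthetic_data as sd

pos = st.floats(0.05, 20.0, allow_nan=False)


class TestIndices:
    def test_ssi_no_effect_is_zero(self):
        assert pe.compute_SSI(1.0, 1.0) == 0.0

    def test_ssi_halved_steepness(self):
        assert pe.compute_SSI(2.0, 1.0) == pytest.approx(-0.6667, abs=1e-4)

    def test_ssi_rejects_nonpositive(self):
        with pytest.raises(pe.DegenerateDataError):
            pe.compute_SSI(0.0, 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(x=pos, y=pos)
    def test_ssi_antisymmetric_and_bounded(self, x, y):
        s = pe.compute_SSI(x, y)
        assert s == pytest.approx(-pe.compute_SSI(y, x))
        assert -2.0 < s < 2.0

    def test_lsi_printed_lick_means(self):
        """Mean lick counts of 12.9 (OFF) and 11.0 (ON) give LSI near -0.16."""
        assert pe.lick_stimulation_index(12.9, 11.0) == pytest.approx(
            -0.159, abs=1e-3)

    def test_lsi_identical_lick_trains_zero(self):
        session = sd.gen_session(sd.BehaviorGenParams(
            n_trials=400, seed=1, stim=sd.StimGenParams(2.0, 1.0),
            lick_rate_OFF=4.0, lick_rate_ON=4.0))
        assert abs(pe.compute_LSI(session)) < 0.1

    def test_lsi_halved_lick_rate(self):
        session = sd.gen_session(sd.BehaviorGenParams(
            n_trials=2000, seed=2, stim=sd.StimGenParams(2.0, 1.0),
            lick_rate_OFF=4.0, lick_rate_ON=2.0))
        assert pe.compute_LSI(session) == pytest.approx(-0.667, abs=0.07)

    def test_lsi_zero_denominator_raises(self):
        session = sd.gen_session(sd.BehaviorGenParams(
            n_trials=50, seed=3, stim=sd.StimGenParams(2.0, 1.0),
            lick_rate_OFF=0.0, lick_rate_ON=0.0))
        with pytest.raises(pe.DegenerateDataError):
            pe.compute_LSI(session)

    def test_choice_deficit_sign(self):
        effects = [
            pe.StimEffect("s0", 2.0, 2.5, 1.0, 0.6, pe.compute_SSI(1.0, 0.6)),
            pe.StimEffect("s1", 2.0, 1.5, 1.2, 0.8, pe.compute_SSI(1.2, 0.8)),
        ]
        cd = pe.choice_deficits(effects, {"s0": "m1", "s1": "m1"})
        assert cd["m1"] > 0  # steepness dropped, so the deficit is positive


class TestDistributionTests:
    def test_f_identical_samples(self):
        x = [0.5, 0.7, 0.9, 1.1, 0.6]
        F, p = pe.variance_broadening_test(x, x)
        assert F == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_f_zero_variance_raises(self):
        with pytest.raises(pe.DegenerateDataError):
            pe.variance_broadening_test([1.0, 1.0, 1.0], [0.5, 0.7, 0.9])

    def test_f_power_under_broadening(self):
        rej = 0
        for i in range(300):
            df = sd.gen_stim_parameter_sets(15, seed=5000 + i, effect=True)
            _, p = pe.variance_broadening_test(df.log_rho_OFF, df.log_rho_ON)
            rej += p < 0.01
        assert rej / 300 > 0.5  # vastly above the 1% nominal rate

    def test_t_identical_pairs(self):
        x = [1.0, 1.2, 0.8, 1.1]
        t, p = pe.steepness_reduction_test(x, x)
        assert t == 0.0 and p == 1.0

    def test_t_mismatched_lengths(self):
        with pytest.raises(ValueError):
            pe.steepness_reduction_test([1.0, 1.0], [1.0])

    def test_t_power_under_steepness_drop(self):
        for m in range(3):
            df = sd.gen_stim_parameter_sets(15, seed=600 + m, effect=True)
            t, p = pe.steepness_reduction_test(df.eta_OFF, df.eta_ON)
            assert t < 0 and p < 0.01


class TestCorrelation:
    def test_perfect_linear(self):
        effects = [pe.StimEffect(f"s{i}", 2, 2, 1, 1, SSI=0.1 * i, LSI=0.2 * i)
                   for i in range(6)]
        out = pe.ssi_lsi_correlation(effects)
        assert out["r"] == pytest.approx(1.0)

    def test_independent_indices_mean_r_near_zero(self):
        rng = np.random.default_rng(9)
        rs = []
        for _ in range(300):
            effects = [
                pe.StimEffect(f"s{i}", 2, 2, 1, 1,
                              SSI=rng.normal(), LSI=rng.normal())
                for i in range(20)
            ]
            rs.append(pe.ssi_lsi_correlation(effects)["r"])
        assert abs(np.mean(rs)) < 0.05

    def test_noise_attenuation_matches_closed_form(self):
        """r for LSI = SSI + noise matches 1/sqrt(1 + sigma^2/var(SSI))."""
        rng = np.random.default_rng(10)
        sigma, n = 0.5, 60
        rs = []
        for _ in range(200):
            ssi = rng.normal(0.0, 0.4, n)
            lsi = ssi + rng.normal(0.0, sigma, n)
            effects = [pe.StimEffect(f"s{i}", 2, 2, 1, 1, SSI=s, LSI=l)
                       for i, (s, l) in enumerate(zip(ssi, lsi))]
            rs.append(pe.ssi_lsi_correlation(effects)["r"])
        expected = 1.0 / math.sqrt(1.0 + sigma**2 / 0.4**2)
        assert np.mean(rs) == pytest.approx(expected, abs=0.03)

    def test_exclusions_are_reported(self):
        effects = [pe.StimEffect(f"s{i}", 2, 2, 1, 1,
                                 SSI=0.1 * i, LSI=0.05 * (i % 3))
                   for i in range(5)]
        out = pe.ssi_lsi_correlation(effects, exclude={"s0"})
        assert out["excluded_sessions"] == ["s0"]
        assert out["n"] == 4

    def test_too_few_sessions_raises(self):
        effects = [pe.StimEffect("s0", 2, 2, 1, 1, SSI=0.1, LSI=0.1)]
        with pytest.raises(pe.InsufficientDataError):
            pe.ssi_lsi_correlation(effects)

    def test_robust_outlier_mask(self):
        x = np.array([0.0, 0.1, -0.1, 0.05, -0.05, 10.0])
        mask = pe.robust_outliers(x)
        assert mask.tolist() == [False] * 5 + [True]


class TestLassoDeficitMap:
    def test_exact_single_area_support(self):
        X, _ = sd.gen_lesion_dataset(6, noise_sd=0.0, seed=1)
        z = (X - X.mean()) / X.std(ddof=0)
        y = 0.8 * z["LO_a1"]
        res = pe.lasso_deficit_map(X, y)
        assert res.coefficients["LO_a1"] > 0.4
        others = res.coefficients.drop("LO_a1").abs()
        assert (others < 0.05).all()

    def test_all_zero_deficit_gives_zero_map(self):
        X, _ = sd.gen_lesion_dataset(5, seed=2)
        y = pd.Series(0.0, index=X.index)
        res = pe.lasso_deficit_map(X, y)
        assert (res.coefficients == 0.0).all()

    def test_too_few_mice_raises(self):
        X, y = sd.gen_lesion_dataset(3, seed=3)
        with pytest.raises(pe.InsufficientDataError):
            pe.lasso_deficit_map(X.iloc[:2], y.iloc[:2])

    def test_constant_column_dropped_with_warning(self):
        X, y = sd.gen_lesion_dataset(5, beta={"LO_a1": 0.8},
                                     noise_sd=0.05, seed=4)
        X = X.copy()
        X["EX"] = 100.0
        with pytest.warns(UserWarning, match="EX"):
            res = pe.lasso_deficit_map(X, y)
        assert "EX" in res.dropped_areas
        assert "EX" not in res.coefficients.index

    def test_infinite_penalty_limit_is_all_zero(self):
        X, y = sd.gen_lesion_dataset(5, beta={"LO_a1": 0.8},
                                     noise_sd=0.05, seed=5)
        res = pe.lasso_deficit_map(X, y)
        # at the top of the path (largest penalty) everything is zero
        top = res.support_path.iloc[0]
        assert not top.any()
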