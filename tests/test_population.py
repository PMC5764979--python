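"""Population-level statistics: model selection, attenuation, dispersion."""

import numpy as np
import pandas as pd
import pytest

from divnorm import fitting, population, simulate
from divnorm.population import (
    binned_coefficients,
    context_attenuation,
    epoch_proportions,
    equal_ev_deviation,
    parameter_dispersion,
    parameter_kruskal,
    parameter_sanity,
    phase_trials,
    population_best_model,
    risk_attitude_correlation,
)


class TestBestModel:
    def test_identical_aics_give_no_winner(self):
        table = pd.DataFrame({"M1": [10.0, 12.0, 9.0], "M2": [10.0, 12.0, 9.0]})
        out = population_best_model(table, "M1")
        assert out.loc[0, "t"] == 0.0
        assert not out.attrs["is_best"]

    def test_value_modulated_data_penalizes_null_model(self, schedule):
        """Mean AIC(M1) - AIC(M9) is negative when rates track value."""
        trials = simulate.simulate_behavior(schedule, simulate.BehaviorParams(), seed=1)
        rows = []
        for s in range(8):
            truth = simulate.GroundTruth("M1", {"R_max": 40.0, "beta": 20.0, "sigma": 60.0})
            sess = simulate.simulate_neuron(trials, truth, seed=500 + s)
            aics = {m: fitting.fit_model(sess.trials, "cue", m, "EVr+EVs-",
                                         n_restarts=15, seed=s).aic
                    for m in ("M1", "M9")}
            rows.append(aics)
        out = population_best_model(pd.DataFrame(rows), "M1")
        assert out.loc[0, "mean_aic_diff"] < 0

    def test_requires_reference_and_size(self):
        with pytest.raises(ValueError):
            population_best_model(pd.DataFrame({"M1": [1.0, 2.0]}), "M2")
        with pytest.raises(ValueError):
            population_best_model(pd.DataFrame({"M1": [1.0], "M2": [2.0]}), "M1")


class TestEpochProportions:
    def test_identical_proportions(self):
        r = epoch_proportions({"cue": (20, 100), "sac": (20, 100), "fb": (20, 100)})
        assert r.statistic == pytest.approx(0.0)
        assert r.df == 2

    def test_df_with_three_epochs(self):
        r = epoch_proportions({"cue": (28, 101), "sac": (29, 101), "fb": (24, 101)})
        assert r.df == 2 and r.p_value > 0.05

    def test_extreme_heterogeneity(self):
        r = epoch_proportions({"cue": (80, 100), "sac": (0, 100), "fb": (0, 100)})
        assert r.p_value < 0.001

    def test_zero_margin_flags_exact_fallback(self):
        r = epoch_proportions({"cue": (0, 100), "sac": (0, 100), "fb": (0, 100)})
        assert r.extra["exact_fallback"]


class TestContextAttenuation:
    def test_identical_coefficients(self):
        table = pd.DataFrame({
            "b_EVr_free": [0.03, 0.05], "b_EVr_forced": [0.03, 0.05],
            "b_EVs_free": [-0.04, -0.02], "b_EVs_forced": [-0.04, -0.02],
        })
        out = context_attenuation(table)
        assert out["EVr"].statistic == 0.0 and out["EVr"].p_value == 1.0

    def test_single_pair_rejected(self):
        table = pd.DataFrame({
            "b_EVr_free": [0.03], "b_EVr_forced": [0.01],
            "b_EVs_free": [-0.04], "b_EVs_forced": [-0.01],
        })
        with pytest.raises(ValueError):
            context_attenuation(table)

    def test_synthetic_attenuation_detected(self):
        rng = np.random.default_rng(0)
        n = 40
        free_evr = rng.normal(0.03, 0.005, n)
        table = pd.DataFrame({
            "b_EVr_free": free_evr, "b_EVr_forced": free_evr * 0.4,
            "b_EVs_free": -free_evr, "b_EVs_forced": -free_evr * 0.4,
        })
        out = context_attenuation(table)
        assert out["EVr"].p_value < 0.05
        assert out["EVr"].extra["mean_free"] > out["EVr"].extra["mean_forced"]


class TestBinnedCoefficients:
    def test_bin_counts(self, m1_session):
        out = binned_coefficients([(m1_session.trials, "cue")] * 3)
        per_context = out["table"].groupby("context")["bin_start"].nunique()
        assert per_context["forced"] == 3   # 36 forced trials -> 3 bins of 12
        assert per_context["free"] == 4     # 50 free trials -> 4 bins, 2 dropped

    def test_stationary_coding_is_typically_flat(self, schedule):
        trials = simulate.simulate_behavior(schedule, simulate.BehaviorParams(), seed=2)
        truth = simulate.GroundTruth("M3", {"G": 0.08, "b": 10.0})
        acts = [(simulate.simulate_neuron(trials, truth, seed=700 + s).trials, "cue")
                for s in range(10)]
        out = binned_coefficients(acts)
        assert out["anova"]["free"].p_value > 0.01  # no trend built in

    def test_boundary_test_pairs_activities(self, m1_session):
        out = binned_coefficients([(m1_session.trials, "cue")] * 5)
        assert out["boundary"].extra["n"] == 10  # 5 activities x 2 coefficients


class TestDispersion:
    def test_identical_groups_give_zero_f(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        table = pd.DataFrame({
            "phase": ["forced"] * 4 + ["free1"] * 4 + ["free2"] * 4,
            "R_max": np.tile(base, 3), "beta": np.tile(base, 3),
            "sigma": np.tile(base, 3),
        })
        out = parameter_dispersion(table)
        assert out["sigma"].statistic == pytest.approx(0.0)

    def test_wider_forced_spread_detected(self):
        rng = np.random.default_rng(1)
        n = 60
        table = pd.DataFrame({
            "phase": ["forced"] * n + ["free1"] * n + ["free2"] * n,
            "R_max": rng.normal(20, 5, 3 * n),
            "beta": np.r_[rng.normal(80, 100, n), rng.normal(80, 20, 2 * n)],
            "sigma": np.r_[rng.normal(90, 150, n), rng.normal(90, 30, 2 * n)],
        })
        out = parameter_dispersion(table)
        assert out["sigma"].p_value < 0.05 and out["beta"].p_value < 0.05

    def test_constant_group_flagged(self):
        table = pd.DataFrame({
            "phase": ["forced"] * 3 + ["free1"] * 3,
            "R_max": [1.0] * 3 + [1.0, 2.0, 3.0],
            "beta": [1.0, 2.0, 3.0] * 2, "sigma": [1.0, 2.0, 3.0] * 2,
        })
        assert parameter_dispersion(table)["R_max"].extra["constant_group"]

    def test_kruskal_identical_epochs(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(20, 5, 30)
        table = pd.DataFrame({
            "epoch": ["cue"] * 30 + ["sac"] * 30,
            "R_max": np.tile(vals, 2), "beta": np.tile(vals, 2),
            "sigma": np.tile(vals, 2),
        })
        out = parameter_kruskal(table)
        assert out["R_max"].statistic == pytest.approx(0.0, abs=1e-9)
        assert out["R_max"].p_value > 0.9


class TestParameterSanity:
    def test_recovers_strong_rmax_correlation(self):
        rng = np.random.default_rng(3)
        r_max = rng.uniform(10, 60, 40)
        table = pd.DataFrame({
            "R_max": r_max, "beta": rng.uniform(10, 100, 40),
            "sigma": rng.uniform(20, 200, 40),
            "max_rate": r_max * rng.normal(1.1, 0.1, 40),
            "baseline_rate": rng.uniform(5, 20, 40),
        })
        out = parameter_sanity(table)
        assert out["rmax_vs_max_rate"].statistic > 0.6

    def test_constant_baseline_flagged(self):
        table = pd.DataFrame({
            "R_max": [20.0, 30.0, 40.0], "beta": [50.0] * 3, "sigma": [100.0] * 3,
            "max_rate": [25.0, 33.0, 44.0], "baseline_rate": [8.0] * 3,
        })
        out = parameter_sanity(table)
        assert out["baseline_vs_baseline_rate"].extra.get("constant_input")

    def test_negative_parameters_excluded_from_baseline_relation(self):
        rng = np.random.default_rng(4)
        n = 20
        table = pd.DataFrame({
            "R_max": rng.uniform(10, 60, n), "beta": rng.uniform(10, 100, n),
            "sigma": rng.uniform(20, 200, n),
            "max_rate": rng.uniform(10, 70, n), "baseline_rate": rng.uniform(2, 20, n),
        })
        table.loc[0, "beta"] = -5.0
        out = parameter_sanity(table)
        assert out["baseline_vs_baseline_rate"].extra["n"] == n - 1


class TestRiskAttitude:
    def test_zero_deviations_degenerate(self):
        table = pd.DataFrame({
            "label": ["EVr+EVs-"] * 5, "deviation": [0.0] * 5,
            "risky_pct": [30.0, 40.0, 50.0, 60.0, 70.0],
        })
        out = risk_attitude_correlation(table)
        assert out["EVr+EVs-"].extra["degenerate"]

    def test_constructed_positive_and_mirrored_correlations(self):
        rng = np.random.default_rng(5)
        risky = rng.uniform(20, 80, 30)
        dev = 0.1 * (risky - 50) + rng.normal(0, 0.5, 30)
        table = pd.DataFrame({
            "label": ["EVr+EVs-"] * 30 + ["EVr-EVs+"] * 30,
            "deviation": np.r_[dev, -dev], "risky_pct": np.tile(risky, 2),
        })
        out = risk_attitude_correlation(table)
        assert out["EVr+EVs-"].statistic > 0.5
        assert out["EVr-EVs+"].statistic < -0.5

    def test_small_groups_omitted(self):
        table = pd.DataFrame({"label": ["EVr+EVs-"] * 2,
                              "deviation": [0.1, 0.2], "risky_pct": [40.0, 60.0]})
        assert risk_attitude_correlation(table) == {}

    def test_equal_ev_deviation_zero_for_linear_neuron(self, behavior_trials):
        """A perfectly linear-in-(EVr-EVs) neuron deviates by zero at LP3."""
        from conftest import noise_free_session

        truth = simulate.GroundTruth("M3", {"G": 0.1, "b": 15.0})
        sess = noise_free_session(behavior_trials, truth)
        assert equal_ev_deviation(sess.trials, "cue") == pytest.approx(0.0, abs=1e-9)


class TestPhases:
    def test_phase_partition(self, m1_session):
        t = m1_session.trials
        n = sum(len(phase_trials(t, p)) for p in ("forced", "free1", "free2"))
        assert n == len(t)
        assert (phase_trials(t, "forced")["context"] == "forced").all()
        assert (phase_trials(t, "free1")["context"] == "free").all()

    def test_unknown_phase(self, m1_session):
        with pytest.raises(ValueError):
            phase_trials(m1_session.trials, "warmup")
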