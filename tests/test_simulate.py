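"""Behavior and spike-count simulation: choice probabilities, Poisson noise."""

import numpy as np
import pandas as pd
import pytest

from divnorm import simulate, task
from divnorm.simulate import BehaviorParams, GroundTruth


def repeated_pair_schedule(block_id, lp_index, n, context="free"):
    """A schedule of one lottery pair repeated n times (single block)."""
    block = task.build_payoff_blocks()[block_id - 1]
    return pd.DataFrame({
        "block_id": block_id, "trial": np.arange(1, n + 1), "context": context,
        "lp_index": lp_index, "safe_mag_ul": block.safe_magnitude_ul,
        "risky_mag_ul": block.risky_magnitudes_ul[lp_index - 1],
        "instructed": "none" if context == "free" else "risky",
        "risky_side": "left",
    })


class TestBehavior:
    def test_softmax_probability_lp5_block1(self):
        # EVr 120 vs EVs 60 at inverse temperature 0.05/ul: logistic(3) = 0.953
        sched = repeated_pair_schedule(1, 5, 20000)
        params = BehaviorParams(inverse_temperature=0.05, risk_bonus=0.0, abort_rate=0.0)
        trials = simulate.simulate_behavior(sched, params, seed=0)
        assert (trials["choice"] == "risky").mean() * 100 == pytest.approx(95.3, abs=1.0)

    def test_zero_temperature_is_indifferent(self):
        sched = repeated_pair_schedule(1, 5, 20000)
        params = BehaviorParams(inverse_temperature=0.0, abort_rate=0.0)
        trials = simulate.simulate_behavior(sched, params, seed=1)
        assert (trials["choice"] == "risky").mean() == pytest.approx(0.5, abs=0.02)

    def test_equal_ev_pair_is_indifferent(self):
        sched = repeated_pair_schedule(2, 3, 20000)
        trials = simulate.simulate_behavior(sched, BehaviorParams(abort_rate=0.0), seed=2)
        assert (trials["choice"] == "risky").mean() == pytest.approx(0.5, abs=0.02)

    def test_forced_trials_follow_instruction(self, behavior_trials):
        forced = behavior_trials[behavior_trials["context"] == "forced"]
        assert (forced["choice"] == forced["instructed"]).all()

    def test_monotone_psychometric_curve(self, behavior_trials):
        free = behavior_trials[(behavior_trials["context"] == "free")
                               & (behavior_trials["aborted"] == 0)]
        by_diff = free.groupby(free["EVr_ul"] - free["EVs_ul"])["choice"].apply(
            lambda c: (c == "risky").mean())
        # non-decreasing within binomial error: allow small inversions
        assert (np.diff(by_diff.to_numpy()) > -0.15).all()

    def test_determinism(self, schedule):
        p = BehaviorParams()
        a = simulate.simulate_behavior(schedule, p, seed=5)
        b = simulate.simulate_behavior(schedule, p, seed=5)
        assert a.equals(b)


class TestNeuron:
    def test_poisson_mean_null_model(self):
        sched = repeated_pair_schedule(1, 3, 10000)
        trials = simulate.simulate_behavior(sched, BehaviorParams(abort_rate=0.0), seed=3)
        sess = simulate.simulate_neuron(trials, GroundTruth("M9", {"b": 20.0},
                                                            coding_type="none"), seed=4)
        assert sess.trials["rate_cue"].mean() == pytest.approx(20.0, abs=0.5)

    def test_poisson_variance_matches_mean(self):
        sched = repeated_pair_schedule(1, 3, 10000)
        trials = simulate.simulate_behavior(sched, BehaviorParams(abort_rate=0.0), seed=3)
        sess = simulate.simulate_neuron(trials, GroundTruth("M9", {"b": 20.0},
                                                            coding_type="none"), seed=4)
        r = sess.trials["rate_cue"]
        assert r.var() == pytest.approx(r.mean(), rel=0.1)

    def test_baseline_is_zero_value_output(self, behavior_trials):
        # R_max * beta / sigma = 80 spikes/s; Poisson over 0.6 s
        truth = GroundTruth("M1", {"R_max": 40.0, "beta": 20.0, "sigma": 10.0})
        rng_draws = [simulate.simulate_neuron(behavior_trials, truth, seed=s).baseline_rate
                     for s in range(200)]
        assert np.mean(rng_draws) == pytest.approx(80.0, abs=2.5)

    def test_session_determinism(self, behavior_trials, m1_truth):
        a = simulate.simulate_neuron(behavior_trials, m1_truth, seed=6)
        b = simulate.simulate_neuron(behavior_trials, m1_truth, seed=6)
        assert a.trials.equals(b.trials) and a.baseline_rate == b.baseline_rate

    def test_m1_condition_means_are_saturating(self, behavior_trials):
        """M1 at strong curvature is non-linear in EVr, unlike a linear model."""
        truth = GroundTruth("M1", {"R_max": 60.0, "beta": 10.0, "sigma": 20.0})
        sess = simulate.simulate_neuron(behavior_trials, truth, seed=8)
        free = sess.trials[sess.trials["context"] == "free"]
        m = free[free["block_id"] == 1].groupby("lp_index")["rate_cue"].mean()
        # increments shrink as EVr grows (concave response)
        inc = np.diff(m.to_numpy())
        assert inc[0] > inc[-1]

    def test_degenerate_truth_warns(self, behavior_trials):
        truth = GroundTruth("M3", {"G": 0.001, "b": -50.0})
        with pytest.warns(UserWarning, match="degenerate"):
            simulate.simulate_neuron(behavior_trials, truth, seed=9)

    def test_forced_attenuation_reduces_modulation(self, behavior_trials):
        truth = GroundTruth("M1", {"R_max": 40.0, "beta": 20.0, "sigma": 10.0},
                            forced_beta_scale=5.0, forced_sigma_scale=5.0)
        sess = simulate.simulate_neuron(behavior_trials, truth, seed=10)
        t = sess.trials
        spread = {c: t[t["context"] == c].groupby(["block_id", "lp_index"])["rate_cue"]
                  .mean().pipe(np.ptp) for c in ("free", "forced")}
        assert spread["forced"] < spread["free"]


class TestDataset:
    def test_shapes_and_registry(self):
        sampler = lambda rng, i: GroundTruth("M1", {"R_max": 40.0, "beta": 20.0,
                                                    "sigma": 10.0})
        sessions = simulate.generate_dataset(5, sampler, seed=1)
        assert len(sessions) == 5
        assert all(len(s.trials) == 344 for s in sessions)
        assert all(s.ground_truth.model_id == "M1" for s in sessions)

    def test_seeds_differentiate_sessions(self):
        sampler = lambda rng, i: GroundTruth("M9", {"b": 20.0}, coding_type="none")
        a = simulate.generate_dataset(2, sampler, seed=1)
        b = simulate.generate_dataset(2, sampler, seed=2)
        assert not a[0].trials["rate_cue"].equals(b[0].trials["rate_cue"])

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            simulate.generate_dataset(0, lambda rng, i: None)


class TestBehaviorSummary:
    def test_no_aborts_means_full_correct(self, schedule):
        trials = simulate.simulate_behavior(schedule, BehaviorParams(abort_rate=0.0), seed=1)
        table = simulate.behavior_summary(trials)
        assert len(table) == 20
        assert (table["percent_correct"] == 100.0).all()

    def test_extreme_preference_all_risky(self, schedule):
        params = BehaviorParams(inverse_temperature=10.0, risk_bonus=500.0, abort_rate=0.0)
        trials = simulate.simulate_behavior(schedule, params, seed=1)
        table = simulate.behavior_summary(trials)
        assert (table["risky_pct"] == 100.0).all()

    def test_risky_pct_tracks_softmax(self):
        sched = repeated_pair_schedule(1, 5, 10000)
        params = BehaviorParams(inverse_temperature=0.05, risk_bonus=0.0, abort_rate=0.0)
        trials = simulate.simulate_behavior(sched, params, seed=0)
        table = simulate.behavior_summary(trials)
        assert table.loc[0, "risky_pct"] == pytest.approx(95.3, abs=1.0)
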