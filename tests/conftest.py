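"""Shared fixtures: small simulated sessions and an independent AIC oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from divnorm import simulate, task


@pytest.fixture(scope="session")
def blocks():
    return task.build_payoff_blocks()


@pytest.fixture(scope="session")
def schedule():
    return task.build_trial_schedule(seed=7)


@pytest.fixture(scope="session")
def behavior_trials(schedule):
    return simulate.simulate_behavior(schedule, simulate.BehaviorParams(), seed=11)


@pytest.fixture(scope="session")
def m1_truth():
    return simulate.GroundTruth("M1", {"R_max": 40.0, "beta": 20.0, "sigma": 10.0})


@pytest.fixture(scope="session")
def m1_session(behavior_trials, m1_truth):
    return simulate.simulate_neuron(behavior_trials, m1_truth, seed=13)


def noise_free_session(trials, truth, epoch_value=None):
    """A session whose epoch rates equal the ground-truth means exactly."""
    from divnorm import models

    df = trials.copy()
    cov = models.build_covariates(df, truth.coding_type)
    pred = models.predict(truth.model_id, truth.params, cov)
    for ep in simulate.EPOCHS:
        df[f"rate_{ep}"] = pred
    df.insert(0, "neuron_id", 0)
    return simulate.NeuronSession(0, df, truth, baseline_rate=np.nan,
                                  max_rate=float(np.max(pred)))


def brute_force_screen(y, X, candidates):
    """Independent oracle: exhaustively enumerate subsets with statsmodels OLS.

    Returns (best_subset, best_aic) under the Gaussian concentrated-likelihood
    convention AIC = n ln(SSE/n) + 2k, ties broken toward smaller subsets in
    candidate order.  Kept deliberately separate from the package's
    implementation (different OLS route, different enumeration order).
    """
    import statsmodels.api as sm

    n = len(y)
    results = []
    for size in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            if size == 0:
                sse = float(np.sum(np.asarray(y) ** 2))
            else:
                A = np.asarray(X[list(subset)])
                if np.linalg.matrix_rank(A) < size:
                    continue
                fit = sm.OLS(y, A).fit()
                sse = float(fit.ssr)
            aic = n * np.log(max(sse, np.finfo(float).tiny) / n) + 2 * size
            results.append((aic, size, tuple(candidates.index(v) for v in subset), subset))
    results.sort()
    best = results[0]
    return best[3], best[0]
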