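"""Synthetic behavior and neuron sessions with the structure the analysis assumes.

The real recordings behind this analysis are not public, so every downstream
stage is exercised on simulated sessions: softmax choice behavior over the
cued expected values, and Poisson spike counts whose per-trial mean follows
one of the candidate firing-rate models.  The generator's ground truth is
retained alongside each session so recovery can be verified.

The behavior and noise models are stand-ins chosen for simplicity: logistic
choice in the EV difference (risk attitude as an additive bonus for the risky
option), log-normal reaction times, Bernoulli aborts, and independent Poisson
counts per 1.0-s analysis epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence
import warnings

import numpy as np
import pandas as pd

from divnorm import models, task

EPOCHS = ("cue", "sac", "fb")
EPOCH_WINDOW_S = 1.0
BASELINE_WINDOW_S = 0.6
RATE_FLOOR = 0.01  # spikes/s; Poisson means are floored here

#: Session-table schema used for delimited-text round trips.
SESSION_COLUMNS = [
    "neuron_id", "block_id", "trial", "context", "lp_index",
    "EVr_ul", "EVs_ul", "choice", "chosen_side", "Fb", "rt_ms", "aborted",
    "rate_cue", "rate_sac", "rate_fb",
]


@dataclass
class BehaviorParams:
    """Parameters of the stand-in choice model.

    inverse_temperature (1/ul) scales the softmax on the EV difference;
    risk_bonus (ul) is an additive value bonus for the risky option encoding
    risk attitude; abort_rate is the per-trial abort probability; rt_location
    (ms, median) and rt_scale (log-sd) parameterise log-normal saccadic
    reaction times.
    """

    inverse_temperature: float = 0.05
    risk_bonus: float = 0.0
    abort_rate: float = 0.05
    rt_location: float = 200.0
    rt_scale: float = 0.2

    def __post_init__(self) -> None:
        if self.inverse_temperature < 0:
            raise ValueError("inverse_temperature must be >= 0")
        if not 0.0 <= self.abort_rate <= 0.2:
            raise ValueError("abort_rate must lie in [0, 0.2]")
        if self.rt_scale <= 0:
            raise ValueError("rt_scale must be > 0")


@dataclass
class GroundTruth:
    """The generating model of one simulated neuron.

    ``coding_type`` selects how trial values drive the rate: the two
    relative-value coding types map (EVr, EVs) onto (EV1, EV2); "choice_only"
    neurons fire as b + a*Cho(left); "none" neurons fire at a constant b.
    ``forced_beta_scale``/``forced_sigma_scale`` (>= 1) multiply beta and
    sigma of fractional models on forced-choice trials, emulating the
    attenuation of value sensitivity outside of free choice.  ``fb_gain``
    adds fb_gain * Fb to the feedback-epoch mean.
    """

    model_id: str
    params: dict
    coding_type: str = "EVr+EVs-"
    forced_beta_scale: float = 1.0
    forced_sigma_scale: float = 1.0
    fb_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.coding_type in ("EVr+EVs-", "EVr-EVs+"):
            missing = set(models.PARAM_NAMES[self.model_id]) - set(self.params)
            if missing:
                raise ValueError(f"{self.model_id} truth missing parameters {sorted(missing)}")
        elif self.coding_type in ("choice_only", "none"):
            if "b" not in self.params:
                raise ValueError(f"{self.coding_type} truth requires parameter 'b'")
        else:
            raise ValueError(f"unknown coding_type {self.coding_type!r}")
        if self.forced_beta_scale < 1.0 or self.forced_sigma_scale < 1.0:
            raise ValueError("forced attenuation scales must be >= 1")


@dataclass
class NeuronSession:
    """One simulated neuron: its trials, epoch firing rates and ground truth."""

    neuron_id: int
    trials: pd.DataFrame  # one row per trial, incl. rate_cue / rate_sac / rate_fb
    ground_truth: GroundTruth | None
    baseline_rate: float
    max_rate: float


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_behavior(schedule: pd.DataFrame, params: BehaviorParams, seed: int) -> pd.DataFrame:
    """Play out a schedule: choices, outcomes, reaction times and aborts.

    Free-choice trials pick the risky option with probability
    logistic(inverse_temperature * (EVr + risk_bonus - EVs)); forced trials
    follow the instruction.  Rewards are drawn per the chosen option's payout
    probability.  Returns one row per trial (aborted trials keep their row,
    flagged; analyses use non-aborted trials).
    """
    rng = np.random.default_rng(seed)
    df = task.schedule_expected_values(schedule)

    free = (df["context"] == "free").to_numpy()
    p_risky = _logistic(
        params.inverse_temperature
        * (df["EVr_ul"].to_numpy() + params.risk_bonus - df["EVs_ul"].to_numpy())
    )
    choose_risky = np.where(
        free, rng.random(len(df)) < p_risky, (df["instructed"] == "risky").to_numpy()
    )
    df["choice"] = np.where(choose_risky, "risky", "safe")
    df["chosen_side"] = np.where(
        choose_risky,
        df["risky_side"],
        np.where(df["risky_side"] == "left", "right", "left"),
    )

    chosen_mag = np.where(choose_risky, df["risky_mag_ul"], df["safe_mag_ul"])
    chosen_p = np.where(choose_risky, task.RISKY_PROBABILITY, task.SAFE_PROBABILITY)
    rewarded = rng.random(len(df)) < chosen_p
    df["rewarded"] = rewarded.astype(int)
    df["reward_ul"] = np.where(rewarded, chosen_mag, 0.0)
    df["Fb"] = df["rewarded"]

    df["rt_ms"] = rng.lognormal(np.log(params.rt_location), params.rt_scale, len(df))
    df["aborted"] = (rng.random(len(df)) < params.abort_rate).astype(int)
    return df


def simulate_neuron(trials: pd.DataFrame, truth: GroundTruth, seed: int,
                    neuron_id: int = 0) -> NeuronSession:
    """Attach Poisson epoch firing rates driven by a ground-truth model.

    Per trial and epoch the mean rate is the model prediction (floored at
    ``RATE_FLOOR``); the observed rate is a Poisson count over the 1.0-s epoch
    window.  Forced trials use beta/sigma inflated by the truth's attenuation
    scales (fractional models only).  The baseline rate is a Poisson count in
    a 0.6-s pre-cue window around the model's zero-value output
    (R_max*beta/sigma for fractional truths, else the intercept b).
    """
    rng = np.random.default_rng(seed)
    df = trials.copy()
    mean = _mean_rates(df, truth)

    n_low = int((mean < RATE_FLOOR).sum())
    if n_low > 0.5 * mean.size:
        warnings.warn(
            f"ground-truth prediction below {RATE_FLOOR} spikes/s on "
            f"{n_low}/{mean.size} trial-epochs: degenerate parameterization",
            stacklevel=2,
        )
    mean = np.maximum(mean, RATE_FLOOR)
    counts = rng.poisson(mean * EPOCH_WINDOW_S)
    rates = counts / EPOCH_WINDOW_S
    for j, ep in enumerate(EPOCHS):
        df[f"rate_{ep}"] = rates[:, j].astype(float)

    base_mean = max(_zero_value_rate(truth), RATE_FLOOR)
    baseline = rng.poisson(base_mean * BASELINE_WINDOW_S) / BASELINE_WINDOW_S
    df.insert(0, "neuron_id", neuron_id)
    return NeuronSession(
        neuron_id=neuron_id,
        trials=df,
        ground_truth=truth,
        baseline_rate=float(baseline),
        max_rate=float(rates.max()),
    )


def _mean_rates(df: pd.DataFrame, truth: GroundTruth) -> np.ndarray:
    """(n_trials, 3) model-mean firing rates for the cue/sac/fb epochs."""
    n = len(df)
    if truth.coding_type == "choice_only":
        cho = (df["chosen_side"] == "left").to_numpy(float)
        base = truth.params["b"] + truth.params.get("a", 0.0) * cho
    elif truth.coding_type == "none":
        base = np.full(n, float(truth.params["b"]))
    else:
        cov = models.build_covariates(df, truth.coding_type)
        forced = (df["context"] == "forced").to_numpy()
        if truth.model_id in ("M1", "M11", "M12", "M13") and (
            truth.forced_beta_scale != 1.0 or truth.forced_sigma_scale != 1.0
        ):
            base = np.empty(n)
            free_params = dict(truth.params)
            forced_params = dict(truth.params)
            forced_params["beta"] = truth.params["beta"] * truth.forced_beta_scale
            forced_params["sigma"] = truth.params["sigma"] * truth.forced_sigma_scale
            base[~forced] = models.predict(truth.model_id, free_params, cov[~forced])
            if forced.any():
                base[forced] = models.predict(truth.model_id, forced_params, cov[forced])
        else:
            base = models.predict(truth.model_id, truth.params, cov)

    mean = np.tile(np.asarray(base, float)[:, None], (1, len(EPOCHS)))
    if truth.fb_gain != 0.0 and "Fb" in df:
        mean[:, EPOCHS.index("fb")] += truth.fb_gain * df["Fb"].to_numpy(float)
    return mean


def _zero_value_rate(truth: GroundTruth) -> float:
    if truth.coding_type in ("EVr+EVs-", "EVr-EVs+") and truth.model_id in (
        "M1", "M11", "M12", "M13"
    ):
        p = truth.params
        if p["sigma"] == 0:
            raise ZeroDivisionError("sigma = 0: zero-value output undefined")
        return p["R_max"] * p["beta"] / p["sigma"]
    return float(truth.params.get("b", 0.0))


def generate_dataset(
    n_neurons: int,
    truth_sampler: Callable[[np.random.Generator, int], GroundTruth],
    behavior_params: BehaviorParams | None = None,
    seed: int = 0,
) -> list[NeuronSession]:
    """Simulate ``n_neurons`` independent sessions (schedule + behavior + rates).

    ``truth_sampler(rng, neuron_id)`` supplies each neuron's generating model;
    the returned sessions carry it for recovery tests.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    params = behavior_params or BehaviorParams()
    root = np.random.SeedSequence(seed)
    sessions = []
    for neuron_id, ss in enumerate(root.spawn(n_neurons)):
        s_sched, s_beh, s_truth, s_neur = (s.generate_state(1)[0] % 2**31 for s in ss.spawn(4))
        schedule = task.build_trial_schedule(int(s_sched))
        trials = simulate_behavior(schedule, params, int(s_beh))
        truth = truth_sampler(np.random.default_rng(int(s_truth)), neuron_id)
        sessions.append(simulate_neuron(trials, truth, int(s_neur), neuron_id=neuron_id))
    return sessions


def behavior_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-lottery-pair behavioral table: risky%, percent correct, mean RT.

    Risky% is computed over non-aborted free-choice trials; percent correct
    (non-aborted) and mean reaction time over all trials of the pair.  Pairs
    with no free trials get a missing risky%.
    """
    rows = []
    for (block_id, lp), g in trials.groupby(["block_id", "lp_index"]):
        free = g[(g["context"] == "free") & (g["aborted"] == 0)]
        risky_pct = 100.0 * (free["choice"] == "risky").mean() if len(free) else np.nan
        rows.append({
            "block_id": block_id,
            "lp_index": lp,
            "risky_pct": risky_pct,
            "percent_correct": 100.0 * (1.0 - g["aborted"].mean()),
            "mean_rt_ms": g.loc[g["aborted"] == 0, "rt_ms"].mean(),
        })
    return pd.DataFrame(rows)


def session_risk_attitude(trials: pd.DataFrame) -> float:
    """Risk attitude of a session: % risky choices on equal-EV (LP3) free trials."""
    lp3 = trials[(trials["context"] == "free") & (trials["aborted"] == 0) & (trials["lp_index"] == 3)]
    if len(lp3) == 0:
        return np.nan
    return 100.0 * (lp3["choice"] == "risky").mean()
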