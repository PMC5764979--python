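"""Round-trippable delimited-text I/O for schedules, sessions and fit tables.

Everything is plain comma-separated text with a header row; session ground
truth and baseline rates travel in a YAML sidecar.  Columns are matched by
name, so files with shuffled column order are accepted; missing or extra
columns raise a schema error naming the offenders.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from divnorm import task
from divnorm.simulate import SESSION_COLUMNS, GroundTruth, NeuronSession


def write_schedule(schedule: pd.DataFrame, path) -> None:
    schedule[task.SCHEDULE_COLUMNS].to_csv(path, index=False)


def read_schedule(path) -> pd.DataFrame:
    df = _read_checked(path, task.SCHEDULE_COLUMNS)
    return df[task.SCHEDULE_COLUMNS]


def write_sessions(sessions: list[NeuronSession], path, sidecar=None) -> None:
    """Write sessions as one trial-per-row table, plus a YAML sidecar.

    The sidecar (default: ``<path>`` with a ``.truth.yaml`` suffix) stores per
    neuron the ground-truth model and the baseline firing rate, which are not
    per-trial quantities.
    """
    frames = [s.trials[SESSION_COLUMNS] for s in sessions]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    meta = {}
    for s in sessions:
        entry: dict = {"baseline_rate": s.baseline_rate}
        if s.ground_truth is not None:
            t = s.ground_truth
            entry["ground_truth"] = {
                "model_id": t.model_id,
                "params": {k: float(v) for k, v in t.params.items()},
                "coding_type": t.coding_type,
                "forced_beta_scale": t.forced_beta_scale,
                "forced_sigma_scale": t.forced_sigma_scale,
                "fb_gain": t.fb_gain,
            }
        meta[int(s.neuron_id)] = entry
    with open(_sidecar_path(path, sidecar), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_sessions(path, sidecar=None) -> list[NeuronSession]:
    """Read sessions written by :func:`write_sessions`.

    Reconstructs the derived trial columns (cue magnitudes, instructed option,
    risky side, rewards) from the stored ones, so write-then-read is the
    identity on every stored quantity.
    """
    df = _read_checked(path, SESSION_COLUMNS)

    df["safe_mag_ul"] = df["EVs_ul"] / task.SAFE_PROBABILITY
    df["risky_mag_ul"] = df["EVr_ul"] / task.RISKY_PROBABILITY
    df["instructed"] = np.where(df["context"] == "forced", df["choice"], "none")
    df["risky_side"] = np.where(
        df["choice"] == "risky",
        df["chosen_side"],
        np.where(df["chosen_side"] == "left", "right", "left"),
    )
    df["rewarded"] = df["Fb"].astype(int)
    chosen_mag = np.where(df["choice"] == "risky", df["risky_mag_ul"], df["safe_mag_ul"])
    df["reward_ul"] = np.where(df["rewarded"] == 1, chosen_mag, 0.0)

    meta_path = _sidecar_path(path, sidecar)
    meta = {}
    if Path(meta_path).exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}

    sessions = []
    for neuron_id, trials in df.groupby("neuron_id", sort=True):
        trials = trials.reset_index(drop=True)
        entry = meta.get(int(neuron_id), {})
        truth = None
        if "ground_truth" in entry:
            truth = GroundTruth(**entry["ground_truth"])
        rates = trials[["rate_cue", "rate_sac", "rate_fb"]].to_numpy(float)
        sessions.append(NeuronSession(
            neuron_id=int(neuron_id),
            trials=trials,
            ground_truth=truth,
            baseline_rate=float(entry.get("baseline_rate", np.nan)),
            max_rate=float(rates.max()),
        ))
    return sessions


def write_fits(fits: pd.DataFrame, path) -> None:
    fits.to_csv(path, index=False)


def _sidecar_path(path, sidecar) -> Path:
    if sidecar is not None:
        return Path(sidecar)
    p = Path(path)
    return p.with_suffix(p.suffix + ".truth.yaml")


def _read_checked(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed delimited file {path}: {exc}") from exc
    missing = set(required) - set(df.columns)
    extra = set(df.columns) - set(required)
    if missing or extra:
        raise ValueError(
            f"schema mismatch in {path}: missing columns {sorted(missing)}, "
            f"unexpected columns {sorted(extra)}"
        )
    bad = df[required].isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ValueError(f"incomplete row in {path} at line {line}")
    return df
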