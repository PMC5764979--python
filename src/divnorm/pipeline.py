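"""Config-driven end-to-end run: simulate, screen, fit, population report.

A :class:`PipelineConfig` (serializable to YAML) plus the package version
determines every output bit-for-bit.  :func:`run_pipeline` writes the
schedule, sessions (+ ground-truth sidecar), screening report, fit table,
population summary and a run manifest into an output directory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
import json
import logging
from pathlib import Path
import time

import numpy as np
import pandas as pd
import yaml

import divnorm
from divnorm import fitting, io, models, population, screening, simulate, task

logger = logging.getLogger(__name__)


@dataclass
class TruthConfig:
    """How each simulated neuron's generating model is sampled."""

    model_id: str = "M1"
    rmax_range: tuple[float, float] = (10.0, 60.0)
    beta_range: tuple[float, float] = (10.0, 100.0)
    sigma_range: tuple[float, float] = (20.0, 200.0)
    gain_range: tuple[float, float] = (0.02, 0.10)   # linear-model slope a or G
    baseline_range: tuple[float, float] = (5.0, 30.0)
    p_coding: float = 0.6       # probability a neuron codes relative value
    p_positive: float = 0.5     # EVr+EVs- fraction among coders
    forced_beta_scale: float = 1.0
    forced_sigma_scale: float = 1.0


@dataclass
class PipelineConfig:
    seed: int = 1
    n_neurons: int = 12
    behavior: simulate.BehaviorParams = field(default_factory=simulate.BehaviorParams)
    truth: TruthConfig = field(default_factory=TruthConfig)
    models: tuple[str, ...] = ("M1", "M2", "M3", "M4")
    n_restarts: int = 20
    epochs: tuple[str, ...] = ("cue", "sac", "fb")

    def validate(self) -> None:
        unknown = [m for m in self.models if m not in models.MODEL_IDS]
        if unknown:
            raise ValueError(f"unknown model ids in config: {unknown}")
        if self.truth.model_id not in models.MODEL_IDS:
            raise ValueError(f"unknown truth model id {self.truth.model_id!r}")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["behavior"] = simulate.BehaviorParams(**raw.get("behavior", {}))
        truth = raw.get("truth", {})
        for key in ("rmax_range", "beta_range", "sigma_range", "gain_range", "baseline_range"):
            if key in truth:
                truth[key] = tuple(truth[key])
        raw["truth"] = TruthConfig(**truth)
        for key in ("models", "epochs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def make_truth_sampler(cfg: TruthConfig):
    """Build a ``truth_sampler(rng, neuron_id)`` from a :class:`TruthConfig`."""

    def sampler(rng: np.random.Generator, neuron_id: int) -> simulate.GroundTruth:
        if rng.random() >= cfg.p_coding:
            return simulate.GroundTruth("M9", {"b": rng.uniform(*cfg.baseline_range)},
                                        coding_type="none")
        coding = "EVr+EVs-" if rng.random() < cfg.p_positive else "EVr-EVs+"
        params = sample_params(cfg, rng)
        return simulate.GroundTruth(
            cfg.model_id, params, coding_type=coding,
            forced_beta_scale=cfg.forced_beta_scale,
            forced_sigma_scale=cfg.forced_sigma_scale,
        )

    return sampler


def sample_params(cfg: TruthConfig, rng: np.random.Generator) -> dict:
    """Draw one parameter set for ``cfg.model_id`` from the configured ranges."""
    m = cfg.model_id
    if m in ("M1", "M11", "M12", "M13"):
        p = {"R_max": rng.uniform(*cfg.rmax_range), "beta": rng.uniform(*cfg.beta_range),
             "sigma": rng.uniform(*cfg.sigma_range)}
        if m != "M1":
            p["a"] = 0.0
        return p
    if m in ("M2", "M4"):
        return {"R_max": rng.uniform(*cfg.rmax_range), "b": rng.uniform(*cfg.baseline_range)}
    if m == "M3":
        return {"G": rng.uniform(*cfg.gain_range), "b": rng.uniform(*cfg.baseline_range)}
    if m in ("M5", "M6", "M7"):
        return {"a": rng.uniform(*cfg.gain_range), "b": rng.uniform(*cfg.baseline_range)}
    if m == "M8":
        return {"a": rng.uniform(5.0, 15.0), "b": rng.uniform(*cfg.baseline_range)}
    if m == "M9":
        return {"b": rng.uniform(*cfg.baseline_range)}
    if m == "M10":
        return {**{f"a{i}": rng.uniform(*cfg.gain_range) for i in range(1, 5)},
                **{f"b{i}": rng.uniform(*cfg.baseline_range) for i in range(1, 5)}}
    raise ValueError(f"unknown model id {m!r}")


def fit_table(sessions, screen_report: pd.DataFrame, model_ids, n_restarts=20,
              seed=0, context_scope="free", epochs=("cue", "sac", "fb")) -> pd.DataFrame:
    """Fit every requested model to every relative-value activity.

    Returns a tidy frame: one row per (neuron, epoch, model) with the fitted
    parameters, SSE, AIC and both variance-explained measures.
    """
    by_id = {s.neuron_id: s for s in sessions}
    rel = screen_report[screen_report["label"].isin(("EVr+EVs-", "EVr-EVs+"))]
    rows = []
    for _, act in rel.iterrows():
        s = by_id[act["neuron_id"]]
        for model_id in model_ids:
            fit = fitting.fit_model(s.trials, act["epoch"], model_id, act["label"],
                                    n_restarts=n_restarts, seed=seed,
                                    context_scope=context_scope)
            rows.append({
                "neuron_id": act["neuron_id"], "epoch": act["epoch"],
                "label": act["label"], "model_id": model_id,
                "context_scope": context_scope,
                "params": json.dumps({k: float(v) for k, v in fit.params.items()}),
                "sse": fit.sse, "aic": fit.aic,
                "ve_trial": fit.ve_trial, "ve_mean": fit.ve_mean,
                "n_trials": fit.n_trials,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run simulate -> screen -> fit -> population stages, writing artifacts.

    Outputs in ``out_dir``: config.yaml, schedule.csv (first neuron's
    schedule), sessions.csv + sessions.csv.truth.yaml, screening.csv,
    fits.csv, population.csv, summary.txt, manifest.json.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = {"package_version": divnorm.__version__, "seed": config.seed,
                "n_neurons": config.n_neurons, "stages": {}}

    def stage(name, fn):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)
        try:
            result = fn()
        except Exception:
            logger.exception("stage %s failed", name)
            manifest["stages"][name] = {"status": "failed"}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise
        manifest["stages"][name] = {"status": "ok",
                                    "seconds": round(time.perf_counter() - t0, 3)}
        return result

    sampler = make_truth_sampler(config.truth)
    sessions = stage("simulate", lambda: simulate.generate_dataset(
        config.n_neurons, sampler, config.behavior, seed=config.seed))
    io.write_schedule(sessions[0].trials, out / "schedule.csv")
    io.write_sessions(sessions, out / "sessions.csv")

    report = stage("screen", lambda: screening.screen_sessions(sessions, config.epochs))
    report.to_csv(out / "screening.csv", index=False)

    fits = stage("fit", lambda: fit_table(
        sessions, report, config.models, n_restarts=config.n_restarts,
        seed=config.seed, epochs=config.epochs))
    io.write_fits(fits, out / "fits.csv")

    def _population():
        lines = []
        counts = {e: (int((report[report["epoch"] == e]["label"]
                           .isin(("EVr+EVs-", "EVr-EVs+"))).sum()),
                      int((report["epoch"] == e).sum()))
                  for e in config.epochs}
        prop = population.epoch_proportions(counts)
        lines.append(f"relative-value activities per epoch: "
                     f"{ {e: c[0] for e, c in counts.items()} } "
                     f"(chi2={prop.statistic:.3f}, df={prop.df}, P={prop.p_value:.3f})")
        comparison = pd.DataFrame()
        if len(fits):
            aic_table = fits.pivot_table(index=["neuron_id", "epoch"],
                                         columns="model_id", values="aic")
            if len(aic_table) >= 2 and config.models[0] in aic_table:
                comparison = population.population_best_model(aic_table, config.models[0])
                for _, r in comparison.iterrows():
                    lines.append(
                        f"AIC({r['reference']}) - AIC({r['competitor']}): "
                        f"mean={r['mean_aic_diff']:.2f}, t={r['t']:.2f}, "
                        f"df={r['df']}, P={r['p']:.4g}")
                lines.append(f"{config.models[0]} population-best: "
                             f"{comparison.attrs['is_best']}")
        return comparison, lines

    comparison, lines = stage("population", _population)
    comparison.to_csv(out / "population.csv", index=False)
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
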