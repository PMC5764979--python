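"""Fit firing-rate models to neuron-epoch activities by least squares.

Models linear in their parameters (M2-M10; the fractional/range regressors
are fixed functions of the trial covariates) are solved exactly by ordinary
least squares.  The divisive-normalization forms (M1, M11-M13) are fitted by
derivative-based nonlinear least squares restarted from random initial
values; the lowest-SSE converged solution wins.  AIC uses the same Gaussian
concentrated-likelihood convention as the screening stage, so AIC differences
between models fitted to one activity are convention-invariant.

Parameters are unbounded: negative fitted beta/sigma are legitimate outcomes
(they flag activities the normalization form no longer describes well).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from divnorm import models
from divnorm.screening import gaussian_aic

CONTEXT_SCOPES = ("free", "forced_a1", "forced_a2", "free_plus_forced")

#: Random-start ranges for the nonlinear parameters (beta, sigma in ul).
START_BETA_RANGE = (1.0, 600.0)
START_SIGMA_RANGE = (1.0, 600.0)
START_RMAX_FACTORS = (0.5, 2.0)

XTOL = 1e-8
MAX_NFEV = 500


@dataclass
class ModelFit:
    """One model fitted to one neuron-epoch activity."""

    model_id: str
    params: dict
    sse: float
    n_trials: int
    aic: float
    ve_trial: float
    ve_mean: float
    n_restarts_converged: int
    context_scope: str
    seed: int | None = None


@dataclass
class CrossValidationResult:
    """Two-fold stratified cross-validation of one model on one activity."""

    ve_train: float
    ve_test: float
    split_seed: int


def select_trials(trials: pd.DataFrame, context_scope: str) -> pd.DataFrame:
    """Non-aborted trials of the requested context, with any forced-choice
    value assumption applied to the EV columns."""
    if context_scope not in CONTEXT_SCOPES:
        raise ValueError(f"context_scope must be one of {CONTEXT_SCOPES}")
    ok = trials["aborted"] == 0
    if context_scope == "free":
        data = trials[ok & (trials["context"] == "free")]
    elif context_scope in ("forced_a1", "forced_a2"):
        data = trials[ok & (trials["context"] == "forced")]
        data = models.apply_forced_assumption(data, int(context_scope[-1]))
    else:
        data = trials[ok]
        # pooled fits (M11-M13) treat forced values as cued (assumption 1)
    return data


def variance_explained(y: np.ndarray, pred: np.ndarray,
                       pairs: pd.DataFrame | None = None,
                       basis: str = "trial") -> float:
    """Percent variance explained: 100 (1 - residual SS / total SS).

    ``basis="trial"`` uses single trials; ``basis="mean20"`` first averages
    observed and predicted rates within each lottery pair (``pairs`` must give
    the per-trial block_id / lp_index).  Zero total variance yields NaN.
    """
    y = np.asarray(y, float)
    pred = np.asarray(pred, float)
    if basis == "trial":
        sst = float(((y - y.mean()) ** 2).sum())
        sse = float(((y - pred) ** 2).sum())
    elif basis == "mean20":
        if pairs is None:
            raise ValueError("mean20 basis requires the per-trial pair labels")
        key = pd.MultiIndex.from_frame(pairs[["block_id", "lp_index"]])
        ym = pd.Series(y, index=key).groupby(level=[0, 1]).mean()
        pm = pd.Series(pred, index=key).groupby(level=[0, 1]).mean()
        sst = float(((ym - ym.mean()) ** 2).sum())
        sse = float(((ym - pm) ** 2).sum())
    else:
        raise ValueError(f"unknown basis {basis!r}")
    if sst == 0.0:
        return np.nan
    return 100.0 * (1.0 - sse / sst)


def _linear_design(model_id: str, cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    ev1, ev2 = cov["EV1"].to_numpy(), cov["EV2"].to_numpy()
    one = np.ones(len(cov))
    if model_id == "M2":
        return np.column_stack([ev1 / (ev1 + ev2), one]), ["R_max", "b"]
    if model_id == "M3":
        return np.column_stack([ev1 - ev2, one]), ["G", "b"]
    if model_id == "M4":
        frac = (ev1 - cov["v_min"].to_numpy()) / (cov["v_max"].to_numpy() - cov["v_min"].to_numpy())
        return np.column_stack([frac, one]), ["R_max", "b"]
    if model_id in ("M5", "M6", "M7", "M8"):
        col = {"M5": "EVr", "M6": "EVs", "M7": "EVchosen", "M8": "RiskyCho"}[model_id]
        return np.column_stack([cov[col].to_numpy(), one]), ["a", "b"]
    if model_id == "M9":
        return one[:, None], ["b"]
    if model_id == "M10":
        block = cov["block_id"].to_numpy()
        evr = cov["EVr"].to_numpy()
        cols, names = [], []
        for i in (1, 2, 3, 4):
            m = (block == i).astype(float)
            cols.extend([evr * m, m])
            names.extend([f"a{i}", f"b{i}"])
        return np.column_stack(cols), names
    raise ValueError(f"{model_id} is not linear in its parameters")


def _fit_linear(model_id: str, cov: pd.DataFrame, y: np.ndarray) -> tuple[dict, float]:
    A, names = _linear_design(model_id, cov)
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return dict(zip(names, beta)), float(resid @ resid)


def _residual_fn(model_id: str, cov: pd.DataFrame, y: np.ndarray):
    ev1 = cov["EV1"].to_numpy()
    ev2 = cov["EV2"].to_numpy()
    extra = None
    if model_id in ("M11", "M12", "M13"):
        col = {"M11": "Context", "M12": "PercentCorrect", "M13": "RT"}[model_id]
        extra = cov[col].to_numpy()

    def residual(p):
        r_max, beta, sigma = p[0], p[1], p[2]
        den = sigma + ev1 + ev2
        # keep residuals finite when a restart wanders across the pole
        den = np.where(np.abs(den) < 1e-6, np.sign(den + (den == 0)) * 1e-6, den)
        pred = r_max * (beta + ev1) / den
        if extra is not None:
            pred = pred + p[3] * extra
        return pred - y

    return residual


def _random_start(model_id: str, rng: np.random.Generator, y: np.ndarray) -> np.ndarray:
    y_max = float(np.max(y)) if len(y) and np.max(y) > 0 else 40.0
    start = [
        rng.uniform(*START_RMAX_FACTORS) * y_max,
        rng.uniform(*START_BETA_RANGE),
        rng.uniform(*START_SIGMA_RANGE),
    ]
    if model_id in ("M11", "M12", "M13"):
        start.append(rng.normal(0.0, y.std() + 1e-6))
    return np.asarray(start)


def fit_model(trials: pd.DataFrame, epoch: str, model_id: str, label: str,
              n_restarts: int = 100, seed: int = 0,
              context_scope: str = "free") -> ModelFit:
    """Fit one model to one activity (a neuron's rates in one epoch).

    ``label`` (EVr+EVs- or EVr-EVs+) fixes the EV1/EV2 assignment.  Nonlinear
    models run ``n_restarts`` derivative-based least-squares minimizations
    from random initial values drawn sequentially from ``seed`` (so the best
    SSE is non-increasing in ``n_restarts``); linear models are solved in
    closed form.  Raises if no restart converges; warns below 10.
    """
    models._check_model(model_id)
    data = select_trials(trials, context_scope)
    y = data[f"rate_{epoch}"].to_numpy(float)
    k = models.n_params(model_id)
    if len(y) < 2 * k:
        raise ValueError(f"need >= {2 * k} trials to fit {model_id}, got {len(y)}")
    cov = models.build_covariates(data, label)

    if model_id in models.LINEAR_MODELS:
        params, sse = _fit_linear(model_id, cov, y)
        n_converged = 1
    else:
        residual = _residual_fn(model_id, cov, y)
        rng = np.random.default_rng(seed)
        best_sse, best_x, n_converged = np.inf, None, 0
        for _ in range(n_restarts):
            x0 = _random_start(model_id, rng, y)
            try:
                res = least_squares(residual, x0, method="lm", xtol=XTOL,
                                    ftol=XTOL, max_nfev=MAX_NFEV)
            except (ValueError, ZeroDivisionError):
                continue
            if not res.success:
                continue
            n_converged += 1
            sse = float(res.fun @ res.fun)
            if sse < best_sse:
                best_sse, best_x = sse, res.x
        if best_x is None:
            raise RuntimeError(
                f"no converged restart fitting {model_id} "
                f"(n_restarts={n_restarts}, n_trials={len(y)})"
            )
        if n_converged < 10:
            warnings.warn(
                f"only {n_converged}/{n_restarts} restarts converged for {model_id}",
                stacklevel=2,
            )
        params = dict(zip(models.PARAM_NAMES[model_id], best_x))
        sse = best_sse

    pred = _predict_unclipped(model_id, params, cov)
    return ModelFit(
        model_id=model_id,
        params=params,
        sse=sse,
        n_trials=len(y),
        aic=gaussian_aic(sse, len(y), k),
        ve_trial=variance_explained(y, pred, basis="trial"),
        ve_mean=variance_explained(y, pred, pairs=cov, basis="mean20"),
        n_restarts_converged=n_converged,
        context_scope=context_scope,
        seed=seed,
    )


def _predict_unclipped(model_id, params, cov):
    # same pole guard as the residual so fitted predictions never blow up
    if model_id in models.NONLINEAR_MODELS:
        r = _residual_fn(model_id, cov, np.zeros(len(cov)))
        return r([params[n] for n in models.PARAM_NAMES[model_id]])
    return models.predict(model_id, params, cov)


def fit_forced(trials: pd.DataFrame, epoch: str, model_id: str, label: str,
               assumption: int = 1, n_restarts: int = 100, seed: int = 0) -> ModelFit:
    """Fit on forced-choice trials under one of the two value assumptions.

    Assumption 1 keeps the cued option values; assumption 2 zeroes the value
    of the non-selectable option.
    """
    if assumption not in (1, 2):
        raise ValueError("assumption must be 1 or 2")
    if not ((trials["context"] == "forced") & (trials["aborted"] == 0)).any():
        raise ValueError("no usable forced-choice trials present")
    return fit_model(trials, epoch, model_id, label, n_restarts=n_restarts,
                     seed=seed, context_scope=f"forced_a{assumption}")


def crossvalidate(trials: pd.DataFrame, epoch: str, model_id: str, label: str,
                  seed: int = 0, n_restarts: int = 20) -> CrossValidationResult:
    """Two-fold cross-validation stratified by lottery pair (free trials).

    Each of the 20 pairs contributes half its trials to each fold (odd counts
    split off by one); the model is fitted on the training fold and percent
    variance explained (mean-response basis) is reported for both folds using
    the training parameters.  Pairs with fewer than 2 trials are excluded.
    """
    rng = np.random.default_rng(seed)
    data = select_trials(trials, "free")
    train_idx, test_idx = [], []
    for _, g in data.groupby(["block_id", "lp_index"]):
        if len(g) < 2:
            warnings.warn("lottery pair with < 2 trials excluded from cross-validation",
                          stacklevel=2)
            continue
        perm = rng.permutation(len(g))
        half = len(g) // 2
        train_idx.extend(g.index[perm[:half]])
        test_idx.extend(g.index[perm[half:]])
    train = trials.loc[sorted(train_idx)]
    test_data = data.loc[sorted(test_idx)]

    fit = fit_model(train, epoch, model_id, label, n_restarts=n_restarts,
                    seed=seed, context_scope="free")
    cov_test = models.build_covariates(test_data, label)
    pred_test = _predict_unclipped(model_id, fit.params, cov_test)
    y_test = test_data[f"rate_{epoch}"].to_numpy(float)
    return CrossValidationResult(
        ve_train=fit.ve_mean,
        ve_test=variance_explained(y_test, pred_test, pairs=cov_test, basis="mean20"),
        split_seed=seed,
    )
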