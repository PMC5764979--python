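"""The thirteen candidate firing-rate models behind one prediction interface.

M1 is the divisive ("advanced fractional") normalization model

    R = R_max (beta + EV1) / (sigma + EV1 + EV2)

where EV1/EV2 are the expected values of the two options after assignment by
coding type (the preferred option's EV goes in the numerator).  M2 is the
simple fractional form, M3 a value-difference (linear) model, M4 range
normalization by the block's reward range.  M5-M10 are non-relative
alternatives (linear in EVr, EVs, chosen EV, risky-choice indicator, a
constant, and a block-wise piecewise-linear "artificial" model).  M11-M13
extend M1 with an additive behavioral covariate (free/forced context, percent
correct per lottery pair, saccadic reaction time).

Predictions are not clipped at zero: linear models may output negative rates
and fitted beta/sigma may go negative during optimization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MODEL_IDS = tuple(f"M{i}" for i in range(1, 14))

#: Free parameters per model, in canonical order.
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "M1": ("R_max", "beta", "sigma"),
    "M2": ("R_max", "b"),
    "M3": ("G", "b"),
    "M4": ("R_max", "b"),
    "M5": ("a", "b"),
    "M6": ("a", "b"),
    "M7": ("a", "b"),
    "M8": ("a", "b"),
    "M9": ("b",),
    "M10": ("a1", "b1", "a2", "b2", "a3", "b3", "a4", "b4"),
    "M11": ("R_max", "beta", "sigma", "a"),
    "M12": ("R_max", "beta", "sigma", "a"),
    "M13": ("R_max", "beta", "sigma", "a"),
}

#: Models that are linear in their parameters (fit exactly by least squares).
LINEAR_MODELS = ("M2", "M3", "M4", "M5", "M6", "M7", "M8", "M9", "M10")
#: Models requiring iterative nonlinear least squares.
NONLINEAR_MODELS = ("M1", "M11", "M12", "M13")

_DENOM_FLOOR = 1e-9  # |sigma + EV1 + EV2| below this is a degenerate parameterization


def n_params(model_id: str) -> int:
    """Number of free parameters of a model."""
    return len(PARAM_NAMES[_check_model(model_id)])


def _check_model(model_id: str) -> str:
    if model_id not in PARAM_NAMES:
        raise ValueError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")
    return model_id


def assign_ev1_ev2(label: str, EVr, EVs) -> tuple:
    """Assign (EV1, EV2) from (EVr, EVs) according to the coding type.

    EVr+EVs- neurons prefer the risky option, so EV1 = EVr; EVr-EVs+ neurons
    prefer the safe option, so EV1 = EVs.
    """
    if label == "EVr+EVs-":
        return EVr, EVs
    if label == "EVr-EVs+":
        return EVs, EVr
    raise ValueError(f"cannot assign EV1/EV2 for label {label!r}")


def forced_choice_evs(trial, assumption: int) -> tuple[float, float]:
    """(EVr, EVs) for a forced-choice trial under one of two value assumptions.

    Assumption 1: both options keep the values cued by the pie charts, as on
    free-choice trials.  Assumption 2: the non-selectable option is worth zero
    — choosing it aborts the trial and pays nothing — so only the instructed
    option keeps its cued value.

    ``trial`` is any mapping with fields ``context``, ``instructed``,
    ``EVr_ul``, ``EVs_ul`` (e.g. a DataFrame row).
    """
    if trial["context"] != "forced":
        raise ValueError("forced_choice_evs applies to forced-choice trials only")
    evr, evs = float(trial["EVr_ul"]), float(trial["EVs_ul"])
    if assumption == 1:
        return evr, evs
    if assumption == 2:
        if trial["instructed"] == "risky":
            return evr, 0.0
        return 0.0, evs
    raise ValueError(f"assumption must be 1 or 2, got {assumption!r}")


def apply_forced_assumption(trials: pd.DataFrame, assumption: int) -> pd.DataFrame:
    """Vectorised ``forced_choice_evs`` over a trial table (forced rows only)."""
    out = trials.copy()
    forced = out["context"] == "forced"
    if assumption == 2:
        risky_instructed = forced & (out["instructed"] == "risky")
        safe_instructed = forced & (out["instructed"] == "safe")
        out.loc[risky_instructed, "EVs_ul"] = 0.0
        out.loc[safe_instructed, "EVr_ul"] = 0.0
    elif assumption != 1:
        raise ValueError(f"assumption must be 1 or 2, got {assumption!r}")
    return out


def build_covariates(trials: pd.DataFrame, label: str) -> pd.DataFrame:
    """Build the per-trial covariates every model may consume.

    Returns a frame with EV1/EV2 (assigned by coding ``label``), EVr/EVs,
    EVchosen, RiskyCho, Context (1 free / 0 forced), PercentCorrect (percent
    non-aborted trials of the trial's lottery pair over the session), RT
    (z-scored saccadic reaction time), v_min/v_max of the trial's block, and
    block_id.  Input rows are used as given — apply any forced-choice value
    assumption beforehand.
    """
    evr = trials["EVr_ul"].to_numpy(float)
    evs = trials["EVs_ul"].to_numpy(float)
    ev1, ev2 = assign_ev1_ev2(label, evr, evs)

    cov = pd.DataFrame(index=trials.index)
    cov["EV1"], cov["EV2"] = ev1, ev2
    cov["EVr"], cov["EVs"] = evr, evs
    risky_cho = (trials["choice"] == "risky").to_numpy(float) if "choice" in trials else np.zeros(len(trials))
    cov["RiskyCho"] = risky_cho
    cov["EVchosen"] = np.where(risky_cho == 1.0, evr, evs)
    cov["Context"] = (trials["context"] == "free").to_numpy(float)

    # percent correct (non-aborted) per lottery pair, computed over the session
    if "aborted" in trials:
        grp = trials.groupby(["block_id", "lp_index"])["aborted"]
        pc = (1.0 - grp.transform("mean")) * 100.0
    else:
        pc = pd.Series(100.0, index=trials.index)
    cov["PercentCorrect"] = pc.to_numpy(float)

    if "rt_ms" in trials:
        rt = trials["rt_ms"].to_numpy(float)
        sd = rt.std()
        cov["RT"] = (rt - rt.mean()) / sd if sd > 0 else np.zeros_like(rt)
    else:
        cov["RT"] = 0.0

    block = trials["block_id"].to_numpy(int)
    cov["block_id"] = block
    cov["lp_index"] = trials["lp_index"].to_numpy(int)
    v_max_by_block = {1: 240.0, 2: 360.0, 3: 480.0, 4: 600.0}
    cov["v_min"] = 0.0
    cov["v_max"] = np.vectorize(v_max_by_block.__getitem__)(block).astype(float)
    return cov


def _fractional(params: dict, cov: pd.DataFrame) -> np.ndarray:
    ev1, ev2 = cov["EV1"].to_numpy(), cov["EV2"].to_numpy()
    den = params["sigma"] + ev1 + ev2
    if np.any(np.abs(den) < _DENOM_FLOOR):
        raise ZeroDivisionError(
            f"normalization denominator vanishes: sigma={params['sigma']} with "
            f"EV1+EV2 range [{(ev1 + ev2).min()}, {(ev1 + ev2).max()}]"
        )
    return params["R_max"] * (params["beta"] + ev1) / den


def predict(model_id: str, params: dict, cov: pd.DataFrame) -> np.ndarray:
    """Evaluate a model's predicted firing rate (spikes/s) for each trial.

    ``cov`` is the output of :func:`build_covariates` (or any frame with the
    columns the model consumes).  ``params`` maps the model's parameter names
    (``PARAM_NAMES``) to values.
    """
    _check_model(model_id)
    missing = set(PARAM_NAMES[model_id]) - set(params)
    if missing:
        raise ValueError(f"{model_id} missing parameters {sorted(missing)}")

    if model_id == "M1":
        return _fractional(params, cov)
    if model_id == "M2":
        ev1, ev2 = cov["EV1"].to_numpy(), cov["EV2"].to_numpy()
        den = ev1 + ev2
        if np.any(np.abs(den) < _DENOM_FLOOR):
            raise ZeroDivisionError("EV1 + EV2 vanishes on some trial; simple fractional model undefined")
        return params["R_max"] * ev1 / den + params["b"]
    if model_id == "M3":
        return params["G"] * (cov["EV1"] - cov["EV2"]).to_numpy() + params["b"]
    if model_id == "M4":
        v_min, v_max = cov["v_min"].to_numpy(), cov["v_max"].to_numpy()
        if np.any(v_max <= v_min):
            raise ValueError("range normalization requires v_max > v_min")
        return params["R_max"] * (cov["EV1"].to_numpy() - v_min) / (v_max - v_min) + params["b"]
    if model_id == "M5":
        return params["a"] * cov["EVr"].to_numpy() + params["b"]
    if model_id == "M6":
        return params["a"] * cov["EVs"].to_numpy() + params["b"]
    if model_id == "M7":
        return params["a"] * cov["EVchosen"].to_numpy() + params["b"]
    if model_id == "M8":
        return params["a"] * cov["RiskyCho"].to_numpy() + params["b"]
    if model_id == "M9":
        return np.full(len(cov), float(params["b"]))
    if model_id == "M10":
        block = cov["block_id"].to_numpy()
        evr = cov["EVr"].to_numpy()
        out = np.empty(len(cov))
        for i in (1, 2, 3, 4):
            m = block == i
            out[m] = params[f"a{i}"] * evr[m] + params[f"b{i}"]
        return out
    # M11-M13: divisive normalization plus one behavioral covariate
    extra = {"M11": "Context", "M12": "PercentCorrect", "M13": "RT"}[model_id]
    return _fractional(params, cov) + params["a"] * cov[extra].to_numpy()
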