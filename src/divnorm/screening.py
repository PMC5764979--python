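"""Screen neuron-epoch activities for relative-value and choice coding.

Firing rates on free-choice trials are regressed on every subset of the
candidate variables {intercept, EVr, EVs, Fb (feedback epoch only), Cho
(choice variant only)} and the subset with minimal AIC is selected.  An
activity is *relative-value coding* when the winning subset contains EVr and
EVs with opposite-signed coefficients (EVr+EVs- or EVr-EVs+), and *choice
coding* when it contains Cho and none of the value/feedback regressors.

AIC for these least-squares fits uses the Gaussian concentrated likelihood,
AIC = n ln(SSE/n) + 2k with k the number of fitted coefficients; additive
constants are dropped, which leaves all within-activity comparisons intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical candidate order; subsets are reported and tie-broken in it.
VARIABLE_ORDER = ("b0", "EVr", "EVs", "Fb", "Cho")

LABELS = ("EVr+EVs-", "EVr-EVs+", "choice_only", "other")


def aic(log_likelihood: float, k: int) -> float:
    """Akaike's information criterion: -2 log L + 2 k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return -2.0 * log_likelihood + 2.0 * k


def gaussian_aic(sse: float, n: int, k: int) -> float:
    """AIC of a least-squares fit under Gaussian errors, constants dropped."""
    if n <= 0:
        raise ValueError("n must be positive")
    sse = max(float(sse), np.finfo(float).tiny)  # guard perfect fits
    return n * np.log(sse / n) + 2.0 * k


@dataclass
class RegressionResult:
    """Outcome of the exhaustive-subset screen for one activity."""

    epoch: str
    selected_subset: tuple[str, ...]
    coefficients: dict = field(default_factory=dict)
    aic: float = np.nan
    label: str = "other"
    n_trials: int = 0

    @property
    def is_relative_value(self) -> bool:
        return self.label in ("EVr+EVs-", "EVr-EVs+")


def _candidate_columns(trials: pd.DataFrame, epoch: str, include_choice: bool) -> pd.DataFrame:
    X = pd.DataFrame(index=trials.index)
    X["b0"] = 1.0
    X["EVr"] = trials["EVr_ul"].to_numpy(float)
    X["EVs"] = trials["EVs_ul"].to_numpy(float)
    if epoch == "fb":
        X["Fb"] = trials["Fb"].to_numpy(float)
    if include_choice:
        X["Cho"] = (trials["chosen_side"] == "left").to_numpy(float)
    return X


def _classify(subset: tuple[str, ...], coefs: dict) -> str:
    if "EVr" in subset and "EVs" in subset:
        if coefs["EVr"] > 0 and coefs["EVs"] < 0:
            return "EVr+EVs-"
        if coefs["EVr"] < 0 and coefs["EVs"] > 0:
            return "EVr-EVs+"
    if "Cho" in subset and not ({"EVr", "EVs", "Fb"} & set(subset)):
        return "choice_only"
    return "other"


def _screen(trials: pd.DataFrame, epoch: str, include_choice: bool) -> RegressionResult:
    data = trials[(trials["context"] == "free") & (trials["aborted"] == 0)]
    rate_col = f"rate_{epoch}"
    if rate_col not in data:
        raise KeyError(f"no column {rate_col!r}; epoch must be one of cue/sac/fb")
    y = data[rate_col].to_numpy(float)
    n = len(y)
    if data["EVr_ul"].nunique() < 2 or data["EVs_ul"].nunique() < 2:
        raise ValueError("screening needs variation in both EVr and EVs (>= 2 blocks)")
    if include_choice and data["chosen_side"].nunique() < 2:
        raise ValueError("choice screening needs both chosen sides present")

    X = _candidate_columns(data, epoch, include_choice)
    candidates = [v for v in VARIABLE_ORDER if v in X.columns]

    best: tuple | None = None  # (aic, size, order_key, subset, coefs, sse)
    for size in range(len(candidates) + 1):
        for subset in combinations(candidates, size):
            if size == 0:
                sse = float(y @ y)  # empty model predicts zero
                coefs = {}
            else:
                A = X[list(subset)].to_numpy()
                if np.linalg.matrix_rank(A) < size:
                    logger.info("skipping rank-deficient subset %s", subset)
                    continue
                beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
                resid = y - A @ beta
                sse = float(resid @ resid)
                coefs = dict(zip(subset, beta))
            a = gaussian_aic(sse, n, size)
            key = (a, size, tuple(candidates.index(v) for v in subset))
            if best is None or key < best[:3]:
                best = (*key, subset, coefs)

    assert best is not None
    _, _, _, subset, coefs = best
    return RegressionResult(
        epoch=epoch,
        selected_subset=subset,
        coefficients=coefs,
        aic=best[0],
        label=_classify(subset, coefs),
        n_trials=n,
    )


def screen_activity(trials: pd.DataFrame, epoch: str) -> RegressionResult:
    """AIC-select over subsets of {b0, EVr, EVs, Fb} and classify the activity.

    Uses non-aborted free-choice trials only.  Fb enters the candidate set for
    the feedback epoch only.  Ties on AIC prefer the smaller subset, then the
    earlier subset in canonical variable order.
    """
    return _screen(trials, epoch, include_choice=False)


def screen_choice(trials: pd.DataFrame, epoch: str) -> RegressionResult:
    """As :func:`screen_activity` with Cho (left/right choice) as a candidate.

    The activity is labeled ``choice_only`` when the winning subset contains
    Cho and none of EVr/EVs/Fb.
    """
    return _screen(trials, epoch, include_choice=True)


def screen_sessions(sessions, epochs=("cue", "sac", "fb")) -> pd.DataFrame:
    """Screen every neuron x epoch activity; one tidy row each."""
    rows = []
    for s in sessions:
        for epoch in epochs:
            r = screen_activity(s.trials, epoch)
            rows.append({
                "neuron_id": s.neuron_id,
                "epoch": epoch,
                "selected_subset": "+".join(r.selected_subset) or "(empty)",
                **{f"b_{v}": r.coefficients.get(v, np.nan) for v in VARIABLE_ORDER[:4]},
                "aic": r.aic,
                "label": r.label,
            })
    return pd.DataFrame(rows)
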