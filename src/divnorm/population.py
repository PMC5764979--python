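"""Population-level inference over relative-value coding activities.

The analysis unit is an *activity*: one neuron's firing in one task epoch.
Activities labeled EVr+EVs- or EVr-EVs+ by the screening stage enter the
model-comparison analyses.  This module implements: model selection by
one-sample t-tests on per-activity AIC differences; epoch proportions with a
chi-square homogeneity test; paired free-vs-forced coefficient attenuation;
12-trial binned coefficient time courses with one-way ANOVAs; parameter
dispersion across task phases (Brown-Forsythe) and epochs (Kruskal-Wallis);
parameter sanity correlations (fitted R_max vs observed max rate, fitted
baseline R_max*beta/sigma vs observed pre-cue baseline); and the correlation
between equal-EV activity deviations and behavioral risk attitude.

All tests are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float | tuple
    extra: dict | None = None


def population_best_model(aic_table: pd.DataFrame, reference: str = "M1") -> pd.DataFrame:
    """Compare a reference model's AIC against every competitor across activities.

    ``aic_table`` has one row per activity and one column per model id.  For
    each competitor Mj the per-activity differences AIC_ref - AIC_Mj are
    tested against zero by a two-tailed one-sample t-test; the reference is
    the population-best model iff every mean difference is negative and
    significant at P < 0.05.  Activities missing either fit are dropped
    pairwise.
    """
    if reference not in aic_table.columns:
        raise ValueError(f"reference model {reference!r} not in table")
    if len(aic_table) < 2:
        raise ValueError("need >= 2 activities")
    rows = []
    for competitor in aic_table.columns:
        if competitor == reference:
            continue
        diff = (aic_table[reference] - aic_table[competitor]).dropna()
        n_dropped = len(aic_table) - len(diff)
        if n_dropped:
            logger.info("dropped %d activities missing %s vs %s fits",
                        n_dropped, reference, competitor)
        if diff.std(ddof=1) == 0.0:
            t, p = (0.0, 1.0) if diff.mean() == 0 else (np.inf * np.sign(diff.mean()), 0.0)
        else:
            t, p = stats.ttest_1samp(diff, 0.0)
        rows.append({
            "reference": reference, "competitor": competitor,
            "mean_aic_diff": diff.mean(), "sem": diff.sem(),
            "t": float(t), "df": len(diff) - 1, "p": float(p), "n": len(diff),
        })
    out = pd.DataFrame(rows)
    out.attrs["is_best"] = bool(
        len(out) and ((out["mean_aic_diff"] < 0) & (out["p"] < 0.05)).all()
    )
    return out


def epoch_proportions(counts: dict[str, tuple[int, int]]) -> TestResult:
    """Chi-square homogeneity of modulated proportions across task epochs.

    ``counts`` maps epoch -> (n_modulated, n_total).  The 2 x n_epochs table
    (modulated vs not, per epoch) is tested for homogeneity; df = n_epochs-1.
    Falls back to a Fisher-style permutation-free exact flag when an expected
    cell is zero.
    """
    epochs = list(counts)
    table = np.array([[counts[e][0], counts[e][1] - counts[e][0]] for e in epochs]).T
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return TestResult(np.nan, np.nan, len(epochs) - 1, {"exact_fallback": True})
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    pcts = {e: 100.0 * counts[e][0] / counts[e][1] for e in epochs}
    return TestResult(float(chi2), float(p), int(df), {"percent": pcts})


def context_attenuation(coef_table: pd.DataFrame) -> dict[str, TestResult]:
    """Paired t-tests on |regression coefficients|, free vs forced trials.

    ``coef_table`` has one row per activity with columns b_EVr_free,
    b_EVr_forced, b_EVs_free, b_EVs_forced (assumption-1 regressors).  Rows
    with any missing entry are dropped.  Returns per-variable results with
    means +/- sem of the absolute coefficients in ``extra``.
    """
    table = coef_table.dropna(
        subset=["b_EVr_free", "b_EVr_forced", "b_EVs_free", "b_EVs_forced"]
    )
    if len(table) < 2:
        raise ValueError("need >= 2 paired activities for the attenuation test")
    out = {}
    for var in ("EVr", "EVs"):
        free = table[f"b_{var}_free"].abs()
        forced = table[f"b_{var}_forced"].abs()
        if (free - forced).std(ddof=1) == 0.0:
            t, p = (0.0, 1.0)
        else:
            t, p = stats.ttest_rel(free, forced)
        out[var] = TestResult(float(t), float(p), len(table) - 1, {
            "mean_free": free.mean(), "sem_free": free.sem(),
            "mean_forced": forced.mean(), "sem_forced": forced.sem(),
            "n": len(table),
        })
    return out


def value_regression_coefficients(trials: pd.DataFrame, epoch: str,
                                  context: str) -> dict[str, float]:
    """OLS coefficients of rate ~ 1 + EVr + EVs on one context's trials."""
    sel = trials[(trials["context"] == context) & (trials["aborted"] == 0)]
    A = np.column_stack([np.ones(len(sel)), sel["EVr_ul"], sel["EVs_ul"]])
    beta, _, _, _ = np.linalg.lstsq(A, sel[f"rate_{epoch}"].to_numpy(float), rcond=None)
    return {"b0": float(beta[0]), "b_EVr": float(beta[1]), "b_EVs": float(beta[2])}


def attenuation_table(activities: list[tuple[pd.DataFrame, str]]) -> pd.DataFrame:
    """Free and forced value-regression coefficients, one row per activity."""
    rows = []
    for trials, epoch in activities:
        free = value_regression_coefficients(trials, epoch, "free")
        forced = value_regression_coefficients(trials, epoch, "forced")
        rows.append({
            "epoch": epoch,
            "b_EVr_free": free["b_EVr"], "b_EVs_free": free["b_EVs"],
            "b_EVr_forced": forced["b_EVr"], "b_EVs_forced": forced["b_EVs"],
        })
    return pd.DataFrame(rows)


def phase_trials(trials: pd.DataFrame, phase: str) -> pd.DataFrame:
    """Subset of a session for one task phase.

    ``forced`` = within-block trials 1-36; ``free1``/``free2`` = first / second
    half of the 50 free-choice trials (37-61 / 62-86), split by trial index
    within the block.
    """
    if phase == "forced":
        return trials[trials["trial"] <= 36]
    if phase == "free1":
        return trials[(trials["trial"] > 36) & (trials["trial"] <= 61)]
    if phase == "free2":
        return trials[trials["trial"] > 61]
    raise ValueError(f"unknown phase {phase!r}")


def _bin_coefficients(trials: pd.DataFrame, epoch: str, bin_size: int,
                      n_forced: int, n_free_binned: int) -> list[dict]:
    """|EVr| and |EVs| coefficients per 12-trial bin for one activity.

    Bin j pools trials with within-block index in the bin across all blocks
    and regresses the epoch rate on {1, EVr, EVs}; trailing partial free bins
    are dropped.
    """
    rows = []
    edges = list(range(0, n_forced + n_free_binned, bin_size))
    for start in edges:
        lo, hi = start + 1, start + bin_size
        sel = trials[(trials["trial"] >= lo) & (trials["trial"] <= hi)
                     & (trials["aborted"] == 0)]
        context = "forced" if hi <= n_forced else "free"
        if len(sel) < 4 or sel["EVr_ul"].nunique() < 2:
            logger.info("bin %d-%d skipped (too few usable trials)", lo, hi)
            continue
        A = np.column_stack([np.ones(len(sel)), sel["EVr_ul"], sel["EVs_ul"]])
        beta, _, _, _ = np.linalg.lstsq(A, sel[f"rate_{epoch}"].to_numpy(float), rcond=None)
        rows.append({"bin_start": lo, "context": context,
                     "abs_b_EVr": abs(beta[1]), "abs_b_EVs": abs(beta[2])})
    return rows


def binned_coefficients(activities: list[tuple[pd.DataFrame, str]],
                        bin_size: int = 12) -> dict:
    """12-trial binned coefficient time course with within-context ANOVAs.

    ``activities`` is a list of (trials, epoch) pairs, one per relative-value
    activity.  Coefficients are estimated in bins of ``bin_size`` trials from
    the start of each payoff block: 3 forced bins (36 trials) and 4 free bins
    (first 48 of the 50 free trials; the trailing 2 are dropped).  Returns the
    per-bin table, a one-way ANOVA across bins within each context (on the
    pooled |EVr| and |EVs| entries), and a paired t-test between the last
    forced and first free bin.
    """
    n_forced, n_free_binned = 36, (50 // bin_size) * bin_size
    rows = []
    for i, (trials, epoch) in enumerate(activities):
        for r in _bin_coefficients(trials, epoch, bin_size, n_forced, n_free_binned):
            rows.append({"activity": i, **r})
    table = pd.DataFrame(rows)
    long = table.melt(id_vars=["activity", "bin_start", "context"],
                      value_vars=["abs_b_EVr", "abs_b_EVs"], value_name="abs_coef")

    anova = {}
    for context in ("forced", "free"):
        groups = [g["abs_coef"].to_numpy()
                  for _, g in long[long["context"] == context].groupby("bin_start")]
        f, p = stats.f_oneway(*groups)
        df = (len(groups) - 1, sum(len(g) for g in groups) - len(groups))
        anova[context] = TestResult(float(f), float(p), df,
                                    {"n": sum(len(g) for g in groups)})

    last_forced = long[long["bin_start"] == n_forced - bin_size + 1]
    first_free = long[long["bin_start"] == n_forced + 1]
    merged = last_forced.merge(first_free, on=["activity", "variable"],
                               suffixes=("_forced", "_free"))
    t, p = stats.ttest_rel(merged["abs_coef_free"], merged["abs_coef_forced"])
    boundary = TestResult(float(t), float(p), len(merged) - 1, {"n": len(merged)})
    return {"table": table, "anova": anova, "boundary": boundary}


def parameter_dispersion(params_by_phase: pd.DataFrame) -> dict[str, TestResult]:
    """Brown-Forsythe test of parameter spread across task phases.

    ``params_by_phase`` has columns phase (forced / free1 / free2 for forced
    trials and the two halves of the free trials) and R_max / beta / sigma.
    The Brown-Forsythe test is the median-centered Levene test; a wider
    forced-phase distribution drives it significant.
    """
    out = {}
    phases = [g for _, g in params_by_phase.groupby("phase")]
    if len(phases) < 2 or any(len(g) < 3 for g in phases):
        raise ValueError("need >= 2 phases with >= 3 values each")
    for name in ("R_max", "beta", "sigma"):
        groups = [g[name].dropna().to_numpy() for g in phases]
        if any(np.ptp(g) == 0 for g in groups):
            out[name] = TestResult(np.nan, np.nan, np.nan, {"constant_group": True})
            continue
        f, p = stats.levene(*groups, center="median")
        n = sum(len(g) for g in groups)
        out[name] = TestResult(float(f), float(p), n - len(groups), {"n": n})
    return out


def parameter_kruskal(params_by_epoch: pd.DataFrame) -> dict[str, TestResult]:
    """Kruskal-Wallis test of free-choice parameter location across epochs."""
    out = {}
    groups_by_epoch = [g for _, g in params_by_epoch.groupby("epoch")]
    for name in ("R_max", "beta", "sigma"):
        groups = [g[name].dropna().to_numpy() for g in groups_by_epoch]
        h, p = stats.kruskal(*groups)
        out[name] = TestResult(float(h), float(p), len(groups) - 1,
                               {"n": sum(len(g) for g in groups)})
    return out


def parameter_sanity(table: pd.DataFrame) -> dict[str, TestResult]:
    """Correlate fitted normalization parameters with observed firing rates.

    ``table`` has one row per activity with fitted R_max / beta / sigma and
    the observed max_rate and baseline_rate.  Reports Pearson r (with t and
    df) for fitted R_max vs max rate, and for the model's zero-value output
    R_max*beta/sigma vs the pre-cue baseline rate; rows with negative fitted
    beta or sigma are excluded from the baseline relation.
    """
    out = {}

    def _corr(x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return TestResult(np.nan, np.nan, len(x) - 2, {"constant_input": True})
        r, p = stats.pearsonr(x, y)
        df = len(x) - 2
        t = r * np.sqrt(df / (1.0 - r**2)) if abs(r) < 1 else np.inf
        return TestResult(float(r), float(p), df, {"t": float(t), "n": len(x)})

    out["rmax_vs_max_rate"] = _corr(table["R_max"], table["max_rate"])
    ok = table[(table["beta"] > 0) & (table["sigma"] > 0)]
    n_excluded = len(table) - len(ok)
    if n_excluded:
        logger.info("excluded %d activities with negative beta/sigma from baseline relation",
                    n_excluded)
    baseline_pred = ok["R_max"] * ok["beta"] / ok["sigma"]
    out["baseline_vs_baseline_rate"] = _corr(baseline_pred, ok["baseline_rate"])
    return out


def equal_ev_deviation(trials: pd.DataFrame, epoch: str) -> float:
    """Deviation of equal-EV (LP3) firing from the linear value trend.

    Per payoff block, condition-mean rates across LP1-5 are regressed on
    EVr - EVs; the deviation is the mean LP3 rate minus the value the linear
    fit predicts at LP3, averaged over blocks.  A systematic deviation tracks
    a curvature in value coding that risk attitude can induce.
    """
    data = trials[(trials["context"] == "free") & (trials["aborted"] == 0)]
    devs = []
    for _, g in data.groupby("block_id"):
        m = g.groupby("lp_index").agg(
            rate=(f"rate_{epoch}", "mean"), EVr=("EVr_ul", "first"), EVs=("EVs_ul", "first")
        )
        if len(m) < 3 or 3 not in m.index:
            continue
        x = (m["EVr"] - m["EVs"]).to_numpy()
        A = np.column_stack([np.ones(len(m)), x])
        beta, _, _, _ = np.linalg.lstsq(A, m["rate"].to_numpy(), rcond=None)
        x3 = float(m.loc[3, "EVr"] - m.loc[3, "EVs"])
        devs.append(float(m.loc[3, "rate"] - (beta[0] + beta[1] * x3)))
    return float(np.mean(devs)) if devs else np.nan


def risk_attitude_correlation(table: pd.DataFrame) -> dict[str, TestResult]:
    """Correlate equal-EV activity deviations with behavioral risk attitude.

    ``table`` has one row per relative-value activity with columns label,
    deviation (from :func:`equal_ev_deviation`) and risky_pct (the session's
    % risky choices on equal-EV trials).  Pearson r is computed separately
    for the EVr+EVs- and EVr-EVs+ groups; groups with < 3 activities are
    omitted.
    """
    out = {}
    for label, g in table.groupby("label"):
        if label not in ("EVr+EVs-", "EVr-EVs+"):
            continue
        g = g.dropna(subset=["deviation", "risky_pct"])
        if len(g) < 3:
            logger.info("label %s has < 3 activities; correlation omitted", label)
            continue
        if np.ptp(g["deviation"]) == 0 or np.ptp(g["risky_pct"]) == 0:
            out[label] = TestResult(0.0, np.nan, len(g) - 2, {"degenerate": True})
            continue
        r, p = stats.pearsonr(g["deviation"], g["risky_pct"])
        out[label] = TestResult(float(r), float(p), len(g) - 2, {"n": len(g)})
    return out
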