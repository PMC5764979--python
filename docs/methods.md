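# Methods

## The task and its encoding

The package models a two-alternative cued-lottery task for behaving monkeys.
On every trial a *safe* option pays a cued water volume with certainty and a
*risky* option pays its cued volume with probability 0.5 (otherwise nothing).
Twenty lottery pairs are organised into four payoff blocks (PB1–PB4) with
safe magnitudes 60/120/180/240 μl. Within a block the five risky magnitudes
sit on the task's 60-μl cue grid at `2·safe + {−120, −60, 0, +60, +120}` μl,
so the middle pair (LP3) has exactly equal expected values and the risky
expected values straddle the safe one (LP1 < LP2 < LP3 = safe < LP4 < LP5).
This grid is the unique one consistent with the block maxima (240/360/480/600
μl), the equal-EV middle pair and the 60-μl increment rule. The lowest entry
of PB1 falls off the grid at 0 and is rendered as a blank cue paying 5 μl; we
treat it as PB1's lowest risky cue (EV 2.5 μl) while the block's minimum
reward *outcome* stays 0 μl (the risky no-reward outcome), which is what the
range-normalization model consumes.

Each block runs 86 trials: 36 forced-choice trials (6 repeats × 6 instructed
conditions — the five risky-instructed pairs plus one safe-instructed
condition whose displayed risky cue cycles deterministically over the pairs)
followed by 50 free-choice trials (10 repeats × 5 pairs), both phases
shuffled. The risky option's screen side is drawn once per block; the four
blocks appear in random order without replacement. Aborted trials are flagged
and excluded from analysis rather than re-inserted: re-presentation changes
only trial bookkeeping, not any fitted quantity.

## Synthetic behavior and spiking

No public recordings accompany the analysis, so the generator supplies
sessions with the statistical structure the pipeline assumes. These choices
are stand-ins, selected for simplicity, not estimates of the animals:

- **Choice**: on free trials the risky option is chosen with probability
  `logistic(λ (EVr + ρ − EVs))`, inverse temperature λ = 0.05 μl⁻¹ and risky
  bonus ρ = 0 μl by default. λ = 0.05 puts the extreme pairs (±60 μl EV
  difference) at ≈95%/5% risky choice, matching the steep but imperfect
  psychometric curves the task is designed to produce. ρ shifts the
  indifference point and encodes risk attitude with a single parameter;
  utility curvature is deliberately not modelled.
- **Reaction times** are log-normal (median 200 ms, log-sd 0.2); **aborts**
  are Bernoulli at 5% per trial by default.
- **Spiking**: per trial and epoch (cue / saccade / feedback, 1.0-s windows)
  the mean rate is the ground-truth model's prediction floored at 0.01
  spikes s⁻¹, and the observed rate is a Poisson count over the window.
  Poisson counts are the simplest noise model consistent with non-negative
  rates and mean-proportional variance; epochs are drawn independently given
  the trial because all analyses treat epochs separately. The baseline rate
  is a Poisson count over a 0.6-s pre-cue window around the model's
  zero-value output (`R_max β/σ` for fractional models, the intercept
  otherwise).
- **Context attenuation**: ground truths carry multiplicative β and σ
  inflation factors (≥ 1) applied on forced-choice trials, emulating reduced
  value sensitivity outside of free choice. The ×5 factor used in the
  recovery experiments produces coefficient ratios of roughly one half,
  comparable to the effect size the analysis is meant to detect.

What the generator does **not** emulate: spike-train temporal structure
within epochs, firing-rate drift or adaptation across trials, inter-neuron
correlations, behavioral state (motivation/attention) dynamics, and any
systematic EV dependence of reaction times or abort rates. Passing recovery
tests therefore show that the pipeline is correct and well-powered under its
own assumptions, not that real cortical data satisfy them.

## Screening for relative-value coding

Non-aborted free-choice rates are regressed on every subset of
{b₀, EVr, EVs, Fb} (Fb, the reward/no-reward indicator, only in the feedback
epoch; a left/right choice regressor Cho is added in the choice variant),
including the empty and intercept-only subsets. The subset with minimal AIC
wins; an activity is relative-value coding when the winner contains EVr and
EVs with opposite-signed coefficients, and choice-coding when it contains Cho
without any value/feedback regressor. AIC for all least-squares fits uses
the Gaussian concentrated likelihood, `AIC = n ln(SSE/n) + 2k`, with k the
number of fitted coefficients and additive constants dropped — the
likelihood family is a convention, applied identically to every fit of one
activity, so all within-activity AIC differences are invariant to it. Ties
prefer the smaller subset, then canonical variable order, for determinism.

## The model zoo

Thirteen firing-rate models share one prediction interface. For the
relative-value models, EV₁ is the preferred option's expected value (the
risky EV for EVr+EVs− activities, the safe EV for EVr−EVs+):

| id | form | free parameters |
|----|------|----|
| M1 | `R_max (β + EV₁)/(σ + EV₁ + EV₂)` — divisive normalization | R_max, β, σ |
| M2 | `R_max EV₁/(EV₁ + EV₂) + b` — simple fractional | R_max, b |
| M3 | `G (EV₁ − EV₂) + b` — value difference | G, b |
| M4 | `R_max (EV₁ − V_min)/(V_max − V_min) + b` — range normalization | R_max, b |
| M5–M8 | linear in EVr / EVs / EV_chosen / risky-choice indicator | a, b |
| M9 | constant (null) | b |
| M10 | block-wise linear in EVr: `a_i EVr + b_i` in block i | a₁–a₄, b₁–b₄ |
| M11–M13 | M1 + a·Context / a·PercentCorrect / a·RT | R_max, β, σ, a |

M10 is written as a single sum over block terms in some notations; the only
reading with eight identifiable parameters is block-indexed piecewise-linear,
which is what we implement. PercentCorrect (M12) is the percentage of
non-aborted trials of the trial's lottery pair over the session; RT (M13) is
the saccadic reaction time z-scored per session — an affine transformation
that conditions the optimization without changing AIC comparisons. On
forced-choice trials two value conventions are supported: assumption 1 keeps
the cued values, assumption 2 zeroes the non-selectable option's value.

## Fitting

Models linear in their parameters (M2–M10; the fractional and range
regressors are fixed functions of the covariates) are solved exactly by
ordinary least squares. M1 and M11–M13 are fitted by unbounded
Levenberg–Marquardt least squares restarted from random initial values:
R_max ~ U(0.5, 2)× the observed max rate, β, σ ~ U(1, 600) μl, the covariate
gain ~ N(0, sd of the rates). Starts are drawn sequentially from one seeded
stream, so the best SSE is non-increasing in the restart count and every fit
is replayable from its recorded seed. Defaults: 100 restarts (the recovery
experiments use 20–30, which on this 3–4-parameter problem already finds the
global basin in essentially every session), relative tolerance 1e-8, 500
function evaluations per restart. Parameters are unbounded because negative
fitted β/σ are informative — they flag activities the normalization form no
longer describes. Near-singular denominators are clamped at |σ + EV₁ + EV₂|
≥ 1e-6 inside the residual so restarts that wander across the pole stay
finite; fits whose best solution sits at the clamp are effectively rejected
by their SSE.

Percent variance explained is `100 (1 − SSE/SST)` computed either over
single trials or over the 20 lottery-pair condition means; the mean-response
basis discounts trial-by-trial Poisson variability and is therefore the
larger of the two on noisy data. Two-fold cross-validation splits each
lottery pair's trials in half (stratified, ±1 for odd counts), fits on the
training fold and evaluates mean-response VE on both folds with the training
parameters.

## Population inference

All tests are two-tailed. The analysis unit is the *activity* (neuron ×
epoch); activities passing the relative-value screen enter model comparison,
with epoch identity retained as a column. A reference model is
population-best when its per-activity AIC differences against every
competitor are negative and significant by one-sample t-test at P < 0.05.
Epoch proportions use a 2 × 3 chi-square homogeneity test (df = 2).
Free-vs-forced attenuation is a paired t-test on |EVr| and |EVs| regression
coefficients per activity. Binned time courses estimate the coefficients in
12-trial bins pooled across blocks — three forced bins and the first four
free bins (two trailing free trials dropped) — with a one-way ANOVA across
bins within each context and a paired t-test at the forced→free boundary.
Parameter dispersion across phases (forced / first half of free / second
half of free, split by within-block trial index) uses the Brown–Forsythe
(median-centered Levene) test; parameter location across epochs uses
Kruskal–Wallis. Parameter sanity reports Pearson correlations of fitted
R_max with the observed maximal rate and of `R_max β/σ` with the observed
pre-cue baseline, excluding activities with negative fitted β or σ from the
baseline relation.

The risk-attitude analysis needs a deviation statistic for equal-EV trials:
per block, the five condition-mean rates are regressed linearly on
EVr − EVs, and the deviation is the LP3 mean rate minus the linear fit's
prediction at LP3, averaged over blocks. This operationalization — a
departure from linearity at the indifference point — is our design choice;
the session's risk attitude is its percentage of risky choices on LP3 free
trials. Correlations are computed separately per coding type and omitted
below three activities.

## Numerical and degenerate-input conventions

SSE is floored at the smallest positive float inside the AIC logarithm so
perfect (noise-free) fits remain finite. Rank-deficient screening subsets
are skipped with a log entry; lottery pairs with fewer than two trials are
excluded from cross-validation; constant groups make dispersion and
correlation statistics undefined and are flagged rather than raised. Zero
total variance yields a missing VE. Fits with zero converged restarts raise
with diagnostics; fewer than ten converged restarts warns.

## Problem sizes

The recovery experiments shipped with the package use 30–50 simulated
neurons with 344-trial sessions (the task's natural session length), 20–30
optimizer restarts, and 100 cross-validation splits. These sizes were chosen
so each experiment has clear statistical power for the directional effects
it checks while a full run of the suite and the acceptance script completes
in well under a minute each on one core.

## Known limitations

- The Gaussian-AIC convention is one defensible likelihood family for
  least-squares fits; absolute AIC values are convention-dependent even
  though all comparisons reported are not.
- The generator's independence assumptions (across trials, epochs and
  neurons) make population tests better behaved than real recordings, where
  slow drift and correlated noise inflate false-positive rates.
- Model M10's parameters are only jointly identifiable when all four blocks
  are present; with missing blocks the fit silently returns the minimum-norm
  solution for the absent blocks' parameters.
- The equal-EV deviation statistic is one of several reasonable
  operationalizations; conclusions about risk-attitude coupling are specific
  to it.
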