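"""Population-level model selection and the free-vs-forced context effect.

Generates a small population of divisive-normalization neurons whose value
sensitivity is attenuated on forced-choice trials (beta and sigma inflated
x5), then runs the population AIC comparison and the paired attenuation test.
"""

import warnings

import pandas as pd

from divnorm import simulate, fitting, population

warnings.filterwarnings("ignore", message="only .* restarts converged")


def sampler(rng, i):
    return simulate.GroundTruth(
        "M1",
        {"R_max": rng.uniform(20, 50), "beta": rng.uniform(10, 60),
         "sigma": rng.uniform(20, 100)},
        forced_beta_scale=5.0, forced_sigma_scale=5.0)


sessions = simulate.generate_dataset(15, sampler, seed=4)

aics = pd.DataFrame(
    [{m: fitting.fit_model(s.trials, "cue", m, "EVr+EVs-", n_restarts=20, seed=i).aic
      for m in ("M1", "M2", "M3", "M4")}
     for i, s in enumerate(sessions)])
comp = population.population_best_model(aics, "M1")
print("population AIC comparison (negative mean favors M1):")
for _, r in comp.iterrows():
    print(f"  M1 - {r['competitor']}: mean={r['mean_aic_diff']:7.2f}  "
          f"t={r['t']:6.2f}  P={r['p']:.2g}")
print(f"  M1 declared population-best: {comp.attrs['is_best']}")

att = population.context_attenuation(
    population.attenuation_table([(s.trials, "cue") for s in sessions]))
for var in ("EVr", "EVs"):
    e = att[var].extra
    print(f"|b_{var}|: free {e['mean_free']:.3f} vs forced {e['mean_forced']:.3f}  "
          f"(paired t={att[var].statistic:.2f}, P={att[var].p_value:.2g})")

print("\nWith forced-phase beta/sigma inflated, the regression coefficients on"
      "\nforced trials should be roughly half their free-choice size and the"
      "\npaired t-tests clearly significant.")
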