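"""Screen a simulated neuron for relative-value coding.

Simulates a neuron whose firing follows the divisive-normalization model and
runs the exhaustive-AIC variable selection on each task epoch.  A neuron
coding relative value is flagged by opposite-signed EVr/EVs coefficients.
"""

from divnorm import task, simulate, screening

schedule = task.build_trial_schedule(seed=2)
trials = simulate.simulate_behavior(schedule, simulate.BehaviorParams(), seed=2)
truth = simulate.GroundTruth("M1", {"R_max": 40.0, "beta": 20.0, "sigma": 60.0})
session = simulate.simulate_neuron(trials, truth, seed=2)

for epoch in ("cue", "sac", "fb"):
    r = screening.screen_activity(session.trials, epoch)
    coefs = ", ".join(f"{k}={v:.3g}" for k, v in r.coefficients.items())
    print(f"{epoch:>4}: subset={'+'.join(r.selected_subset)}  label={r.label}  "
          f"AIC={r.aic:.1f}  ({coefs})")

print("\nThe generating model prefers the risky option, so every epoch should be"
      "\nlabeled EVr+EVs-: a positive EVr coefficient and a negative EVs one.")
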