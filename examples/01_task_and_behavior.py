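"""Build the cued-lottery task and simulate choice behavior.

Constructs the four payoff blocks (20 lottery pairs), draws a full 344-trial
session schedule and plays it out with the softmax choice model; prints the
block structure and the psychometric pattern of risky choices.
"""

from divnorm import task, simulate

blocks = task.build_payoff_blocks()
print("payoff blocks (safe magnitude, risky magnitudes, value range in ul):")
for b in blocks:
    print(f"  PB{b.block_id}: safe {b.safe_magnitude_ul:5.0f}  "
          f"risky {[int(m) for m in b.risky_magnitudes_ul]}  "
          f"range {task.value_range(b)}")

schedule = task.build_trial_schedule(seed=1)
trials = simulate.simulate_behavior(schedule, simulate.BehaviorParams(), seed=1)
summary = simulate.behavior_summary(trials)

print("\npercent risky choice by lottery pair (rows: payoff block):")
pivot = summary.pivot(index="block_id", columns="lp_index", values="risky_pct")
print(pivot.round(0).to_string())
print("\nLP1/LP2 offer the risky option below the safe expected value and LP4/LP5"
      "\nabove it, so risky% should rise from left to right; LP3 (equal expected"
      "\nvalues) should sit near 50% for a risk-neutral chooser.")
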