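"""Cued-lottery task structure: options, payoff blocks, lottery pairs, schedules.

The task offers a choice between a *safe* option (100% reward) and a *risky*
option (50% reward, otherwise nothing).  Twenty lottery pairs are organised
into four payoff blocks; within a block the safe magnitude is fixed and the
risky magnitude takes five values whose expected values straddle the safe
expected value (LP1 well below ... LP3 equal ... LP5 well above).  Each block
runs 86 trials: 36 forced-choice trials (6 repeats x 6 instructed conditions)
followed by 50 free-choice trials (10 repeats x 5 pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Safe-option reward magnitudes (microlitres) for payoff blocks 1-4.
SAFE_MAGNITUDES_UL = (60.0, 120.0, 180.0, 240.0)

#: Reward paid by the "blank" pie chart (displayed as an empty chart).
BLANK_REWARD_UL = 5.0

#: Probability of reward for risky / safe options.
RISKY_PROBABILITY = 0.5
SAFE_PROBABILITY = 1.0

N_FORCED_PER_BLOCK = 36
N_FREE_PER_BLOCK = 50
N_TRIALS_PER_BLOCK = N_FORCED_PER_BLOCK + N_FREE_PER_BLOCK
N_BLOCKS = 4
N_PAIRS_PER_BLOCK = 5

SCHEDULE_COLUMNS = [
    "block_id", "trial", "context", "lp_index",
    "safe_mag_ul", "risky_mag_ul", "instructed", "risky_side",
]


@dataclass(frozen=True)
class LotteryOption:
    """A single cued option: a reward magnitude delivered with a probability."""

    magnitude_ul: float
    probability: float
    kind: str  # "risky" or "safe"

    def __post_init__(self) -> None:
        if self.magnitude_ul < 0:
            raise ValueError(f"magnitude must be non-negative, got {self.magnitude_ul}")
        if self.probability not in (RISKY_PROBABILITY, SAFE_PROBABILITY):
            raise ValueError(f"probability must be 0.5 or 1.0, got {self.probability}")
        if self.kind not in ("risky", "safe"):
            raise ValueError(f"kind must be 'risky' or 'safe', got {self.kind!r}")

    @property
    def expected_value(self) -> float:
        return self.magnitude_ul * self.probability


def expected_value(option: LotteryOption) -> float:
    """Expected value of an option in microlitres: magnitude x probability."""
    return option.expected_value


@dataclass(frozen=True)
class LotteryPair:
    """One risky-vs-safe pairing; ``lp_index`` 3 has equal expected values."""

    block_id: int
    lp_index: int
    risky: LotteryOption
    safe: LotteryOption

    def __post_init__(self) -> None:
        if self.risky.kind != "risky" or self.safe.kind != "safe":
            raise ValueError("pair must hold exactly one risky and one safe option")
        if not (1 <= self.lp_index <= N_PAIRS_PER_BLOCK):
            raise ValueError(f"lp_index out of range: {self.lp_index}")


@dataclass(frozen=True)
class PayoffBlock:
    """A block's reward structure: one safe magnitude against five risky ones.

    ``v_min``/``v_max`` are the smallest and largest possible reward *outcomes*
    in the block; the risky option can pay nothing, so ``v_min`` is 0.
    """

    block_id: int
    safe_magnitude_ul: float
    risky_magnitudes_ul: tuple[float, ...]
    pairs: tuple[LotteryPair, ...]

    @property
    def v_min(self) -> float:
        return 0.0

    @property
    def v_max(self) -> float:
        return max(self.risky_magnitudes_ul)


def build_payoff_blocks() -> list[PayoffBlock]:
    """Construct payoff blocks 1-4.

    Safe magnitudes are 60/120/180/240 ul.  Risky magnitudes run on the 60-ul
    grid centred (in expected value) on the safe option: twice the safe
    magnitude plus {-120, -60, 0, +60, +120} ul, so the middle pair (LP3) has
    exactly equal expected values.  The lowest entry of block 1 falls off the
    grid and is the "blank" chart paying 5 ul.
    """
    blocks: list[PayoffBlock] = []
    for block_id, safe_mag in enumerate(SAFE_MAGNITUDES_UL, start=1):
        risky_mags = tuple(
            BLANK_REWARD_UL if 2.0 * safe_mag + d == 0.0 else 2.0 * safe_mag + d
            for d in (-120.0, -60.0, 0.0, 60.0, 120.0)
        )
        safe = LotteryOption(safe_mag, SAFE_PROBABILITY, "safe")
        pairs = tuple(
            LotteryPair(block_id, i, LotteryOption(m, RISKY_PROBABILITY, "risky"), safe)
            for i, m in enumerate(risky_mags, start=1)
        )
        blocks.append(PayoffBlock(block_id, safe_mag, risky_mags, pairs))
    return blocks


def value_range(block: PayoffBlock) -> tuple[float, float]:
    """(v_min, v_max) of reward outcomes in a block, in microlitres."""
    return (block.v_min, block.v_max)


def build_trial_schedule(seed: int) -> pd.DataFrame:
    """Build a full session schedule: 4 payoff blocks x 86 trials.

    Per block the first 36 trials are forced choice — 6 repeats of 6 instructed
    conditions (risky-instructed at each of the five lottery pairs, plus one
    safe-instructed condition whose displayed risky cue cycles over the pairs)
    — in random order, followed by 50 free-choice trials (10 repeats x 5 pairs)
    in random order.  The risky option's side is drawn once per block and the
    four blocks appear in a random order without replacement.

    Deterministic: identical seeds give identical schedules.
    """
    rng = np.random.default_rng(seed)
    blocks = build_payoff_blocks()
    block_order = rng.permutation(N_BLOCKS) + 1

    rows = []
    for block_id in block_order:
        block = blocks[block_id - 1]
        risky_side = "left" if rng.random() < 0.5 else "right"

        # forced phase: 6 repeats x (5 risky-instructed + 1 safe-instructed)
        forced: list[tuple[str, int]] = []
        for repeat in range(6):
            forced.extend(("risky", lp) for lp in range(1, 6))
            forced.append(("safe", repeat % N_PAIRS_PER_BLOCK + 1))
        order = rng.permutation(len(forced))
        forced = [forced[i] for i in order]

        free = [lp for lp in range(1, 6) for _ in range(10)]
        free = [free[i] for i in rng.permutation(len(free))]

        trial = 0
        for instructed, lp in forced:
            trial += 1
            rows.append((block_id, trial, "forced", lp,
                         block.safe_magnitude_ul, block.risky_magnitudes_ul[lp - 1],
                         instructed, risky_side))
        for lp in free:
            trial += 1
            rows.append((block_id, trial, "free", lp,
                         block.safe_magnitude_ul, block.risky_magnitudes_ul[lp - 1],
                         "none", risky_side))

    df = pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)
    df["block_id"] = df["block_id"].astype(int)
    return df


def schedule_expected_values(schedule: pd.DataFrame) -> pd.DataFrame:
    """Append EVr_ul / EVs_ul columns derived from the cued magnitudes."""
    out = schedule.copy()
    out["EVr_ul"] = out["risky_mag_ul"] * RISKY_PROBABILITY
    out["EVs_ul"] = out["safe_mag_ul"] * SAFE_PROBABILITY
    return out
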