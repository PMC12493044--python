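"""Probabilistic reward-learning task: schedule generation and outcome sampling.

The task is a two-armed bandit run in short blocks. Within a block two novel
abstract symbols are shown; one pays 100 points with probability 0.75, the
other with probability 0.25. Blocks come in three recipient conditions —
``self`` (points convert to money for the participant), ``other`` (points
convert to money for an anonymous other person) and ``noone`` (points are
displayed but benefit nobody). Each recipient condition is run for three
blocks of 16 trials, giving 48 trials per recipient and 144 trials in total,
with the constraint that the same recipient never appears in consecutive
blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recipient",
    "MISSED",
    "TrialRecord",
    "Block",
    "Schedule",
    "build_schedule",
    "sample_outcome",
    "recipient_orders",
    "write_trials",
    "read_trials",
    "HIGH_PROB",
    "LOW_PROB",
    "POINTS_WIN",
]

HIGH_PROB = 0.75
LOW_PROB = 0.25
POINTS_WIN = 100

#: Sentinel recorded as the chosen symbol when the participant failed to respond.
MISSED = "MISSED"


class Recipient(str, Enum):
    SELF = "self"
    OTHER = "other"
    NOONE = "noone"


RECIPIENTS = (Recipient.SELF, Recipient.OTHER, Recipient.NOONE)


def recipient_orders() -> list[tuple[Recipient, Recipient, Recipient]]:
    """The six recipient-order permutations participants are assigned to."""
    return list(permutations(RECIPIENTS))


@dataclass
class TrialRecord:
    """One observed trial.

    ``chosen`` is the id of the selected symbol, or :data:`MISSED`;
    ``outcome`` is 0 or 100 points and is undefined (stored as 0) for missed
    trials; ``is_high_chosen`` records whether the 75%-reward symbol was
    picked.
    """

    subject_id: str
    block_index: int
    trial_index: int
    recipient: Recipient
    side_of_high: str  # "left" | "right"
    chosen: str = MISSED
    outcome: int = 0
    is_high_chosen: bool = False

    @property
    def missed(self) -> bool:
        return self.chosen == MISSED


@dataclass
class Block:
    recipient: Recipient
    symbol_high: str
    symbol_low: str
    trials: list[TrialRecord] = field(default_factory=list)

    reward_prob_high: float = HIGH_PROB
    reward_prob_low: float = LOW_PROB


@dataclass
class Schedule:
    """Full trial schedule for one participant.

    Nine 16-trial blocks (three per recipient) laid out by repeating one of
    the six recipient orderings, which guarantees no two consecutive blocks
    share a recipient.
    """

    blocks: list[Block]
    order_index: int
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return sum(len(b.trials) for b in self.blocks)

    def trials(self):
        for block in self.blocks:
            yield from block.trials

    def validate(self) -> None:
        counts: dict[Recipient, int] = {r: 0 for r in RECIPIENTS}
        prev = None
        symbols: set[str] = set()
        for block in self.blocks:
            counts[block.recipient] += len(block.trials)
            if prev is not None and block.recipient == prev:
                raise ValueError(
                    f"consecutive blocks share recipient {block.recipient!r}"
                )
            prev = block.recipient
            for sym in (block.symbol_high, block.symbol_low):
                if sym in symbols:
                    raise ValueError(f"symbol {sym!r} repeated across blocks")
                symbols.add(sym)
        if any(c != counts[RECIPIENTS[0]] for c in counts.values()):
            raise ValueError(f"unbalanced recipient trial counts: {counts}")


def build_schedule(
    order_index: int,
    seed: int,
    *,
    n_blocks_per_recipient: int = 3,
    n_trials_per_block: int = 16,
    subject_id: str = "sim",
) -> Schedule:
    """Construct the pseudo-randomised block schedule.

    Parameters
    ----------
    order_index:
        Which of the 6 recipient-order permutations to use (0..5). The
        ordering is repeated ``n_blocks_per_recipient`` times, so the same
        recipient never appears consecutively.
    seed:
        Seeds the left/right placement of the high-probability symbol.
    """
    orders = recipient_orders()
    if not (0 <= order_index < len(orders)):
        raise ValueError(
            f"order_index must be in 0..{len(orders) - 1}, got {order_index}"
        )
    rng = np.random.default_rng(seed)
    recipient_seq = orders[order_index] * n_blocks_per_recipient

    blocks: list[Block] = []
    for b, recipient in enumerate(recipient_seq):
        block = Block(
            recipient=recipient,
            symbol_high=f"b{b:02d}_high",
            symbol_low=f"b{b:02d}_low",
        )
        sides = rng.integers(0, 2, size=n_trials_per_block)
        for t in range(n_trials_per_block):
            block.trials.append(
                TrialRecord(
                    subject_id=subject_id,
                    block_index=b,
                    trial_index=t,
                    recipient=recipient,
                    side_of_high="left" if sides[t] == 0 else "right",
                )
            )
        blocks.append(block)
    schedule = Schedule(blocks=blocks, order_index=order_index, seed=seed)
    schedule.validate()
    return schedule


def sample_outcome(reward_prob: float, rng: np.random.Generator) -> int:
    """Draw one trial outcome: 100 points with probability ``reward_prob`` else 0."""
    if not 0.0 <= reward_prob <= 1.0:
        raise ValueError(f"reward_prob must lie in [0, 1], got {reward_prob}")
    return POINTS_WIN if rng.random() < reward_prob else 0


# ---------------------------------------------------------------------------
# long-format trial table I/O

TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "block",
    "trial",
    "recipient",
    "side_of_high",
    "chosen_is_high",
    "outcome",
    "missed",
]


def trials_frame(records: Sequence[TrialRecord], group: str = "sim") -> pd.DataFrame:
    """Long-format trial table (one row per trial, outcomes in points)."""
    rows = [
        {
            "subject_id": t.subject_id,
            "group": group,
            "block": t.block_index,
            "trial": t.trial_index,
            "recipient": t.recipient.value,
            "side_of_high": t.side_of_high,
            "chosen_is_high": int(t.is_high_chosen),
            "outcome": t.outcome,
            "missed": int(t.missed),
        }
        for t in records
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def write_trials(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return frame
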