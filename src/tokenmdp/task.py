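"""Structure of the stochastic tokens task.

Monkeys (or simulated agents) choose between pairs of four cue images worth
(+2, +1, -1, -2) tokens.  A chosen cue's token change is delivered with
probability 0.75 (no change otherwise), the token count is floored at zero,
and every 4-6 trials all accumulated tokens are cashed out for juice, one
drop per token.  Blocks are 108 completed trials; the six unordered cue
pairs each appear 18 times, twice (once per side arrangement) in every
disjoint 12-trial window.

This module holds the task configuration, the block scheduler, the trial
record container, and the token/cash-out dynamics shared by the behavioral
simulator and the MDP transition model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np

__all__ = [
    "TaskConfig",
    "Schedule",
    "TrialRecord",
    "SessionData",
    "CONDITION_CUES",
    "build_schedule",
    "cashout_hazard",
    "apply_outcome",
]

#: Condition id (1-6) -> the pair of cue indices (0-based into cue_deltas).
#: Cues are ordered (+2, +1, -1, -2); conditions follow the convention
#: 1: +2 v +1, 2: +1 v -1, 3: +2 v -1, 4: +1 v -2, 5: +2 v -2, 6: -2 v -1.
CONDITION_CUES: dict[int, tuple[int, int]] = {
    1: (0, 1),
    2: (1, 2),
    3: (0, 2),
    4: (1, 3),
    5: (0, 3),
    6: (3, 2),
}


@dataclass(frozen=True)
class TaskConfig:
    """Fixed parameters of the tokens task.

    Defaults are the task as run: 108-trial blocks, six conditions seen 18
    times each, 75% outcome delivery, cash-out uniformly after 4-6 trials.
    """

    block_length: int = 108
    n_conditions: int = 6
    presentations_per_condition: int = 18
    outcome_deliver_prob: float = 0.75
    cue_deltas: tuple[int, ...] = (2, 1, -1, -2)
    cashout_support: tuple[int, ...] = (4, 5, 6)
    max_tokens: int = 12
    nobs_max: int = 18
    epoch_labels: tuple[str, ...] = (
        "fixation",
        "cond1", "cond2", "cond3", "cond4", "cond5", "cond6",
        "outcome",
        "cashout",
        "iti",
    )

    def __post_init__(self) -> None:
        if self.block_length != self.n_conditions * self.presentations_per_condition:
            raise ValueError(
                "block_length must equal n_conditions * presentations_per_condition"
            )
        if not (0.0 < self.outcome_deliver_prob <= 1.0):
            raise ValueError("outcome_deliver_prob must be in (0, 1]")
        if self.max_tokens != max(d for d in self.cue_deltas if d > 0) * max(
            self.cashout_support
        ):
            raise ValueError("max_tokens inconsistent with cue_deltas and cashout_support")

    @property
    def tsco_max(self) -> int:
        return max(self.cashout_support)

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_labels)

    def condition_pairs(self) -> dict[int, tuple[int, int]]:
        """Cue-index pairs per condition id.

        For the default four-cue task this is the standard six-condition
        convention; for reduced tasks (used in solver oracles) pairs are
        enumerated in lexicographic order.
        """
        if len(self.cue_deltas) == 4 and self.n_conditions == 6:
            return dict(CONDITION_CUES)
        pairs = list(combinations(range(len(self.cue_deltas)), 2))
        if len(pairs) < self.n_conditions:
            raise ValueError("not enough cue pairs for n_conditions")
        return {c + 1: pairs[c] for c in range(self.n_conditions)}


@dataclass(frozen=True)
class Schedule:
    """Ordered (condition id, side flag) assignments for one block.

    ``sides[t]`` is True when the lower-indexed cue of the pair is shown on
    the left on trial ``t``; the repeat of the same condition within a
    12-trial window uses the opposite arrangement.
    """

    conditions: tuple[int, ...]
    sides: tuple[bool, ...]

    def __len__(self) -> int:
        return len(self.conditions)


@dataclass
class TrialRecord:
    """One trial attempt (completed or aborted)."""

    block: int
    trial: int            # completed-trial index within block (0-based)
    attempt: int          # attempt index for this trial (0 = first)
    condition: int
    side_first_left: bool
    choice: Optional[int]  # cue index 0-3, None when aborted
    delivered: bool
    delta_tokens: int
    tokens_before: int
    tokens_after: int
    tsco: int
    cashout: bool
    juice_drops: int
    rt_fix: Optional[float]
    rt_choice: Optional[float]
    abort_code: str = "none"  # none | fixation_abort | choice_abort

    @property
    def completed(self) -> bool:
        return self.abort_code == "none"


@dataclass
class SessionData:
    """All trial attempts of one session, ordered, with identifiers."""

    records: list[TrialRecord] = field(default_factory=list)
    session_id: str = "session0"
    subject_id: str = "subject0"

    def completed_trials(self) -> list[TrialRecord]:
        return [r for r in self.records if r.completed]

    def n_blocks(self) -> int:
        return 0 if not self.records else max(r.block for r in self.records) + 1

    def block_records(self, block: int) -> list[TrialRecord]:
        return [r for r in self.records if r.block == block]


def build_schedule(config: TaskConfig, seed: int) -> Schedule:
    """Pseudorandom block schedule honoring the 12-trial balancing rule.

    Each disjoint 12-trial window contains every condition exactly twice
    with opposite side arrangements, so over the block each condition is
    seen 18 times, 9 per arrangement.
    """
    if config.block_length % (2 * config.n_conditions) != 0:
        raise ValueError("block_length must be divisible by 2 * n_conditions")
    rng = np.random.default_rng(seed)
    n_windows = config.block_length // (2 * config.n_conditions)
    conditions: list[int] = []
    sides: list[bool] = []
    for _ in range(n_windows):
        window = list(range(1, config.n_conditions + 1)) * 2
        rng.shuffle(window)
        first_seen: dict[int, bool] = {}
        for c in window:
            if c not in first_seen:
                side = bool(rng.integers(2))
                first_seen[c] = side
            else:
                side = not first_seen[c]
            conditions.append(c)
            sides.append(side)
    return Schedule(tuple(conditions), tuple(sides))


def cashout_hazard(tsco: int, support: tuple[int, ...] = (4, 5, 6)) -> float:
    """Conditional cash-out probability after the current trial's outcome.

    The cash-out interval is uniform on ``support``; the hazard at trial t
    is P(interval = t | interval >= t): 0 for TSCO 1-3, then 1/3, 1/2, 1.
    """
    if not (1 <= tsco <= max(support)):
        raise ValueError(f"tsco must be in [1, {max(support)}], got {tsco}")
    eligible = [s for s in support if s >= tsco]
    if tsco not in support:
        return 0.0
    return 1.0 / len(eligible)


def apply_outcome(tokens: int, delta: int, delivered: bool) -> int:
    """Token count after an outcome; undelivered outcomes change nothing
    and the count can never go below zero."""
    if tokens < 0:
        raise ValueError("tokens must be non-negative")
    if not delivered:
        return tokens
    return max(0, tokens + delta)
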