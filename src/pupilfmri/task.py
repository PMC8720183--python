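"""N-back session schedule construction and behavioral scoring.

The task session consists of eight 40-s blocks (two per condition:
fixation, 0-back, 1-back, 2-back) in a fixed order, each preceded by a
6-s instruction period and containing 16 letter trials at 2.5-s spacing
(500 ms stimulus + 2 s fixation cross).  Active blocks contain exactly
four targets (25%).  Letter identities are drawn by a seeded RNG subject
to the n-back constraints: a target letter equals the letter *n* steps
earlier, a non-target never does; in 0-back the target is the
prespecified letter ``W``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STIMULUS_SET = ("B", "C", "D", "G", "P", "T", "W")
ZERO_BACK_TARGET = "W"
FIXATION_LETTER = "X"

STIMULUS_DURATION = 0.5
TRIAL_DURATION = 2.5
INSTRUCTION_DURATION = 6.0
TRIALS_PER_BLOCK = 16
TARGETS_PER_BLOCK = 4
BLOCK_DURATION = TRIALS_PER_BLOCK * TRIAL_DURATION  # 40 s

#: response window: stimulus onset until 1,000 ms after stimulus offset
RESPONSE_WINDOW = STIMULUS_DURATION + 1.0  # 1.5 s

#: fixed block order (condition labels), first and second task half
BLOCK_ORDER = (
    "0-back", "2-back", "1-back", "fixation",
    "2-back", "1-back", "fixation", "0-back",
)


class Condition(enum.Enum):
    """Task condition; working-memory load is the n of n-back."""

    FIXATION = "fixation"
    ZERO_BACK = "0-back"
    ONE_BACK = "1-back"
    TWO_BACK = "2-back"

    @property
    def n_level(self) -> int | None:
        """Working-memory load; ``None`` for the fixation condition."""
        return {"0-back": 0, "1-back": 1, "2-back": 2}.get(self.value)

    @property
    def is_active(self) -> bool:
        return self is not Condition.FIXATION


ACTIVE_CONDITIONS = (Condition.ZERO_BACK, Condition.ONE_BACK, Condition.TWO_BACK)


@dataclass(frozen=True)
class Trial:
    onset: float
    letter: str
    is_target: bool
    condition: Condition
    stimulus_duration: float = STIMULUS_DURATION
    trial_duration: float = TRIAL_DURATION


@dataclass(frozen=True)
class Block:
    condition: Condition
    instruction_onset: float
    trials: tuple[Trial, ...]
    duration: float = BLOCK_DURATION

    @property
    def onset(self) -> float:
        return self.instruction_onset + INSTRUCTION_DURATION

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class TaskSchedule:
    blocks: tuple[Block, ...]
    stimulus_set: tuple[str, ...] = STIMULUS_SET

    @property
    def span(self) -> float:
        """End of the last block, in seconds from session start."""
        return self.blocks[-1].end

    def trials(self):
        for b, block in enumerate(self.blocks):
            for j, trial in enumerate(block.trials):
                yield b, j, trial

    def to_events(self) -> pd.DataFrame:
        """BIDS-style events table (one row per trial)."""
        rows = [
            {
                "onset": t.onset,
                "duration": t.trial_duration,
                "trial_type": t.condition.value,
                "letter": t.letter,
                "is_target": int(t.is_target),
                "block_index": b,
            }
            for b, _, t in self.trials()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ResponseLog:
    """Button-press timestamps, strictly increasing, in seconds."""

    presses: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.presses, dtype=float)
        if p.ndim != 1:
            raise ValueError("presses must be one-dimensional")
        if p.size and (np.any(p < 0) or np.any(np.diff(p) <= 0)):
            raise ValueError("press timestamps must be nonnegative and strictly increasing")
        object.__setattr__(self, "presses", p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"press_time": self.presses})


def _block_letters(condition: Condition, targets: np.ndarray, rng: np.random.Generator) -> list[str]:
    """Draw the 16 letters of one block honoring n-back target logic."""
    if condition is Condition.FIXATION:
        return [FIXATION_LETTER] * TRIALS_PER_BLOCK
    n = condition.n_level
    letters: list[str] = []
    for i in range(TRIALS_PER_BLOCK):
        if n == 0:
            if targets[i]:
                letters.append(ZERO_BACK_TARGET)
            else:
                pool = [c for c in STIMULUS_SET if c != ZERO_BACK_TARGET]
                letters.append(pool[rng.integers(len(pool))])
        else:
            if targets[i]:
                letters.append(letters[i - n])
            else:
                pool = list(STIMULUS_SET)
                if i >= n:
                    pool = [c for c in pool if c != letters[i - n]]
                letters.append(pool[rng.integers(len(pool))])
    return letters


def _target_positions(condition: Condition, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random target flags; n-back targets need n predecessors."""
    flags = np.zeros(TRIALS_PER_BLOCK, dtype=bool)
    if condition is Condition.FIXATION:
        return flags
    n = condition.n_level or 0
    eligible = np.arange(n, TRIALS_PER_BLOCK)
    chosen = rng.choice(eligible, size=TARGETS_PER_BLOCK, replace=False)
    flags[chosen] = True
    return flags


def build_schedule(seed: int, session_start: float = 0.0) -> TaskSchedule:
    """Build the full eight-block session; deterministic per seed.

    Parameters
    ----------
    seed : int
        RNG seed governing target positions and letter identities.
    session_start : float
        Time of the first instruction onset (default 0 s).
    """
    rng = np.random.default_rng(seed)
    blocks = []
    t = session_start
    for label in BLOCK_ORDER:
        condition = Condition(label)
        targets = _target_positions(condition, rng)
        letters = _block_letters(condition, targets, rng)
        onset = t + INSTRUCTION_DURATION
        trials = tuple(
            Trial(onset=onset + j * TRIAL_DURATION, letter=letters[j],
                  is_target=bool(targets[j]), condition=condition)
            for j in range(TRIALS_PER_BLOCK)
        )
        blocks.append(Block(condition=condition, instruction_onset=t, trials=trials))
        t = onset + BLOCK_DURATION
    return TaskSchedule(blocks=tuple(blocks))


def score_responses(schedule: TaskSchedule, log: ResponseLog) -> pd.DataFrame:
    """Label every active-condition trial hit/miss/false alarm/correct rejection.

    A press counts for a trial iff it falls in ``[onset, onset + 1.5)`` s
    (stimulus onset until 1 s after stimulus offset).  RT is press time
    minus onset, defined for hits and false alarms.  Presses matching no
    window (including during instruction periods) are ignored; fixation
    trials are excluded from scoring.
    """
    rows = []
    presses = log.presses
    prev_end = -np.inf
    for b, j, trial in schedule.trials():
        if not trial.condition.is_active:
            continue
        w0, w1 = trial.onset, trial.onset + RESPONSE_WINDOW
        # schedule construction guarantees disjoint response windows
        assert w0 >= prev_end, "overlapping response windows"
        prev_end = w1
        in_window = presses[(presses >= w0) & (presses < w1)]
        pressed = in_window.size > 0
        rt = float(in_window[0] - w0) if pressed else np.nan
        if trial.is_target:
            outcome = "hit" if pressed else "miss"
        else:
            outcome = "false_alarm" if pressed else "correct_rejection"
        rows.append({
            "block_index": b, "trial_index": j, "condition": trial.condition.value,
            "onset": trial.onset, "letter": trial.letter,
            "is_target": trial.is_target, "outcome": outcome, "rt": rt,
        })
    return pd.DataFrame(rows)


def summarize_behavior(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Per-condition accuracy and mean hit RT.

    Accuracy = (hits + correct rejections) / total trials of the
    condition.  Mean RT is over hits only and is NaN (flagged missing)
    for a condition without hits.
    """
    rows = []
    for condition, grp in outcomes.groupby("condition", sort=False):
        counts = grp["outcome"].value_counts()
        hits = int(counts.get("hit", 0))
        cr = int(counts.get("correct_rejection", 0))
        hit_rts = grp.loc[grp["outcome"] == "hit", "rt"]
        rows.append({
            "condition": condition,
            "n_trials": len(grp),
            "hits": hits,
            "misses": int(counts.get("miss", 0)),
            "false_alarms": int(counts.get("false_alarm", 0)),
            "correct_rejections": cr,
            "accuracy": (hits + cr) / len(grp),
            "mean_rt": float(hit_rts.mean()) if hits else np.nan,
        })
    return pd.DataFrame(rows)
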