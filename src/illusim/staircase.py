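"""Interleaved 1-up/1-down staircases on a fixed comparison-size grid.

Each experimental block measures one face orientation and runs four
concurrent staircases — ascending/descending crossed with eyeshadow
present/absent on the standard — randomly interleaved trial by trial.
A staircase moves the comparison eye size down one grid step after a
"comparison larger" response and up one step after a "standard larger"
response, so the presented levels converge on the comparison size judged
larger exactly half the time (the PSE).  A staircase terminates once its
movement direction has reversed a fixed number of times (six in the study
design); the levels at which it reversed are the raw material for PSE
estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .observers import COMPARATIVE_LARGER, STANDARD_LARGER

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "TrialRecord",
    "TrialTable",
    "update_staircase",
    "run_block",
    "run_experiment",
    "STAIRCASE_IDS",
]


class StaircaseUsageError(RuntimeError):
    """Raised when a terminated staircase receives another update."""


@dataclass(frozen=True)
class StaircaseConfig:
    """Grid and termination rules for one staircase.

    Defaults are the study protocol: comparison eye sizes from 92% to 108%
    of the original in 1% steps, ascending staircases starting at 92%,
    descending at 108%, termination after 6 direction reversals.
    ``max_trials`` is a safety cap absent from the protocol; hitting it is
    flagged on the state rather than silently accepted.
    """

    level_min: float = 92.0
    level_max: float = 108.0
    step: float = 1.0
    start_ascending: float = 92.0
    start_descending: float = 108.0
    reversal_criterion: int = 6
    max_trials: int = 200

    def __post_init__(self) -> None:
        if not self.level_min < self.level_max:
            raise ValueError("level_min must be < level_max")
        if not self.step > 0:
            raise ValueError("step must be > 0")
        span = (self.level_max - self.level_min) / self.step
        if abs(span - round(span)) > 1e-9:
            raise ValueError("(level_max - level_min) must be divisible by step")
        for name in ("start_ascending", "start_descending"):
            if not self._on_grid(getattr(self, name)):
                raise ValueError(f"{name} must lie on the level grid")
        if self.reversal_criterion < 1:
            raise ValueError("reversal_criterion must be >= 1")
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")

    def _on_grid(self, level: float) -> bool:
        if not (self.level_min - 1e-9 <= level <= self.level_max + 1e-9):
            return False
        k = (level - self.level_min) / self.step
        return abs(k - round(k)) < 1e-9

    @property
    def levels(self) -> np.ndarray:
        n = int(round((self.level_max - self.level_min) / self.step)) + 1
        return self.level_min + self.step * np.arange(n)


#: The four staircases of one block: (shadow flag, direction).
STAIRCASE_IDS: tuple[tuple[int, str], ...] = (
    (0, "ascending"),
    (0, "descending"),
    (1, "ascending"),
    (1, "descending"),
)


@dataclass
class StaircaseState:
    """Mutable state of one running staircase."""

    staircase_id: str
    shadow: int
    direction: str  # "ascending" | "descending" (starting direction label)
    current_level: float
    last_move: str = "none"  # "up" | "down" | "none"
    reversal_levels: list[float] = field(default_factory=list)
    trial_count: int = 0
    terminated: bool = False
    capped: bool = False  # True when ended by max_trials, not reversals

    @classmethod
    def start(cls, shadow: int, direction: str, config: StaircaseConfig
              ) -> "StaircaseState":
        level = (
            config.start_ascending
            if direction == "ascending"
            else config.start_descending
        )
        return cls(
            staircase_id=f"shadow{shadow}_{direction}",
            shadow=shadow,
            direction=direction,
            current_level=level,
        )


def update_staircase(
    state: StaircaseState, response: str, config: StaircaseConfig
) -> bool:
    """Apply one response to a staircase; return True if it was a reversal.

    "comparison larger" moves the level down one step, "standard larger"
    moves it up; a reversal is recorded — at the level presented on this
    trial — when the intended direction differs from the previous move.
    Levels clamp to the grid bounds; a clamped non-move still updates the
    movement direction but is not itself a reversal.  ``state`` is mutated
    in place.
    """
    if state.terminated:
        raise StaircaseUsageError(
            f"staircase {state.staircase_id} is already terminated"
        )
    if response not in (COMPARATIVE_LARGER, STANDARD_LARGER):
        raise ValueError(f"unknown response {response!r}")

    presented = state.current_level
    intended = "down" if response == COMPARATIVE_LARGER else "up"
    reversal = state.last_move != "none" and intended != state.last_move
    if reversal:
        state.reversal_levels.append(presented)

    if intended == "down":
        state.current_level = max(config.level_min, presented - config.step)
    else:
        state.current_level = min(config.level_max, presented + config.step)
    state.last_move = intended
    state.trial_count += 1

    if len(state.reversal_levels) >= config.reversal_criterion:
        state.terminated = True
    elif state.trial_count >= config.max_trials:
        state.terminated = True
        state.capped = True
    return reversal


@dataclass(frozen=True, slots=True)
class TrialRecord:
    """One logged trial of a block."""

    subject_id: str
    block: float  # orientation angle measured in this block
    staircase_id: str
    shadow: int
    direction: str
    trial_index: int  # presentation order within the block
    comparative_level: float
    standard_side: str  # "left" | "right" (metadata; no effect on response)
    response: str
    reversal: bool


class TrialTable:
    """Tidy log of simulated trials with design metadata.

    Thin container over the list of :class:`TrialRecord`; ``to_frame``
    materialises a pandas DataFrame for I/O and inspection.
    """

    COLUMNS = (
        "subject_id",
        "block",
        "staircase_id",
        "shadow",
        "direction",
        "trial_index",
        "comparative_level",
        "standard_side",
        "response",
        "reversal",
    )

    def __init__(self, records: Iterable[TrialRecord],
                 capped_staircases: Sequence[tuple[str, float, str]] = ()):
        self.records: list[TrialRecord] = list(records)
        #: (subject_id, angle, staircase_id) of staircases ended by the cap.
        self.capped_staircases = list(capped_staircases)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    r.subject_id, r.block, r.staircase_id, r.shadow,
                    r.direction, r.trial_index, r.comparative_level,
                    r.standard_side, r.response, r.reversal,
                )
                for r in self.records
            ],
            columns=self.COLUMNS,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialTable":
        missing = set(cls.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        records = [
            TrialRecord(
                subject_id=str(row.subject_id),
                block=float(row.block),
                staircase_id=str(row.staircase_id),
                shadow=int(row.shadow),
                direction=str(row.direction),
                trial_index=int(row.trial_index),
                comparative_level=float(row.comparative_level),
                standard_side=str(row.standard_side),
                response=str(row.response),
                reversal=bool(row.reversal),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(records)


def run_block(
    observer,
    angle: float,
    config: StaircaseConfig,
    rng: np.random.Generator,
    return_states: bool = False,
):
    """Run the four randomly interleaved staircases of one block.

    On each trial one of the live (non-terminated) staircases is chosen
    uniformly at random, the stimulus side is drawn uniformly, the
    observer responds, and the staircase updates.  The block ends when all
    four staircases have terminated.  Returns the list of
    :class:`TrialRecord`; with ``return_states=True`` also the final
    :class:`StaircaseState` objects.
    """
    states = [StaircaseState.start(s, d, config) for s, d in STAIRCASE_IDS]
    records: list[TrialRecord] = []
    trial_index = 0
    live = [st for st in states if not st.terminated]
    while live:
        st = live[int(rng.integers(len(live)))]
        level = st.current_level
        side = "left" if rng.random() < 0.5 else "right"
        response = observer.respond(st.shadow, angle, level, rng)
        reversal = update_staircase(st, response, config)
        records.append(
            TrialRecord(
                subject_id=observer.subject_id,
                block=angle,
                staircase_id=st.staircase_id,
                shadow=st.shadow,
                direction=st.direction,
                trial_index=trial_index,
                comparative_level=level,
                standard_side=side,
                response=response,
                reversal=reversal,
            )
        )
        trial_index += 1
        if st.terminated:
            live = [s for s in states if not s.terminated]
    if return_states:
        return records, states
    return records


def run_experiment(
    population: Sequence,
    angles: Sequence[float],
    config: StaircaseConfig,
    seed,
) -> TrialTable:
    """Simulate the full session for every observer in the population.

    Each subject runs one block per orientation, in a per-subject random
    order.  ``seed`` may be an int or a :class:`numpy.random.SeedSequence`;
    every subject gets an independent child stream so the run is
    reproducible as a whole and per subject.
    """
    if len(population) == 0 or len(angles) == 0:
        raise ValueError("population and angles must be non-empty")
    if len(set(float(a) for a in angles)) != len(angles):
        raise ValueError("angles must be unique")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    records: list[TrialRecord] = []
    capped: list[tuple[str, float, str]] = []
    for child, observer in zip(ss.spawn(len(population)), population):
        rng = np.random.default_rng(child)
        order = rng.permutation(len(angles))
        for idx in order:
            angle = float(angles[idx])
            block_records, states = run_block(
                observer, angle, config, rng, return_states=True
            )
            records.extend(block_records)
            capped.extend(
                (observer.subject_id, angle, st.staircase_id)
                for st in states
                if st.capped
            )
    return TrialTable(records, capped_staircases=capped)
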