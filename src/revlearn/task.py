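"""Probabilistic reversal learning (PRL) task: configuration, trial records, task rules.

The task has two nose-poke options.  One option is the "high" side and pays
reward with probability ``p_high`` (default 0.8); the other pays with
``p_low`` (default 0.2).  Outcomes are sampled independently on every trial.
After ``reversal_criterion`` consecutive responses at the high-probability
side (default 8), the contingencies swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .exceptions import ConfigError, DataError

#: Option codes used throughout the package.
LEFT: int = 0
RIGHT: int = 1
OPTIONS: tuple[int, int] = (LEFT, RIGHT)


def other_option(option: int) -> int:
    """Return the option code of the side not given."""
    return RIGHT if option == LEFT else LEFT


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the PRL task.

    Parameters
    ----------
    p_high, p_low
        Reward probability at the high- and low-probability option.
    reversal_criterion
        Number of consecutive responses at the high-probability option that
        triggers a contingency reversal.
    n_trials
        Trials per simulated session.  Sessions are fixed-length in trials;
        wall-clock session duration is not modeled.
    timeout_s
        Time-out duration after a lose trial, in seconds.  Metadata only.
    seed
        Optional RNG seed recorded with the config.
    """

    p_high: float = 0.8
    p_low: float = 0.2
    reversal_criterion: int = 8
    n_trials: int = 200
    timeout_s: float = 10.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_low <= self.p_high <= 1.0):
            raise ConfigError(
                f"require 0 <= p_low <= p_high <= 1, got p_low={self.p_low}, p_high={self.p_high}"
            )
        if self.reversal_criterion < 1:
            raise ConfigError(f"reversal_criterion must be >= 1, got {self.reversal_criterion}")
        if self.n_trials < 1:
            raise ConfigError(f"n_trials must be >= 1, got {self.n_trials}")


@dataclass(frozen=True)
class Trial:
    """One trial: 1-based index, choice, current high side, win/lose outcome."""

    t: int
    choice: int
    high_side: int
    outcome: int
    latency_s: Optional[float] = None


@dataclass
class Session:
    """An ordered sequence of trials plus task metadata.

    Trial data are stored as parallel integer arrays (``choices``,
    ``high_sides``, ``outcomes``) with option codes 0=left, 1=right and
    outcome codes 0=lose, 1=win.  ``latencies`` is an optional float array
    with NaN for absent values; the simulator never fills it.
    """

    choices: np.ndarray
    high_sides: np.ndarray
    outcomes: np.ndarray
    task: TaskConfig = field(default_factory=TaskConfig)
    latencies: Optional[np.ndarray] = None
    subject_id: str = ""
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=np.int64)
        self.high_sides = np.asarray(self.high_sides, dtype=np.int64)
        self.outcomes = np.asarray(self.outcomes, dtype=np.int64)
        n = len(self.choices)
        if len(self.high_sides) != n or len(self.outcomes) != n:
            raise DataError("choices, high_sides and outcomes must have equal length")
        if self.latencies is not None:
            self.latencies = np.asarray(self.latencies, dtype=float)
            if len(self.latencies) != n:
                raise DataError("latencies length mismatch")
        for name, arr in (("choices", self.choices), ("high_sides", self.high_sides),
                          ("outcomes", self.outcomes)):
            if n and not np.isin(arr, (0, 1)).all():
                bad = int(np.flatnonzero(~np.isin(arr, (0, 1)))[0])
                raise DataError(f"{name} must be 0/1; first bad value at trial {bad + 1}")

    @property
    def n_trials(self) -> int:
        return len(self.choices)

    def __len__(self) -> int:
        return self.n_trials

    @property
    def trials(self) -> list[Trial]:
        """Materialize the trial records as :class:`Trial` objects."""
        lat = self.latencies
        return [
            Trial(
                t=i + 1,
                choice=int(self.choices[i]),
                high_side=int(self.high_sides[i]),
                outcome=int(self.outcomes[i]),
                latency_s=None if lat is None or np.isnan(lat[i]) else float(lat[i]),
            )
            for i in range(self.n_trials)
        ]

    @classmethod
    def from_trials(cls, trials: Sequence[Trial], task: TaskConfig = TaskConfig(),
                    subject_id: str = "", condition_label: str = "") -> "Session":
        lat = [np.nan if tr.latency_s is None else tr.latency_s for tr in trials]
        latencies = np.asarray(lat) if any(not np.isnan(v) for v in lat) else None
        return cls(
            choices=np.array([tr.choice for tr in trials]),
            high_sides=np.array([tr.high_side for tr in trials]),
            outcomes=np.array([tr.outcome for tr in trials]),
            task=task,
            latencies=latencies,
            subject_id=subject_id,
            condition_label=condition_label,
        )

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)


def sample_outcome(choice: int, high_side: int, task: TaskConfig,
                   rng: np.random.Generator) -> int:
    """Sample a win (1) / lose (0) outcome for a choice.

    The outcome is 1 with probability ``p_high`` when the chosen option is the
    current high-probability side, else ``p_low``.  Draws are independent
    across calls ("independent sampling": the previous outcome never changes
    the odds of the next).
    """
    p = task.p_high if choice == high_side else task.p_low
    return int(rng.random() < p)


def advance_reversal_state(consecutive_count: int, choice: int, high_side: int,
                           task: TaskConfig) -> tuple[int, int, bool]:
    """Advance the reversal counter after one choice.

    The counter counts consecutive responses at the high-probability option,
    regardless of outcome.  A response at the low side resets it to zero.
    When it reaches ``reversal_criterion`` the contingencies reverse: the
    high side swaps and the counter resets.

    Returns
    -------
    (new_count, new_high_side, reversed)
    """
    if not (0 <= consecutive_count < task.reversal_criterion):
        raise DataError(
            f"consecutive_count must be in [0, {task.reversal_criterion}), got {consecutive_count}"
        )
    if choice != high_side:
        return 0, high_side, False
    count = consecutive_count + 1
    if count >= task.reversal_criterion:
        return 0, other_option(high_side), True
    return count, high_side, False
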