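"""Conventional behavioral measures of PRL performance.

Four session-level measures: number of reversals achieved, fraction of
rewarded trials, win-stay (fraction of win trials followed by the same
choice) and lose-switch (fraction of lose trials followed by the other
choice).  The final trial has no successor and is excluded from the
win-stay/lose-switch denominators; an empty denominator yields a missing
value (None), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import DataError
from .task import Session, advance_reversal_state


@dataclass(frozen=True)
class SessionMetrics:
    n_reversals: int
    reversals_per_100: float
    fraction_rewarded: float
    win_stay: Optional[float]
    lose_switch: Optional[float]
    n_trials: int


def count_reversals(session: Session) -> int:
    """Number of reversal events, obtained by replaying the task's reversal
    rule over the recorded choices.

    Raises :class:`DataError` if the recorded high-side sequence is
    inconsistent with the replay (corrupt or foreign data).
    """
    if session.n_trials == 0:
        return 0
    high = int(session.high_sides[0])
    count = 0
    n_rev = 0
    for t, (choice, stored_high) in enumerate(zip(session.choices.tolist(),
                                                  session.high_sides.tolist())):
        if stored_high != high:
            raise DataError(
                f"high_side at trial {t + 1} ({stored_high}) disagrees with replay ({high})"
            )
        count, high, reversed_ = advance_reversal_state(count, choice, high, session.task)
        if reversed_:
            n_rev += 1
    return n_rev


def fraction_rewarded(session: Session) -> float:
    """Proportion of win trials."""
    if session.n_trials == 0:
        raise DataError("empty session")
    return float(session.outcomes.mean())


def win_stay(session: Session) -> Optional[float]:
    """Fraction of win trials (with a successor) whose next choice repeats;
    None if no eligible win trials."""
    if session.n_trials < 2:
        return None
    wins = session.outcomes[:-1] == 1
    if not wins.any():
        return None
    stays = session.choices[1:] == session.choices[:-1]
    return float(stays[wins].mean())


def lose_switch(session: Session) -> Optional[float]:
    """Fraction of lose trials (with a successor) whose next choice differs;
    None if no eligible lose trials."""
    if session.n_trials < 2:
        return None
    losses = session.outcomes[:-1] == 0
    if not losses.any():
        return None
    switches = session.choices[1:] != session.choices[:-1]
    return float(switches[losses].mean())


def session_metrics(session: Session) -> SessionMetrics:
    """All conventional measures for one session."""
    n_rev = count_reversals(session)
    T = session.n_trials
    return SessionMetrics(
        n_reversals=n_rev,
        reversals_per_100=n_rev / T * 100.0,
        fraction_rewarded=fraction_rewarded(session),
        win_stay=win_stay(session),
        lose_switch=lose_switch(session),
        n_trials=T,
    )


def effect_size_z(treatment_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Z-score of a treatment effect against control variability:
    ``(mean_treatment - mean_control) / SD_control`` with the sample (n-1) SD.

    Note the asymmetry: the denominator is the control group's SD, so
    swapping the groups does not merely flip the sign.
    """
    c = np.asarray(control_values, dtype=float)
    t = np.asarray(treatment_values, dtype=float)
    if len(c) < 2:
        raise DataError("need >= 2 control values to define an SD")
    sd = c.std(ddof=1)
    if sd == 0.0:
        raise DataError("control SD is zero; effect size undefined")
    return float((t.mean() - c.mean()) / sd)
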