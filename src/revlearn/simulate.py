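"""Generative simulation of PRL sessions by RL agents.

``simulate_session`` runs one agent through the task; ``generate_cohort``
produces many sessions with per-session true parameters, either fixed or
drawn from the estimation priors (truncated to the inference grids).  The
cohort generator is the synthetic stand-in for a real multi-session dataset.

Reproducibility contract: one seeded RNG stream per session; the first draw
assigns the initial high-probability side (fair coin), then each trial draws
(choice, outcome) in that order.  Identical seeds give identical sessions.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .models import LEFT, RIGHT, MODEL_PARAMS, Params, check_model
from .task import Session, TaskConfig, advance_reversal_state, other_option


def simulate_session(model: str, params: Params, task: TaskConfig = TaskConfig(),
                     seed: int = 0, subject_id: str = "",
                     condition_label: str = "") -> Session:
    """Simulate one session of the PRL task by an RL agent.

    The agent chooses via the model's softmax rule, outcomes are Bernoulli
    draws at the task's reward probabilities, and the high-probability side
    reverses after ``task.reversal_criterion`` consecutive high-side
    responses.  Latencies are not simulated (left absent).
    """
    check_model(model)
    p = params.for_model(model)
    beta, pi = p.get("beta", 0.0), p.get("pi", 0.0)

    rng = np.random.default_rng(seed)
    high = int(rng.random() < 0.5)  # initial high side: seeded fair coin

    T = task.n_trials
    choices = np.empty(T, dtype=np.int64)
    highs = np.empty(T, dtype=np.int64)
    outcomes = np.empty(T, dtype=np.int64)

    q = [0.5, 0.5]
    gamma = 1.0
    prev_choice = -1
    count = 0
    for t in range(T):
        if model == "RANDOM":
            p_right = 0.5
        else:
            z = beta * (q[RIGHT] - q[LEFT])
            if prev_choice == RIGHT:
                z += pi
            elif prev_choice == LEFT:
                z -= pi
            p_right = 1.0 / (1.0 + math.exp(-z)) if z >= 0 else math.exp(z) / (1.0 + math.exp(z))
        choice = RIGHT if rng.random() < p_right else LEFT
        p_win = task.p_high if choice == high else task.p_low
        outcome = int(rng.random() < p_win)

        choices[t] = choice
        highs[t] = high
        outcomes[t] = outcome

        count, high, _ = advance_reversal_state(count, choice, high, task)

        rpe = outcome - q[choice]
        if model == "RW1":
            q[choice] += p["alpha"] * rpe
        elif model in ("RW2", "RW3"):
            rate = p["alpha_pos"] if outcome == 1 else p["alpha_neg"]
            q[choice] += rate * rpe
        elif model == "RW4":
            q[choice] += p["alpha"] * gamma * rpe
            gamma = (1.0 - p["eta"]) * gamma + p["eta"] * abs(rpe)
        prev_choice = choice

    return Session(choices=choices, high_sides=highs, outcomes=outcomes, task=task,
                   subject_id=subject_id, condition_label=condition_label)


def draw_params(model: str, priors, rng: np.random.Generator) -> Params:
    """Draw one parameter set for ``model`` from the priors, truncated to the
    inference grid support.  ``priors`` is a :class:`revlearn.inference.PriorSpec`."""
    values = {name: float(priors.sample(name, rng)) for name in MODEL_PARAMS[check_model(model)]}
    return Params(**values)


def generate_cohort(model: str, n_sessions: int,
                    param_source: Union[Params, str] = "prior",
                    task: TaskConfig = TaskConfig(), seed: int = 0,
                    priors=None) -> tuple[list[Session], pd.DataFrame]:
    """Generate a cohort of simulated sessions with recorded true parameters.

    Parameters
    ----------
    param_source
        Either a fixed :class:`Params` used for every session, or the string
        ``"prior"`` to draw each session's parameters independently from the
        estimation priors (truncated to the inference grids).
    priors
        A :class:`revlearn.inference.PriorSpec`; defaults to the package
        priors.  Only consulted in prior-draw mode.

    Returns
    -------
    (sessions, truth)
        ``truth`` is a DataFrame with session_id, model and one column per
        free parameter.
    """
    check_model(model)
    if n_sessions < 1:
        raise ConfigError(f"n_sessions must be >= 1, got {n_sessions}")
    master = np.random.default_rng(seed)
    if isinstance(param_source, str):
        if param_source != "prior":
            raise ConfigError(f"param_source must be Params or 'prior', got {param_source!r}")
        if priors is None:
            from .inference import PriorSpec
            priors = PriorSpec()
        param_sets = [draw_params(model, priors, master) for _ in range(n_sessions)]
    else:
        param_sets = [param_source] * n_sessions
    session_seeds = master.integers(0, 2**31, size=n_sessions)

    sessions: list[Session] = []
    rows = []
    for i, (ps, s) in enumerate(zip(param_sets, session_seeds)):
        sid = f"sim{i:04d}"
        sessions.append(simulate_session(model, ps, task, seed=int(s), subject_id=sid,
                                         condition_label=model))
        rows.append({"session_id": sid, "model": model, **ps.for_model(model)})
    return sessions, pd.DataFrame(rows)
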