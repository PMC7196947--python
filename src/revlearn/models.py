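"""Rescorla-Wagner Q-learning model family for two-option choice.

Five candidate models describe how an agent tracks the value ``Q`` of each
option and converts values into choice probabilities:

* ``RW1`` — single learning rate: ``Q_s <- Q_s + alpha * RPE``.
* ``RW2`` — separate learning rates for positive (win) and negative (lose)
  feedback, ``alpha_pos`` / ``alpha_neg``.
* ``RW3`` — RW2 plus a stickiness parameter ``pi`` that adds a bonus to the
  previously chosen option inside the softmax (perseveration if ``pi > 0``,
  alternation if ``pi < 0``).
* ``RW4`` — Rescorla-Wagner / Pearce-Hall hybrid: a fixed rate ``alpha`` is
  multiplied by a dynamic associability ``gamma`` that tracks the unsigned
  prediction error at rate ``eta``:
  ``Q_s <- Q_s + alpha * gamma * RPE``; ``gamma <- (1-eta)*gamma + eta*|RPE|``.
* ``RANDOM`` — coin-flip null, every choice has probability 0.5.

The reward prediction error is ``RPE = outcome - Q_chosen`` (outcome coded
1 for win, 0 for lose); only the chosen option's value is updated.  Choice
probabilities come from a softmax with inverse temperature ``beta``:
``p_right = exp(beta*Q_right + pi*phi_right) / sum(...)`` where ``phi`` is a
previous-choice indicator (the ``pi`` term exists only in RW3).  Both Q
values start at 0.5 and ``phi`` is zero for both options before the first
choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import ConfigError, DataError, ParameterError
from .task import LEFT, RIGHT, Session

#: Free-parameter names per model, in canonical order.
MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "RW1": ("alpha", "beta"),
    "RW2": ("alpha_pos", "alpha_neg", "beta"),
    "RW3": ("alpha_pos", "alpha_neg", "pi", "beta"),
    "RW4": ("alpha", "eta", "beta"),
    "RANDOM": (),
}

MODEL_NAMES: tuple[str, ...] = tuple(MODEL_PARAMS)

#: Parameters constrained to [0, 1] (learning rates and associability weight).
UNIT_INTERVAL_PARAMS = frozenset({"alpha", "alpha_pos", "alpha_neg", "eta"})


def check_model(model: str) -> str:
    if model not in MODEL_PARAMS:
        raise ConfigError(f"unknown model {model!r}; known: {', '.join(MODEL_PARAMS)}")
    return model


def n_free_params(model: str) -> int:
    """Number of free parameters (2/3/4/3/0 for RW1/RW2/RW3/RW4/RANDOM)."""
    return len(MODEL_PARAMS[check_model(model)])


@dataclass(frozen=True)
class Params:
    """A model's free parameters.  Only the fields a model lists are read."""

    alpha: Optional[float] = None
    alpha_pos: Optional[float] = None
    alpha_neg: Optional[float] = None
    pi: Optional[float] = None
    beta: Optional[float] = None
    eta: Optional[float] = None

    def for_model(self, model: str) -> dict[str, float]:
        """Return the parameter dict a model reads, validating it."""
        check_model(model)
        out: dict[str, float] = {}
        for name in MODEL_PARAMS[model]:
            value = getattr(self, name)
            if value is None:
                raise ParameterError(f"model {model} requires parameter {name!r}")
            value = float(value)
            if not math.isfinite(value):
                raise ParameterError(f"parameter {name!r} must be finite, got {value}")
            if name in UNIT_INTERVAL_PARAMS and not (0.0 <= value <= 1.0):
                raise ParameterError(f"parameter {name!r} must lie in [0, 1], got {value}")
            out[name] = value
        return out

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "Params":
        return cls(**d)


@dataclass
class AgentState:
    """Per-trial latent state of an agent: option values, previous-choice
    indicators, associability (RW4), and the last reward prediction error."""

    q: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    phi: np.ndarray = field(default_factory=lambda: np.zeros(2))
    gamma: float = 1.0
    last_rpe: float = 0.0

    @property
    def q_left(self) -> float:
        return float(self.q[LEFT])

    @property
    def q_right(self) -> float:
        return float(self.q[RIGHT])

    def copy(self) -> "AgentState":
        return AgentState(q=self.q.copy(), phi=self.phi.copy(),
                          gamma=self.gamma, last_rpe=self.last_rpe)


def initialize_state(model: str) -> AgentState:
    """Fresh agent state: Q = (0.5, 0.5), no previous choice, gamma = 1."""
    check_model(model)
    return AgentState()


def compute_rpe(outcome: int, q_chosen: float) -> float:
    """Reward prediction error: received outcome minus expected value."""
    return float(outcome) - float(q_chosen)


def update_values(state: AgentState, choice: int, outcome: int, params: Params,
                  model: str) -> AgentState:
    """Apply one trial's learning update in place and return the state.

    The chosen option's Q moves toward the outcome by the model's effective
    learning rate; the unchosen option retains its value.  ``phi`` is set to
    1 for the chosen and 0 for the unchosen option.  RW4 additionally decays
    associability ``gamma`` toward ``|RPE|`` at rate ``eta``.
    """
    p = params.for_model(model)
    rpe = compute_rpe(outcome, state.q[choice])
    if model == "RW1":
        state.q[choice] += p["alpha"] * rpe
    elif model in ("RW2", "RW3"):
        rate = p["alpha_pos"] if outcome == 1 else p["alpha_neg"]
        state.q[choice] += rate * rpe
    elif model == "RW4":
        state.q[choice] += p["alpha"] * state.gamma * rpe
        state.gamma = (1.0 - p["eta"]) * state.gamma + p["eta"] * abs(rpe)
    elif model == "RANDOM":
        pass  # the null model carries state but never learns
    state.phi[:] = 0.0
    state.phi[choice] = 1.0
    state.last_rpe = rpe
    return state


def _p_right(state: AgentState, params: Params, model: str) -> float:
    """Stable softmax probability of choosing right."""
    p = params.for_model(model)
    if model == "RANDOM":
        return 0.5
    z = p["beta"] * (state.q[RIGHT] - state.q[LEFT])
    if model == "RW3":
        z += p["pi"] * (state.phi[RIGHT] - state.phi[LEFT])
    # logistic of z, computed without overflow for large |z|
    if z >= 0.0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def choice_probabilities(state: AgentState, params: Params,
                         model: str) -> tuple[float, float]:
    """Return (p_left, p_right) for the next choice under the model."""
    pr = _p_right(state, params, model)
    return 1.0 - pr, pr


def session_loglik(session: Session, model: str, params: Params) -> float:
    """Log-likelihood of a session's recorded choices under a model.

    The latent state is advanced with the *recorded* choices and outcomes
    (not resampled), and the log-probability of each recorded choice under
    the pre-trial state is accumulated:
    ``sum_t log P(choice_t | state before trial t)``.
    The RANDOM model returns ``T * log(0.5)``.
    """
    check_model(model)
    if session.n_trials == 0:
        raise DataError("cannot score an empty session")
    if model == "RANDOM":
        return session.n_trials * math.log(0.5)
    p = params.for_model(model)  # validate once up front
    beta, pi = p["beta"], p.get("pi", 0.0)
    q = [0.5, 0.5]
    gamma = 1.0
    prev_choice = -1
    ll = 0.0
    for choice, outcome in zip(session.choices.tolist(), session.outcomes.tolist()):
        z = beta * (q[RIGHT] - q[LEFT])
        if prev_choice == RIGHT:
            z += pi
        elif prev_choice == LEFT:
            z -= pi
        if choice == LEFT:
            z = -z
        # log sigmoid(z), stable for large |z|
        ll += -math.log1p(math.exp(-z)) if z >= 0 else z - math.log1p(math.exp(z))
        rpe = outcome - q[choice]
        if model == "RW1":
            q[choice] += p["alpha"] * rpe
        elif model == "RW4":
            q[choice] += p["alpha"] * gamma * rpe
            gamma = (1.0 - p["eta"]) * gamma + p["eta"] * abs(rpe)
        else:
            rate = p["alpha_pos"] if outcome == 1 else p["alpha_neg"]
            q[choice] += rate * rpe
        prev_choice = choice
    return ll
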