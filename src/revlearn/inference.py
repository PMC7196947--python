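"""Maximum a posteriori (MAP) grid estimation of Q-learning parameters.

Per session and model, the posterior ``likelihood x prior`` is evaluated on
a dense rectangular parameter grid, normalized with uniform Riemann weights,
and each parameter is summarized by the mean of its marginal posterior
("integrating the posterior over the parameter's range, marginalized over
the other parameters").  Priors: learning rates and the associability weight
``eta`` are Beta(1.5, 1.5); stickiness ``pi`` is Normal(0.5, 0.5); inverse
temperature ``beta`` is Normal(2, 2) renormalized over its truncated grid
support [0, 10] (negative beta — anti-value-guided choice — is excluded).

The grid likelihood exploits the model structure: value trajectories depend
only on the learning parameters, so they are computed once per learning-rate
combination (vectorized over combinations) and the softmax terms are then
accumulated over the (beta, pi) axes via
``log p(choice_t) = -log1p(exp(-beta*dQ_t) * exp(-/+pi))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .exceptions import ConfigError, DataError, ParameterError
from .models import (LEFT, RIGHT, MODEL_PARAMS, Params, check_model,
                     n_free_params, session_loglik)
from .selection import compute_aic, compute_bic, random_choice_loglik
from .task import Session

#: Prior hyperparameters (field convention: normpdf(mean, SD)).
BETA_AB = (1.5, 1.5)          # learning rates, eta ~ Beta(1.5, 1.5)
PI_MEAN, PI_SD = 0.5, 0.5     # stickiness ~ Normal(0.5, 0.5)
B_MEAN, B_SD = 2.0, 2.0       # inverse temperature ~ Normal(2, 2), truncated


@dataclass(frozen=True)
class GridAxis:
    """A uniform grid over [lo, hi] with ``n`` points."""

    lo: float
    hi: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError(f"grid axis needs >= 2 points, got {self.n}")
        if not self.lo < self.hi:
            raise ConfigError(f"grid axis needs lo < hi, got [{self.lo}, {self.hi}]")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n)

    @property
    def spacing(self) -> float:
        return (self.hi - self.lo) / (self.n - 1)

    def refined(self, factor: int = 2) -> "GridAxis":
        return GridAxis(self.lo, self.hi, (self.n - 1) * factor + 1)


def _default_grids() -> dict[str, GridAxis]:
    rate = GridAxis(0.004, 0.996, 41)
    return {
        "alpha": rate,
        "alpha_pos": rate,
        "alpha_neg": rate,
        "eta": rate,
        "pi": GridAxis(-2.0, 3.0, 21),
        "beta": GridAxis(0.0, 10.0, 21),
    }


@dataclass(frozen=True)
class PriorSpec:
    """Prior densities and estimation grids for all free parameters.

    Grid ranges cover >= 99.9% of each prior's mass within plausible
    behavioral ranges; resolutions trade estimate precision against the cost
    of the (up to 4-D) grid and are configurable per parameter.
    """

    grids: dict[str, GridAxis] = field(default_factory=_default_grids)

    def axis(self, name: str) -> GridAxis:
        try:
            return self.grids[name]
        except KeyError:
            raise ConfigError(f"no grid defined for parameter {name!r}") from None

    def log_prior(self, name: str, values) -> np.ndarray:
        """Elementwise log prior density for one parameter.

        Returns -inf outside the parameter's support.  ``beta``'s normal
        density is renormalized over its truncated grid support.
        """
        x = np.asarray(values, dtype=float)
        if name in ("alpha", "alpha_pos", "alpha_neg", "eta"):
            return stats.beta.logpdf(x, *BETA_AB)
        if name == "pi":
            return stats.norm.logpdf(x, PI_MEAN, PI_SD)
        if name == "beta":
            ax = self.axis("beta")
            mass = stats.norm.cdf(ax.hi, B_MEAN, B_SD) - stats.norm.cdf(ax.lo, B_MEAN, B_SD)
            out = stats.norm.logpdf(x, B_MEAN, B_SD) - math.log(mass)
            return np.where((x >= ax.lo) & (x <= ax.hi), out, -np.inf)
        raise ConfigError(f"unknown parameter {name!r}")

    def sample(self, name: str, rng: np.random.Generator) -> float:
        """Draw one value from the prior truncated to the grid support
        (inverse-CDF sampling)."""
        ax = self.axis(name)
        if name in ("alpha", "alpha_pos", "alpha_neg", "eta"):
            dist = stats.beta(*BETA_AB)
        elif name == "pi":
            dist = stats.norm(PI_MEAN, PI_SD)
        elif name == "beta":
            dist = stats.norm(B_MEAN, B_SD)
        else:
            raise ConfigError(f"unknown parameter {name!r}")
        lo, hi = dist.cdf(ax.lo), dist.cdf(ax.hi)
        return float(dist.ppf(lo + (hi - lo) * rng.random()))


def evaluate_log_prior(params: Params, model: str, priors: PriorSpec) -> float:
    """Sum of per-parameter log prior densities for a model's free parameters."""
    total = 0.0
    for name, value in params.for_model(model).items():
        total += float(priors.log_prior(name, value))
    return total


@dataclass
class PosteriorGrid:
    """Log-posterior evaluated on the full parameter grid of one model.

    ``log_posterior`` holds unnormalized log density values (loglik + log
    prior) with one axis per free parameter in ``param_names`` order.
    ``log_cell`` is the log Riemann cell volume and ``log_norm`` the log
    normalizing constant, so that masses ``exp(log_posterior + log_cell -
    log_norm)`` sum to one.
    """

    model: str
    param_names: tuple[str, ...]
    axes: tuple[np.ndarray, ...]
    log_posterior: np.ndarray
    log_loglik: np.ndarray
    log_cell: float
    log_norm: float

    def masses(self) -> np.ndarray:
        return np.exp(self.log_posterior + self.log_cell - self.log_norm)


@dataclass(frozen=True)
class FitResult:
    """Per-session, per-model estimation summary."""

    model: str
    estimates: dict[str, float]
    max_loglik: float
    loglik_at_estimate: float
    aic: float
    bic: float
    n_trials: int


def _signed_dq_rw(session: Session, a_pos: np.ndarray, a_neg: np.ndarray) -> np.ndarray:
    """Pre-choice signed value difference Q_chosen - Q_unchosen per trial,
    vectorized over learning-rate combinations (RW1/RW2/RW3 family)."""
    C = len(a_pos)
    T = session.n_trials
    ql = np.full(C, 0.5)
    qr = np.full(C, 0.5)
    out = np.empty((C, T))
    for t, (choice, outcome) in enumerate(zip(session.choices.tolist(),
                                              session.outcomes.tolist())):
        d = qr - ql
        out[:, t] = d if choice == RIGHT else -d
        qc = qr if choice == RIGHT else ql
        rate = a_pos if outcome == 1 else a_neg
        qc += rate * (outcome - qc)
    return out


def _signed_dq_hybrid(session: Session, alpha: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Same as :func:`_signed_dq_rw` for the Pearce-Hall hybrid (RW4)."""
    C = len(alpha)
    T = session.n_trials
    ql = np.full(C, 0.5)
    qr = np.full(C, 0.5)
    gamma = np.ones(C)
    out = np.empty((C, T))
    for t, (choice, outcome) in enumerate(zip(session.choices.tolist(),
                                              session.outcomes.tolist())):
        d = qr - ql
        out[:, t] = d if choice == RIGHT else -d
        qc = qr if choice == RIGHT else ql
        rpe = outcome - qc
        qc += alpha * gamma * rpe
        gamma *= 1.0 - eta
        gamma += eta * np.abs(rpe)
    return out


def _phi_sign(session: Session) -> np.ndarray:
    """Per trial: +1 if the previous choice equals the current choice, -1 if
    it differs, 0 on the first trial (no previous choice)."""
    c = session.choices
    s = np.zeros(session.n_trials, dtype=np.int64)
    if session.n_trials > 1:
        s[1:] = np.where(c[1:] == c[:-1], 1, -1)
    return s


def _loglik_kernel(dq: np.ndarray, phi_sign: np.ndarray, betas: np.ndarray,
                   pis: np.ndarray) -> np.ndarray:
    """Accumulate sum_t log sigmoid(beta*dq_t + pi*phi_sign_t) over a
    (combination, beta, pi) grid.  Returns shape (C, n_beta, n_pi).

    Uses exp(-z) factorization: exp(-(beta*dq + pi*s)) =
    exp(-beta*dq) * exp(-pi*s); grid bounds keep both factors well inside
    float range (|beta*dq| <= 10, |pi| <= 3).
    """
    C, T = dq.shape
    E = np.exp(-dq[:, :, None] * betas[None, None, :])        # (C, T, B)
    e_pos = np.exp(-pis)                                      # s = +1
    e_neg = np.exp(pis)                                       # s = -1
    ones = np.ones_like(pis)
    ll = np.zeros((C, len(betas), len(pis)))
    # sum_t log(1 + w_t) == log prod_t (1 + w_t); fold the product over short
    # blocks and take one log per block.  Each factor is <= 1 + e^10 * e^3,
    # so 32-trial blocks stay far below float64 overflow.
    acc = np.ones_like(ll)
    for t in range(T):
        s = phi_sign[t]
        f = e_pos if s == 1 else (e_neg if s == -1 else ones)
        acc *= 1.0 + E[:, t, :, None] * f[None, None, :]
        if (t + 1) % 32 == 0:
            ll -= np.log(acc)
            acc[:] = 1.0
    ll -= np.log(acc)
    return ll


def grid_loglik(session: Session, model: str, priors: PriorSpec
                ) -> tuple[tuple[str, ...], tuple[np.ndarray, ...], np.ndarray]:
    """Session log-likelihood on the model's full parameter grid.

    Returns (param_names, axes, loglik) with ``loglik`` shaped by the axes in
    canonical parameter order.
    """
    check_model(model)
    names = MODEL_PARAMS[model]
    if model == "RANDOM":
        raise ConfigError("RANDOM has no parameters; use random_choice_loglik")
    axes = tuple(priors.axis(n).values for n in names)
    betas = priors.axis("beta").values
    phs = _phi_sign(session)
    if model == "RW1":
        a = priors.axis("alpha").values
        dq = _signed_dq_rw(session, a, a)
        ll = _loglik_kernel(dq, phs, betas, np.zeros(1))[:, :, 0]      # (alpha, beta)
    elif model == "RW2":
        ap = priors.axis("alpha_pos").values
        an = priors.axis("alpha_neg").values
        AP, AN = np.meshgrid(ap, an, indexing="ij")
        dq = _signed_dq_rw(session, AP.ravel(), AN.ravel())
        ll = _loglik_kernel(dq, phs, betas, np.zeros(1))[:, :, 0]
        ll = ll.reshape(len(ap), len(an), len(betas))                  # (a+, a-, beta)
    elif model == "RW3":
        ap = priors.axis("alpha_pos").values
        an = priors.axis("alpha_neg").values
        pis = priors.axis("pi").values
        AP, AN = np.meshgrid(ap, an, indexing="ij")
        dq = _signed_dq_rw(session, AP.ravel(), AN.ravel())
        ll = _loglik_kernel(dq, phs, betas, pis)
        ll = ll.reshape(len(ap), len(an), len(betas), len(pis))
        ll = np.moveaxis(ll, 2, 3)                                     # (a+, a-, pi, beta)
    elif model == "RW4":
        al = priors.axis("alpha").values
        et = priors.axis("eta").values
        A, H = np.meshgrid(al, et, indexing="ij")
        dq = _signed_dq_hybrid(session, A.ravel(), H.ravel())
        ll = _loglik_kernel(dq, phs, betas, np.zeros(1))[:, :, 0]
        ll = ll.reshape(len(al), len(et), len(betas))                  # (alpha, eta, beta)
    return names, axes, ll


def evaluate_posterior_grid(session: Session, model: str,
                            priors: Optional[PriorSpec] = None) -> PosteriorGrid:
    """Evaluate log(likelihood x prior) at every node of the model's grid.

    A zero-trial session has likelihood one everywhere, so the posterior
    reduces to the (gridded) prior.
    """
    priors = priors or PriorSpec()
    check_model(model)
    if model == "RANDOM":
        raise ConfigError("RANDOM has no parameters to estimate")
    names = MODEL_PARAMS[model]
    for n in names:
        priors.axis(n)  # raises ConfigError early on a missing/degenerate axis
    if session.n_trials == 0:
        axes = tuple(priors.axis(n).values for n in names)
        ll = np.zeros(tuple(len(a) for a in axes))
    else:
        names, axes, ll = grid_loglik(session, model, priors)
    log_post = ll.copy()
    for i, n in enumerate(names):
        shape = [1] * len(names)
        shape[i] = len(axes[i])
        log_post = log_post + priors.log_prior(n, axes[i]).reshape(shape)
    log_cell = float(sum(math.log(priors.axis(n).spacing) for n in names))
    log_norm = float(logsumexp(log_post)) + log_cell
    return PosteriorGrid(model=model, param_names=names, axes=axes,
                         log_posterior=log_post, log_loglik=ll,
                         log_cell=log_cell, log_norm=log_norm)


def estimate_parameters(grid: PosteriorGrid) -> dict[str, float]:
    """Marginal-posterior-mean point estimate for each parameter."""
    m = grid.masses()
    out: dict[str, float] = {}
    for i, name in enumerate(grid.param_names):
        marg = m.sum(axis=tuple(j for j in range(m.ndim) if j != i))
        out[name] = float(np.dot(marg, grid.axes[i]))
    return out


def fit_session(session: Session, model: str,
                priors: Optional[PriorSpec] = None) -> FitResult:
    """Fit one model to one session: grid posterior, marginal-mean estimates,
    maximum grid log-likelihood, AIC and BIC.

    AIC/BIC use the *maximum* log-likelihood over the grid (the prior plays
    no role in the penalized criteria); the likelihood at the marginal-mean
    estimate is stored separately for diagnostics.  The RANDOM model bypasses
    the grid entirely.
    """
    check_model(model)
    if session.n_trials == 0:
        raise DataError("cannot fit an empty session")
    T = session.n_trials
    k = n_free_params(model)
    if model == "RANDOM":
        ll = random_choice_loglik(T)
        return FitResult(model=model, estimates={}, max_loglik=ll,
                         loglik_at_estimate=ll, aic=compute_aic(ll, 0),
                         bic=compute_bic(ll, 0, T), n_trials=T)
    priors = priors or PriorSpec()
    grid = evaluate_posterior_grid(session, model, priors)
    estimates = estimate_parameters(grid)
    max_ll = float(grid.log_loglik.max())
    ll_at_est = session_loglik(session, model, Params(**estimates))
    return FitResult(model=model, estimates=estimates, max_loglik=max_ll,
                     loglik_at_estimate=ll_at_est, aic=compute_aic(max_ll, k),
                     bic=compute_bic(max_ll, k, T), n_trials=T)


def fit_cohort(sessions, models, priors: Optional[PriorSpec] = None,
               ) -> list[tuple[str, FitResult]]:
    """Fit every model to every session; returns (session_id, FitResult)
    pairs in session-major order."""
    priors = priors or PriorSpec()
    out = []
    for i, s in enumerate(sessions):
        sid = s.subject_id or f"s{i:04d}"
        for m in models:
            out.append((sid, fit_session(s, m, priors)))
    return out
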