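"""Penalized model comparison and random-effects Bayesian model selection.

Per-session evidence is summarized by the Akaike information criterion
``AIC = 2k - 2 logL`` (or BIC) and converted to a log model-evidence proxy
``-AIC/2``.  Group-level selection treats each session's generating model as
drawn from unknown population frequencies ``r`` with a Dirichlet prior and
uses the variational scheme of Rigoux et al. (2014):

* responsibilities ``u_nk \\propto exp(ev_nk + psi(alpha_k) - psi(sum alpha))``,
* concentration updates ``alpha_k = alpha0 + sum_n u_nk``,

iterated to convergence.  The exceedance probability (EP) of model k is the
posterior probability that ``r_k`` is the largest frequency, estimated from
seeded Dirichlet Monte Carlo draws.  The Bayes omnibus risk (BOR) is the
posterior probability of the null that all models are equally frequent,
computed from the variational free energy of the random-effects model
against the null evidence ``sum_n logsumexp_k(ev_nk - log K)``.  The
protected exceedance probability is ``PXP_k = EP_k (1 - BOR) + BOR / K``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import digamma, expit, gammaln, logsumexp, xlogy

from .exceptions import ConfigError


def compute_aic(loglik: float, k: int) -> float:
    """Akaike information criterion: 2k - 2 logL."""
    if k < 0:
        raise ConfigError(f"parameter count must be >= 0, got {k}")
    return 2.0 * k - 2.0 * loglik


def compute_bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion: -2 logL + k log(n)."""
    if k < 0:
        raise ConfigError(f"parameter count must be >= 0, got {k}")
    if n < 1:
        raise ConfigError(f"trial count must be >= 1, got {n}")
    return -2.0 * loglik + k * math.log(n)


def random_choice_loglik(n: int) -> float:
    """Log-likelihood of the coin-flip null: n * log(0.5).

    ``n = 0`` returns 0 (empty product); negative counts are rejected.
    """
    if n < 0:
        raise ConfigError(f"trial count must be >= 0, got {n}")
    return n * math.log(0.5)


def aic_to_evidence(aic: float) -> float:
    """Log model-evidence proxy from an information criterion: -aic/2."""
    return -0.5 * aic


@dataclass
class BMSResult:
    """Random-effects model-selection summary.

    Attributes
    ----------
    dirichlet_alpha
        Posterior Dirichlet concentration per model.
    expected_freq
        Posterior expected model frequencies (sums to 1).
    ep
        Exceedance probability per model (Monte Carlo estimate).
    bor
        Bayes omnibus risk: posterior probability of equal frequencies.
    pxp
        Protected exceedance probability: ``ep*(1-bor) + bor/K``.
    """

    models: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray
    ep: np.ndarray
    bor: float
    pxp: np.ndarray
    converged: bool
    n_iter: int
    seed: int
    n_mc: int

    def best(self) -> str:
        return self.models[int(np.argmax(self.pxp))]


def _free_energy(ev: np.ndarray, u: np.ndarray, alpha: np.ndarray,
                 alpha0: np.ndarray) -> float:
    """Variational free energy of the random-effects model (lower bound on
    the log evidence of the frequency model)."""
    psi_t = digamma(alpha) - digamma(alpha.sum())
    f = float((u * ev).sum() + (u * psi_t).sum() - xlogy(u, u).sum())
    # E_q[log p(r)] under the Dirichlet prior
    f += float(gammaln(alpha0.sum()) - gammaln(alpha0).sum()
               + ((alpha0 - 1.0) * psi_t).sum())
    # - E_q[log q(r)]
    f -= float(gammaln(alpha.sum()) - gammaln(alpha).sum()
               + ((alpha - 1.0) * psi_t).sum())
    return f


def rfx_bms(evidence: np.ndarray, alpha0: float = 1.0, seed: int = 0,
            n_mc: int = 1_000_000, max_iter: int = 500, tol: float = 1e-6,
            models: Optional[Sequence[str]] = None) -> BMSResult:
    """Random-effects Bayesian model selection over a (sessions x models)
    log-evidence matrix.

    A single-model input returns the trivial EP = PXP = 1.  Non-convergence
    within ``max_iter`` is flagged on the result, not raised.
    """
    ev = np.asarray(evidence, dtype=float)
    if ev.ndim != 2 or ev.shape[0] < 1:
        raise ConfigError("evidence must be a (sessions x models) matrix")
    if not np.isfinite(ev).all():
        raise ConfigError("evidence entries must be finite")
    N, K = ev.shape
    names = tuple(models) if models is not None else tuple(f"M{i+1}" for i in range(K))
    if len(names) != K:
        raise ConfigError("model-name list length must match evidence columns")
    if K == 1:
        one = np.ones(1)
        return BMSResult(models=names, dirichlet_alpha=np.array([alpha0 + N]),
                         expected_freq=one, ep=one.copy(), bor=0.0, pxp=one.copy(),
                         converged=True, n_iter=0, seed=seed, n_mc=0)

    a0 = np.full(K, float(alpha0))
    alpha = a0.copy()
    u = np.full((N, K), 1.0 / K)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = ev + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        w -= w.max(axis=1, keepdims=True)
        u = np.exp(w)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = a0 + u.sum(axis=0)
        if np.abs(alpha_new - alpha).max() < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new

    expected_freq = alpha / alpha.sum()

    # EP by seeded Dirichlet Monte Carlo (argmax ties have probability zero)
    rng = np.random.default_rng(seed)
    ep = np.zeros(K)
    chunk = 200_000
    left = n_mc
    while left > 0:
        m = min(chunk, left)
        draws = rng.dirichlet(alpha, size=m)
        ep += np.bincount(np.argmax(draws, axis=1), minlength=K)
        left -= m
    ep /= n_mc

    # BOR: RFX free energy vs. the fixed equal-frequency null
    f_rfx = _free_energy(ev, u, alpha, a0)
    f_null = float(np.sum(logsumexp(ev - math.log(K), axis=1)))
    bor = float(expit(f_null - f_rfx))

    pxp = ep * (1.0 - bor) + bor / K
    return BMSResult(models=names, dirichlet_alpha=alpha, expected_freq=expected_freq,
                     ep=ep, bor=bor, pxp=pxp, converged=converged, n_iter=n_iter,
                     seed=seed, n_mc=n_mc)
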