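"""Brute-force exact posterior at small taxon counts.

Enumerates all ``2^m`` mode configurations of a single sample and computes
the exact posterior over configurations, the exact posterior mean
composition, and the exact log marginal likelihood.  Serves as the ground
truth against which the variational approximation is checked in tests; it is
not an inference path for real data (the enumeration refuses ``m > 15``).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.special import gammaln, logsumexp, xlogy

from .containers import Hyperparams

__all__ = [
    "ExactPosterior",
    "dirichlet_multinomial_logpmf",
    "exact_posterior",
    "exact_mode_marginals",
]

_ENUM_CAP = 15


@dataclass
class ExactPosterior:
    """Exact single-sample posterior over the ``2^m`` mode configurations."""

    delta_probs: np.ndarray
    mean_composition: np.ndarray
    log_marginal: float


def dirichlet_multinomial_logpmf(W_row: np.ndarray, theta: np.ndarray) -> float:
    """Log pmf of the Dirichlet-multinomial (multinomial-Dirichlet marginal).

    ``log [ N! / prod W_j! * Gamma(sum theta) / Gamma(N + sum theta)
            * prod Gamma(W_j + theta_j) / Gamma(theta_j) ]``
    """
    W_row = np.asarray(W_row, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if W_row.shape != theta.shape or W_row.ndim != 1:
        raise ValueError("W_row and theta must be 1-D of equal length")
    if (theta <= 0).any():
        raise ValueError("theta must be strictly positive")
    if (W_row < 0).any() or not np.allclose(W_row, np.round(W_row)):
        raise ValueError("W_row must contain nonnegative integers")
    N = W_row.sum()
    T = theta.sum()
    return float(
        gammaln(N + 1.0)
        - gammaln(W_row + 1.0).sum()
        + gammaln(T)
        - gammaln(N + T)
        + (gammaln(W_row + theta) - gammaln(theta)).sum()
    )


def exact_posterior(W_row: np.ndarray, hp: Hyperparams) -> ExactPosterior:
    """Exact posterior of one sample by enumerating mode configurations.

    ``p(delta | W) \\propto prod_j pi_j^{delta_j} (1-pi_j)^{1-delta_j}
    * DM(W | theta(delta))`` with ``theta_j(delta) = alpha1_j`` when
    ``delta_j = 1`` else ``alpha0_j``.  The posterior mean composition
    averages the conditional Dirichlet means ``(W + theta)/(N + sum theta)``
    over configurations.
    """
    W_row = np.asarray(W_row, dtype=float)
    m = W_row.shape[0]
    if hp.n_taxa != m:
        raise ValueError("hyperparameter length does not match W_row")
    if m > _ENUM_CAP:
        raise ValueError(
            f"exact enumeration supports at most {_ENUM_CAP} taxa (got {m}); "
            "use the variational fit for larger problems"
        )
    N = W_row.sum()
    log_joint = np.empty(2**m)
    means = np.empty((2**m, m))
    for idx, bits in enumerate(product((0, 1), repeat=m)):
        delta = np.asarray(bits, dtype=float)
        theta = np.where(delta == 1, hp.alpha1, hp.alpha0)
        log_prior = (xlogy(delta, hp.pi) + xlogy(1.0 - delta, 1.0 - hp.pi)).sum()
        log_joint[idx] = log_prior + dirichlet_multinomial_logpmf(W_row, theta)
        means[idx] = (W_row + theta) / (N + theta.sum())
    log_marginal = float(logsumexp(log_joint))
    probs = np.exp(log_joint - log_marginal)
    probs /= probs.sum()
    return ExactPosterior(
        delta_probs=probs,
        mean_composition=probs @ means,
        log_marginal=log_marginal,
    )


def exact_mode_marginals(W_row: np.ndarray, hp: Hyperparams) -> np.ndarray:
    """Exact per-taxon posterior probabilities ``P(delta_j = 1 | W)``."""
    post = exact_posterior(W_row, hp)
    m = np.asarray(W_row).shape[0]
    bits = np.array(list(product((0, 1), repeat=m)), dtype=float)
    return post.delta_probs @ bits
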