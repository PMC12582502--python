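"""Variational EM for the bimodal-Dirichlet multinomial model.

Generative model, per sample ``i`` with depth ``N_i``::

    delta_ij ~ Bernoulli(pi_j)                    (mode indicator, per taxon)
    theta_ij = alpha1_j if delta_ij else alpha0_j
    X_i      ~ Dirichlet(theta_i1, ..., theta_im)  (true composition)
    W_i      ~ Multinomial(N_i, X_i)               (observed counts)

The posterior over ``(X, delta)`` is approximated by the mean field
``Dirichlet(beta_i) x prod_j Bernoulli(gamma_ij)``.  The E-step alternates a
closed-form Dirichlet update ``beta = W + gamma*alpha1 + (1-gamma)*alpha0``
with cyclic responsibility updates across taxa; the M-step updates ``pi`` in
closed form and ``alpha`` by bound-constrained quasi-Newton maximisation of
the Jensen-bounded objective.  Expectations of ``log Gamma`` of a sum of
two-point concentrations are intractable, so both the monitored objective and
the M-step replace them with Jensen lower bounds (log-gamma is convex); the
responsibility update uses the tighter bound conditioned on the taxon being
updated.

A per-coordinate safeguard accepts a responsibility move only when it does
not decrease the monitored surrogate objective, which makes the recorded
objective trace non-decreasing by construction.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import optimize
from scipy.special import digamma, expit, gammaln, logit, xlogy

from .containers import CountMatrix, FitConfig, Hyperparams, VariationalState

__all__ = [
    "update_beta",
    "h_value",
    "update_gamma",
    "update_pi",
    "alpha_objective",
    "update_alpha",
    "surrogate_elbo",
    "estep",
    "fit",
]

logger = logging.getLogger(__name__)

_PI_CEIL = 1.0 - 1e-8


def _validate_hp_len(hp: Hyperparams, m: int) -> None:
    if hp.n_taxa != m:
        raise ValueError(f"hyperparameters have {hp.n_taxa} taxa, data have {m}")


def update_beta(W_row: np.ndarray, gamma_row: np.ndarray, hp: Hyperparams) -> np.ndarray:
    """Closed-form Dirichlet update ``beta_j = W_j + g_j*a1_j + (1-g_j)*a0_j``."""
    W_row = np.asarray(W_row, dtype=float)
    gamma_row = np.asarray(gamma_row, dtype=float)
    if W_row.shape != gamma_row.shape or W_row.ndim != 1:
        raise ValueError("W_row and gamma_row must be 1-D of equal length")
    _validate_hp_len(hp, W_row.shape[0])
    if not (np.isfinite(W_row).all() and np.isfinite(gamma_row).all()):
        raise ValueError("inputs must be finite")
    return W_row + gamma_row * hp.alpha1 + (1.0 - gamma_row) * hp.alpha0


def _mixture_alpha(gamma: np.ndarray, hp: Hyperparams) -> np.ndarray:
    """Responsibility-weighted concentration ``g*a1 + (1-g)*a0``."""
    return gamma * hp.alpha1 + (1.0 - gamma) * hp.alpha0


def h_value(
    j: int,
    d: int,
    beta_row: np.ndarray,
    gamma_row: np.ndarray,
    hp: Hyperparams,
) -> float:
    """Jensen-bounded log evidence for mode ``d`` of taxon ``j`` in one sample.

    ``h_j(d) = lgamma(a_{j,d} + sum_{k != j} [g_k a1_k + (1-g_k) a0_k])
              + (a_{j,d} - 1) (psi(beta_j) - psi(sum_k beta_k))
              - lgamma(a_{j,d})``
    """
    beta_row = np.asarray(beta_row, dtype=float)
    gamma_row = np.asarray(gamma_row, dtype=float)
    m = beta_row.shape[0]
    _validate_hp_len(hp, m)
    if (beta_row <= 0).any():
        raise ValueError("beta_row must be strictly positive")
    if ((gamma_row < 0) | (gamma_row > 1)).any():
        raise ValueError("gamma_row must lie in [0, 1]")
    if d not in (0, 1):
        raise ValueError("mode d must be 0 or 1")
    a_jd = float((hp.alpha1 if d == 1 else hp.alpha0)[j])
    mix = _mixture_alpha(gamma_row, hp)
    rest = float(mix.sum() - mix[j])
    e_logx = digamma(beta_row[j]) - digamma(beta_row.sum())
    return float(gammaln(a_jd + rest) + (a_jd - 1.0) * e_logx - gammaln(a_jd))


def update_gamma(
    j: int,
    beta_row: np.ndarray,
    gamma_row: np.ndarray,
    hp: Hyperparams,
) -> float:
    """One responsibility update: ``logistic(h(1) - h(0) + logit(pi_j))``.

    ``pi_j = 0`` forces the responsibility to 0 (no prior mass on the high
    mode).  Computed in the log domain for stability.
    """
    pi_j = float(hp.pi[j])
    if pi_j == 0.0:
        return 0.0
    dh = h_value(j, 1, beta_row, gamma_row, hp) - h_value(j, 0, beta_row, gamma_row, hp)
    return float(expit(dh + logit(min(pi_j, _PI_CEIL))))


def update_pi(gamma: np.ndarray) -> np.ndarray:
    """M-step for the mode probabilities: column means of the responsibilities."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 2 or gamma.shape[0] == 0:
        raise ValueError("gamma must be a nonempty matrix")
    if ((gamma < 0) | (gamma > 1)).any():
        raise ValueError("gamma must lie in [0, 1]")
    return np.clip(gamma.mean(axis=0), 0.0, _PI_CEIL)


def alpha_objective(
    alpha0: np.ndarray,
    alpha1: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
) -> float:
    """M-step objective for the concentration modes (Jensen lower bound).

    ``sum_i lgamma(sum_j abar_ij)
      + sum_ij [(abar_ij - 1)(psi(beta_ij) - psi(sum_j beta_ij))
                - g_ij lgamma(a1_j) - (1 - g_ij) lgamma(a0_j)]``
    with ``abar_ij = g_ij a1_j + (1 - g_ij) a0_j``.
    """
    alpha0 = np.asarray(alpha0, dtype=float)
    alpha1 = np.asarray(alpha1, dtype=float)
    if (alpha0 <= 0).any() or (alpha1 <= 0).any():
        raise ValueError("alpha modes must be strictly positive")
    gamma = np.asarray(gamma, dtype=float)
    beta = np.asarray(beta, dtype=float)
    abar = gamma * alpha1 + (1.0 - gamma) * alpha0
    e_logx = digamma(beta) - digamma(beta.sum(axis=1, keepdims=True))
    val = gammaln(abar.sum(axis=1)).sum()
    val += ((abar - 1.0) * e_logx).sum()
    val -= (gamma * gammaln(alpha1)).sum() + ((1.0 - gamma) * gammaln(alpha0)).sum()
    return float(val)


def _alpha_objective_grad(
    alpha0: np.ndarray,
    alpha1: np.ndarray,
    gamma: np.ndarray,
    e_logx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    abar = gamma * alpha1 + (1.0 - gamma) * alpha0
    psi_A = digamma(abar.sum(axis=1))[:, None]
    g1 = (gamma * (psi_A + e_logx)).sum(axis=0) - gamma.sum(axis=0) * digamma(alpha1)
    w0 = 1.0 - gamma
    g0 = (w0 * (psi_A + e_logx)).sum(axis=0) - w0.sum(axis=0) * digamma(alpha0)
    return g0, g1


def update_alpha(
    gamma: np.ndarray,
    beta: np.ndarray,
    hp_init: Hyperparams,
    cfg: FitConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximise :func:`alpha_objective` by L-BFGS-B in log-alpha.

    Warm-started at ``hp_init``; guaranteed not to return a point with a
    worse objective than the warm start (falls back on optimizer failure).
    """
    gamma = np.asarray(gamma, dtype=float)
    beta = np.asarray(beta, dtype=float)
    m = gamma.shape[1]
    e_logx = digamma(beta) - digamma(beta.sum(axis=1, keepdims=True))
    lo, hi = cfg.alpha_bounds
    x0 = np.log(np.clip(np.concatenate([hp_init.alpha0, hp_init.alpha1]), lo, hi))

    def neg(x: np.ndarray) -> tuple[float, np.ndarray]:
        a = np.exp(x)
        a0, a1 = a[:m], a[m:]
        f = alpha_objective(a0, a1, gamma, beta)
        g0, g1 = _alpha_objective_grad(a0, a1, gamma, e_logx)
        return -f, -np.concatenate([g0 * a0, g1 * a1])

    f_start = alpha_objective(np.exp(x0[:m]), np.exp(x0[m:]), gamma, beta)
    bounds = [(np.log(lo), np.log(hi))] * (2 * m)
    try:
        res = optimize.minimize(neg, x0, jac=True, method="L-BFGS-B", bounds=bounds)
        a = np.exp(res.x)
        if np.isfinite(res.fun) and -res.fun >= f_start:
            return a[:m], a[m:]
        logger.warning("alpha optimization did not improve the objective; keeping warm start")
    except Exception:  # pragma: no cover - defensive
        logger.warning("alpha optimization failed; keeping warm start", exc_info=True)
    return np.exp(x0[:m]), np.exp(x0[m:])


def surrogate_elbo(W: CountMatrix, state: VariationalState, hp: Hyperparams) -> float:
    """Jensen-bounded evidence lower bound used as the convergence monitor.

    The exact ELBO contains ``E_q[lgamma(sum_j alpha_{j, delta_ij})]``, which
    is intractable; it is replaced by ``lgamma(sum_j abar_ij)`` (Jensen, since
    log-gamma is convex), matching the bound used in the M-step.  The value is
    therefore a lower bound on the exact log marginal likelihood.
    """
    Wm = W.counts.astype(float)
    beta, gamma = state.beta, state.gamma
    if beta.shape != Wm.shape:
        raise ValueError("state shape does not match the count matrix")
    _validate_hp_len(hp, Wm.shape[1])
    N = W.totals.astype(float)
    B = beta.sum(axis=1)
    e_logx = digamma(beta) - digamma(B)[:, None]

    mult = gammaln(N + 1.0).sum() - gammaln(Wm + 1.0).sum() + (Wm * e_logx).sum()
    px = alpha_objective(hp.alpha0, hp.alpha1, gamma, beta)
    pdelta = (xlogy(gamma, hp.pi) + xlogy(1.0 - gamma, 1.0 - hp.pi)).sum()
    ent_g = -(gammaln(B).sum() - gammaln(beta).sum() + ((beta - 1.0) * e_logx).sum())
    ent_q = -(xlogy(gamma, gamma) + xlogy(1.0 - gamma, 1.0 - gamma)).sum()
    return float(mult + px + pdelta + ent_g + ent_q)


def _sweep_gamma(
    Wm: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    hp: Hyperparams,
    guard: bool = True,
) -> float:
    """One cyclic responsibility sweep across taxa, vectorised over samples.

    Updates ``gamma`` in place; returns the largest absolute change.  With
    ``guard=True`` a coordinate move is kept only if it does not decrease the
    monitored surrogate objective at the current ``beta``.
    """
    a0, a1, pi = hp.alpha0, hp.alpha1, hp.pi
    lg_a0, lg_a1 = gammaln(a0), gammaln(a1)
    logit_pi = logit(np.minimum(pi, _PI_CEIL))
    abar = _mixture_alpha(gamma, hp)
    A = abar.sum(axis=1)
    e_logx = digamma(beta) - digamma(beta.sum(axis=1))[:, None]
    max_delta = 0.0
    for j in range(gamma.shape[1]):
        old = gamma[:, j].copy()
        abar_old = abar[:, j]
        R = A - abar_old
        if pi[j] == 0.0:
            new = np.zeros_like(old)
        else:
            dh = (
                gammaln(a1[j] + R)
                - gammaln(a0[j] + R)
                + (a1[j] - a0[j]) * e_logx[:, j]
                - lg_a1[j]
                + lg_a0[j]
            )
            new = expit(dh + logit_pi[j])
        if guard and pi[j] > 0.0:
            # Surrogate-objective change of this coordinate move at fixed beta.
            abar_new = new * a1[j] + (1.0 - new) * a0[j]
            c = (
                (a1[j] - a0[j]) * e_logx[:, j]
                - lg_a1[j]
                + lg_a0[j]
                + logit_pi[j]
            )
            # prior term g*log(pi) + (1-g)*log(1-pi) = g*logit(pi) + const
            dL = (
                gammaln(abar_new + R)
                - gammaln(abar_old + R)
                + (new - old) * c
                - (xlogy(new, new) + xlogy(1 - new, 1 - new))
                + (xlogy(old, old) + xlogy(1 - old, 1 - old))
            )
            keep = dL < -1e-12
            if keep.any():
                new = np.where(keep, old, new)
        gamma[:, j] = new
        abar[:, j] = new * a1[j] + (1.0 - new) * a0[j]
        A = A + abar[:, j] - abar_old
        step = np.abs(new - old).max() if new.size else 0.0
        max_delta = max(max_delta, float(step))
    return max_delta


def estep(
    W: CountMatrix,
    hp: Hyperparams,
    gamma0: np.ndarray | None = None,
    max_sweeps: int = 100,
    tol: float = 1e-6,
) -> VariationalState:
    """Run the mean-field E-step to a fixed point with hyperparameters held fixed.

    Useful on its own for posterior inference at known hyperparameters; the
    full EM uses a bounded number of sweeps per outer iteration instead.
    """
    _validate_hp_len(hp, W.n_taxa)
    Wm = W.counts.astype(float)
    gamma = (Wm > 0).astype(float) if gamma0 is None else np.array(gamma0, dtype=float)
    beta = Wm + _mixture_alpha(gamma, hp)
    for _ in range(max_sweeps):
        beta = Wm + _mixture_alpha(gamma, hp)
        delta = _sweep_gamma(Wm, beta, gamma, hp)
        if delta < tol:
            break
    beta = Wm + _mixture_alpha(gamma, hp)
    return VariationalState(beta=beta, gamma=gamma)


def _init_hyperparams(W: CountMatrix, cfg: FitConfig) -> tuple[Hyperparams, np.ndarray]:
    """Moment-based (or random) initialisation of hyperparameters and gamma."""
    Wm = W.counts.astype(float)
    n, m = Wm.shape
    P = Wm / W.totals[:, None].astype(float)
    rng = np.random.default_rng(cfg.seed)
    if cfg.init_strategy == "random":
        pi = rng.uniform(0.1, 0.9, size=m)
        alpha1 = rng.uniform(0.5, 5.0, size=m)
        alpha0 = np.full(m, 0.01)
        gamma = rng.uniform(0.0, 1.0, size=(n, m))
        return Hyperparams(pi=pi, alpha0=alpha0, alpha1=alpha1), gamma
    # moment init: prevalence for pi; a Dirichlet method-of-moments total
    # concentration scaled by the mean nonzero proportion for alpha1.
    prev = (Wm > 0).mean(axis=0)
    pi = np.clip(prev, 1e-3, _PI_CEIL)
    mbar = P.mean(axis=0)
    vbar = P.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = mbar * (1.0 - mbar) / vbar - 1.0
    conc = conc[np.isfinite(conc) & (conc > 0)]
    A = float(np.median(conc)) if conc.size else 10.0
    A = float(np.clip(A, 1.0, 1e3))
    nz_count = (Wm > 0).sum(axis=0)
    nz_mean = (P * (Wm > 0)).sum(axis=0) / np.maximum(nz_count, 1)
    nz_mean = np.where(nz_count > 0, nz_mean, 1.0 / m)
    lo, hi = cfg.alpha_bounds
    alpha1 = np.clip(A * nz_mean, max(lo, 1e-3), hi)
    alpha0 = np.full(m, 0.01)
    gamma = (Wm > 0).astype(float)
    return Hyperparams(pi=pi, alpha0=alpha0, alpha1=alpha1), gamma


def fit(
    W: CountMatrix,
    cfg: FitConfig | None = None,
    hp_init: Hyperparams | None = None,
) -> tuple[Hyperparams, VariationalState]:
    """Variational EM: estimate hyperparameters and the mean-field posterior.

    Alternates the E-step (closed-form ``beta`` plus bounded responsibility
    sweeps) and the M-step (closed-form ``pi``, quasi-Newton ``alpha``) until
    the relative change of the surrogate objective falls below
    ``cfg.rel_tol``.  Returns hyperparameters in canonical ordering
    (``alpha0 <= alpha1``, responsibilities relabelled consistently).
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or FitConfig()
    if W.n_taxa < 2:
        raise ValueError("at least two taxa are required (one-taxon data are degenerate)")
    zero_cols = (W.counts == 0).all(axis=0)
    if zero_cols.any():
        logger.warning(
            "%d taxa have all-zero counts; their posterior is prior-driven", int(zero_cols.sum())
        )
    Wm = W.counts.astype(float)
    if cfg.init_strategy == "user":
        if hp_init is None:
            raise ValueError("init_strategy='user' requires hp_init")
        hp = hp_init
        gamma = (Wm > 0).astype(float)
    else:
        hp, gamma = _init_hyperparams(W, cfg)

    trace: list[float] = []
    prev = -np.inf
    converged = False
    n_iter = 0
    beta = Wm + _mixture_alpha(gamma, hp)
    for n_iter in range(1, cfg.max_iter + 1):
        # E-step
        for _ in range(cfg.inner_max_sweeps):
            beta = Wm + _mixture_alpha(gamma, hp)
            delta = _sweep_gamma(Wm, beta, gamma, hp)
            if delta < cfg.inner_tol:
                break
        beta = Wm + _mixture_alpha(gamma, hp)
        # M-step
        pi = update_pi(gamma)
        hp = Hyperparams(pi=pi, alpha0=hp.alpha0, alpha1=hp.alpha1)
        a0, a1 = update_alpha(gamma, beta, hp, cfg)
        hp = Hyperparams(pi=pi, alpha0=a0, alpha1=a1)
        # canonical ordering: swap modes and relabel responsibilities
        swap = hp.alpha0 > hp.alpha1
        if swap.any():
            gamma[:, swap] = 1.0 - gamma[:, swap]
            hp = hp.ordered()
        state = VariationalState(beta=beta, gamma=gamma)
        cur = surrogate_elbo(W, state, hp)
        trace.append(cur)
        if np.isfinite(prev) and abs(cur - prev) <= cfg.rel_tol * (abs(prev) + 1e-12):
            converged = True
            break
        prev = cur

    state = VariationalState(
        beta=beta,
        gamma=gamma,
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_iter,
    )
    return hp, state
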