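"""Synthetic count tables: the bimodal-Dirichlet generative process, correlated
parametric alternatives, and two-group differential-abundance designs.

The bimodal generator runs the hierarchical model forward (mode indicators,
Dirichlet composition, multinomial counts).  The misspecified generators draw
per-taxon absolute abundances from gamma or log-normal marginals (or counts
directly from Poisson / negative-binomial marginals) with cross-taxon
correlation induced by a Gaussian copula, then normalise to compositions.
Sequencing depths default to log-uniform on [5e3, 5e4].

All generators are deterministic given their seed and record the ground
truth (composition, mode assignments, group labels, differential taxa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import CompositionMatrix, CountMatrix, Hyperparams, SimulationTruth

__all__ = [
    "CorrelationSpec",
    "default_bimodal_hyperparams",
    "default_depths",
    "simulate_bmdd",
    "simulate_misspecified",
    "simulate_daa",
]

# The gamma scale of the latent absolute abundances cancels from the induced
# composition, so it is pinned internally.
_RHO = 1.0

_MODELS = ("gamma", "lognormal", "poisson", "negbin")


@dataclass
class CorrelationSpec:
    """Cross-taxon correlation structure for the Gaussian copula.

    ``kind`` is ``"exchangeable"`` (constant off-diagonal) or ``"ar1"``
    (geometric decay with taxon distance); ``rho = 0`` gives independence.
    """

    kind: str = "exchangeable"
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("exchangeable", "ar1"):
            raise ValueError("correlation kind must be 'exchangeable' or 'ar1'")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("correlation coefficient must lie in (-1, 1)")

    def matrix(self, m: int) -> np.ndarray:
        if self.kind == "exchangeable":
            if self.rho < -1.0 / max(m - 1, 1):
                raise ValueError("exchangeable correlation is not positive definite")
            C = np.full((m, m), self.rho)
            np.fill_diagonal(C, 1.0)
        else:
            idx = np.arange(m)
            C = self.rho ** np.abs(idx[:, None] - idx[None, :])
        return C


def default_depths(n: int, rng: np.random.Generator, low: float = 5e3, high: float = 5e4) -> np.ndarray:
    """Log-uniform sequencing depths, the package's default depth regime."""
    return np.exp(rng.uniform(np.log(low), np.log(high), size=n)).astype(np.int64)


def default_bimodal_hyperparams(m: int, seed: int) -> Hyperparams:
    """A realistic bimodal hyperparameter set for benchmark-style simulations.

    Per taxon: high-mode probability ``pi ~ U(0.1, 0.9)``, near-zero spike
    ``alpha0 ~ logU(0.01, 0.1)`` and high mode ``alpha1 ~ logU(0.5, 20)``,
    spanning rare to dominant genera.
    """
    rng = np.random.default_rng(seed)
    pi = rng.uniform(0.1, 0.9, size=m)
    alpha0 = np.exp(rng.uniform(np.log(0.01), np.log(0.1), size=m))
    alpha1 = np.exp(rng.uniform(np.log(0.5), np.log(20.0), size=m))
    return Hyperparams(pi=pi, alpha0=alpha0, alpha1=alpha1)


def _dirichlet_rows(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise Dirichlet draws via normalised gammas (scale cancels)."""
    Y = rng.standard_gamma(theta) * _RHO
    total = Y.sum(axis=1, keepdims=True)
    bad = total[:, 0] == 0
    if bad.any():  # extreme underflow with very small concentrations
        Y[bad] = 1.0
        total = Y.sum(axis=1, keepdims=True)
    return Y / total


def simulate_bmdd(
    hp: Hyperparams,
    n: int,
    depths: np.ndarray | int,
    seed: int,
) -> tuple[CountMatrix, SimulationTruth]:
    """Run the bimodal-Dirichlet hierarchical model forward.

    Per sample: mode indicators ``delta_j ~ Bernoulli(pi_j)``, composition
    ``X ~ Dirichlet(alpha_{1,delta_1}, ..., alpha_{m,delta_m})``, counts
    ``W ~ Multinomial(N_i, X)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    m = hp.n_taxa
    depths = np.broadcast_to(np.asarray(depths, dtype=np.int64), (n,)).copy()
    if (depths <= 0).any():
        raise ValueError("depths must be positive")
    delta = rng.random((n, m)) < hp.pi
    theta = np.where(delta, hp.alpha1, hp.alpha0)
    X = _dirichlet_rows(theta, rng)
    W = np.stack([rng.multinomial(depths[i], X[i]) for i in range(n)])
    counts = CountMatrix(W)
    truth = SimulationTruth(
        composition=CompositionMatrix(X),
        depths=depths,
        hyperparams=hp,
        delta=delta.astype(np.int8),
    )
    return counts, truth


def _copula_uniforms(
    n: int, m: int, corr: CorrelationSpec, rng: np.random.Generator
) -> np.ndarray:
    C = corr.matrix(m)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(m))
    Z = rng.standard_normal((n, m)) @ L.T
    return stats.norm.cdf(Z)


def _marginal_params(
    model: str, m: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Documented default marginals: abundance means span ~2 orders of magnitude."""
    mu = np.exp(rng.normal(0.0, 1.5, size=m))
    if model == "gamma":
        shape = rng.uniform(0.3, 2.0, size=m)
        return {"mean": mu, "shape": shape, "scale": mu / shape}
    if model == "lognormal":
        sigma = rng.uniform(1.0, 2.0, size=m)
        return {"mean": mu, "sigma": sigma, "logmean": np.log(mu) - sigma**2 / 2.0}
    if model == "negbin":
        return {"mean": mu, "size": np.full(m, 0.5)}
    return {"mean": mu}


def simulate_misspecified(
    model: str,
    n: int,
    m: int,
    depths: np.ndarray | int,
    correlation: CorrelationSpec | None = None,
    seed: int = 0,
    group_scale: np.ndarray | None = None,
) -> tuple[CountMatrix, SimulationTruth]:
    """Correlated count tables from gamma / log-normal / Poisson / neg-binomial laws.

    Gamma and log-normal draw latent absolute abundances, normalise them to a
    per-sample composition and sample multinomial counts at the given depths.
    Poisson and negative-binomial draw counts directly with per-cell means
    proportional to depth; the recorded true composition is the normalised
    mean abundance vector.  ``group_scale`` (n x m) multiplies abundance
    means cell-wise (used by the differential-abundance designs).
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    corr = correlation or CorrelationSpec()
    ss = np.random.SeedSequence(seed)
    rng_par, rng_cop, rng_cnt = (np.random.default_rng(s) for s in ss.spawn(3))
    depths = np.broadcast_to(np.asarray(depths, dtype=np.int64), (n,)).copy()
    if (depths <= 0).any():
        raise ValueError("depths must be positive")
    par = _marginal_params(model, m, rng_par)
    scale = np.ones((n, m)) if group_scale is None else np.asarray(group_scale, dtype=float)
    U = _copula_uniforms(n, m, corr, rng_cop)
    U = np.clip(U, 1e-12, 1.0 - 1e-12)

    if model in ("gamma", "lognormal"):
        if model == "gamma":
            Y = stats.gamma.ppf(U, a=par["shape"], scale=par["scale"] * scale)
        else:
            Y = stats.lognorm.ppf(U, s=par["sigma"], scale=np.exp(par["logmean"]) * scale)
        Y = np.clip(Y, 1e-300, None)
        X = Y / Y.sum(axis=1, keepdims=True)
        W = np.stack([rng_cnt.multinomial(depths[i], X[i]) for i in range(n)])
    else:
        mean_ab = par["mean"] * scale
        comp = mean_ab / mean_ab.sum(axis=1, keepdims=True)
        lam = comp * depths[:, None]
        if model == "poisson":
            W = stats.poisson.ppf(U, mu=np.clip(lam, 1e-12, None)).astype(np.int64)
        else:
            size = par["size"]
            p = size / (size + np.clip(lam, 1e-12, None))
            W = stats.nbinom.ppf(U, n=size, p=p).astype(np.int64)
        X = comp
    empty = W.sum(axis=1) == 0
    if empty.any():  # keep sample alignment: give empty draws one pseudo-read
        W[empty, int(np.argmax(par["mean"]))] = 1
    counts = CountMatrix(W)
    truth = SimulationTruth(composition=CompositionMatrix(X), depths=depths)
    return counts, truth


def simulate_daa(
    model: str,
    n: int,
    m: int,
    prop_differential: float,
    effect: float,
    depths: np.ndarray | int | None = None,
    correlation: CorrelationSpec | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, SimulationTruth]:
    """Two-group design with a random differential-taxon set.

    The groups are equal halves; ``ceil(prop_differential * m)`` taxa receive
    a multiplicative mean-abundance shift of ``effect`` (fold change) in
    group 1.  The truth records group labels, the differential set and the
    per-taxon log-fold effects.
    """
    if not 0.0 <= prop_differential <= 1.0:
        raise ValueError("prop_differential must lie in [0, 1]")
    if effect <= 0:
        raise ValueError("effect must be a positive fold change")
    ss = np.random.SeedSequence(seed)
    s_design, s_data = ss.spawn(2)
    rng = np.random.default_rng(s_design)
    if depths is None:
        depths = default_depths(n, rng)
    group = np.zeros(n, dtype=np.int8)
    group[n // 2 :] = 1
    k = int(np.ceil(prop_differential * m))
    diff_set = np.sort(rng.choice(m, size=k, replace=False)) if k else np.empty(0, dtype=int)
    scale = np.ones((n, m))
    scale[np.ix_(group == 1, diff_set)] = effect
    counts, truth = simulate_misspecified(
        model,
        n,
        m,
        depths=depths,
        correlation=correlation,
        seed=int(s_data.generate_state(1)[0] % (2**31)),
        group_scale=scale,
    )
    truth.group = group
    truth.differential_set = diff_set
    truth.log_fold = np.full(k, float(np.log(effect)))
    return counts, truth
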