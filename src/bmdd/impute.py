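"""Posterior imputation, posterior sampling, predictive checks, naive
baselines and count-table preprocessing.

The fitted mean-field posterior of each sample's composition is a Dirichlet
with parameter row ``beta_i``; its mean ``beta_ij / sum_k beta_ik`` is the
single-imputation estimate (strictly positive, so log transforms are safe),
and independent Dirichlet draws provide multiple imputations that carry the
estimation uncertainty of the zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    CompositionMatrix,
    CountMatrix,
    PosteriorSampleSet,
    VariationalState,
)

__all__ = [
    "posterior_mean",
    "sample_posterior",
    "posterior_predictive",
    "PosteriorPredictiveSummary",
    "naive_impute",
    "preprocess",
]

_NAIVE_METHODS = ("naive1", "naive2", "naive3", "naive4")


def posterior_mean(
    state: VariationalState,
    sample_ids: list[str] | None = None,
    taxon_ids: list[str] | None = None,
) -> CompositionMatrix:
    """Posterior-mean composition ``beta_ij / sum_k beta_ik`` (no zeros survive)."""
    X = state.beta / state.beta.sum(axis=1, keepdims=True)
    return CompositionMatrix(X, sample_ids=sample_ids, taxon_ids=taxon_ids)


def sample_posterior(
    state: VariationalState,
    L: int,
    seed: int,
    sample_ids: list[str] | None = None,
    taxon_ids: list[str] | None = None,
) -> PosteriorSampleSet:
    """Draw ``L`` composition matrices from the variational posterior.

    Row ``i`` of each draw is Dirichlet(``beta_i``); under the mean-field
    factorisation the composition is independent of the mode indicators, so
    this is the full variational posterior of the composition.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    beta = state.beta
    G = rng.standard_gamma(np.broadcast_to(beta, (L, *beta.shape)))
    total = G.sum(axis=2, keepdims=True)
    zero = total == 0
    if zero.any():  # tiny-concentration underflow: fall back to the mean
        G = np.where(zero, beta, G)
        total = G.sum(axis=2, keepdims=True)
    return PosteriorSampleSet(
        samples=G / total, seed=seed, sample_ids=sample_ids, taxon_ids=taxon_ids
    )


@dataclass
class PosteriorPredictiveSummary:
    """Per-taxon predictive-check summaries of replicated count tables."""

    observed_zero_prop: np.ndarray
    replicate_zero_prop: np.ndarray  # (L, m)
    observed_sd: np.ndarray
    replicate_sd: np.ndarray  # (L, m)

    @property
    def mean_replicate_zero_prop(self) -> np.ndarray:
        return self.replicate_zero_prop.mean(axis=0)


def posterior_predictive(
    state: VariationalState,
    W: CountMatrix,
    L: int,
    seed: int,
) -> tuple[np.ndarray, PosteriorPredictiveSummary]:
    """Replicate count tables from the fitted posterior and summarise them.

    Each replicate draws compositions from the posterior and then counts via
    ``Multinomial(N_i, X_i)``; per-taxon zero proportions and count standard
    deviations of the replicates are compared with the observed table.
    """
    ss = np.random.SeedSequence(seed)
    s_comp, s_count = ss.spawn(2)
    draws = sample_posterior(state, L, seed=int(s_comp.generate_state(1)[0] % 2**31))
    rng = np.random.default_rng(s_count)
    N = W.totals
    n, m = W.shape
    reps = np.empty((L, n, m), dtype=np.int64)
    for ell in range(L):
        for i in range(n):
            reps[ell, i] = rng.multinomial(N[i], draws.samples[ell, i])
    summary = PosteriorPredictiveSummary(
        observed_zero_prop=(W.counts == 0).mean(axis=0),
        replicate_zero_prop=(reps == 0).mean(axis=1),
        observed_sd=W.counts.std(axis=0),
        replicate_sd=reps.std(axis=1),
    )
    return reps, summary


def naive_impute(W: CountMatrix, method: str) -> CompositionMatrix:
    """The four naive composition estimates.

    ``naive1`` — plain proportions (zeros retained); ``naive2`` — add a
    pseudocount of 1 to every cell; ``naive3`` — replace zero cells with 0.5;
    ``naive4`` — replace a zero cell (i, j) with ``N_i / max_k{N_k : W_kj = 0}``
    (vacuous for taxa with no zeros).  Rows are renormalised to the simplex.
    """
    if method not in _NAIVE_METHODS:
        raise ValueError(f"method must be one of {_NAIVE_METHODS}")
    Wf = W.counts.astype(float)
    N = W.totals.astype(float)
    if method == "naive1":
        V = Wf
    elif method == "naive2":
        V = Wf + 1.0
    elif method == "naive3":
        V = np.where(Wf == 0, 0.5, Wf)
    else:
        V = Wf.copy()
        zero = Wf == 0
        for j in range(W.n_taxa):
            zj = zero[:, j]
            if zj.any():
                V[zj, j] = N[zj] / N[zj].max()
    X = V / V.sum(axis=1, keepdims=True)
    return CompositionMatrix(X, sample_ids=W.sample_ids, taxon_ids=W.taxon_ids)


def preprocess(
    W: CountMatrix,
    min_depth: int = 1000,
    min_prevalence: float = 0.2,
    winsor_q: float = 0.97,
) -> CountMatrix:
    """Standard real-data filters: depth, prevalence, then winsorization.

    Drops samples with fewer than ``min_depth`` reads, then taxa present in
    fewer than ``min_prevalence`` of the retained samples, then caps each
    taxon column at its ``winsor_q`` empirical quantile (linear
    interpolation, rounded to keep counts integral).
    """
    if not (0 <= min_prevalence <= 1 and 0 < winsor_q <= 1 and min_depth >= 0):
        raise ValueError("thresholds out of range")
    keep_s = W.totals >= min_depth
    if not keep_s.any():
        raise ValueError(f"no samples retained at min_depth={min_depth}")
    counts = W.counts[keep_s]
    sample_ids = [s for s, k in zip(W.sample_ids, keep_s) if k]
    prevalence = (counts > 0).mean(axis=0)
    keep_t = prevalence >= min_prevalence
    if not keep_t.any():
        raise ValueError(f"no taxa retained at min_prevalence={min_prevalence}")
    counts = counts[:, keep_t]
    taxon_ids = [t for t, k in zip(W.taxon_ids, keep_t) if k]
    caps = np.quantile(counts, winsor_q, axis=0)
    counts = np.minimum(counts, np.rint(caps).astype(np.int64))
    return CountMatrix(counts, sample_ids=sample_ids, taxon_ids=taxon_ids)
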