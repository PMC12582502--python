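"""Core data containers for the bimodal-Dirichlet imputation model.

The observed data are a samples-by-taxa table of sequencing read counts
``W`` with per-sample totals (sequencing depths) ``N``.  The model places a
two-mode mixture prior on each taxon's Dirichlet concentration: taxon ``j``
draws its concentration from a low mode ``alpha0[j]`` or a high mode
``alpha1[j]`` according to a latent Bernoulli indicator with success
probability ``pi[j]``.  The mean-field variational posterior is parameterised
by a Dirichlet parameter matrix ``beta`` (one row per sample) and a
responsibility matrix ``gamma`` (posterior probability that each sample/taxon
cell arose from the high mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CountMatrix",
    "Hyperparams",
    "VariationalState",
    "FitConfig",
    "CompositionMatrix",
    "PosteriorSampleSet",
    "SimulationTruth",
]


def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{what} must be unique")
    return labels


@dataclass
class CountMatrix:
    """Nonnegative integer read counts, samples as rows.

    Parameters
    ----------
    counts
        ``(n_samples, n_taxa)`` array of nonnegative integers.
    sample_ids, taxon_ids
        Unique row and column labels.  Generated automatically when omitted.
    """

    counts: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    taxon_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        W = np.asarray(self.counts)
        if W.ndim != 2:
            raise ValueError("counts must be a 2-D samples-by-taxa matrix")
        if not np.isfinite(W).all():
            raise ValueError("counts must be finite")
        if (W < 0).any():
            bad = np.argwhere(W < 0)[0]
            raise ValueError(f"negative count at sample {bad[0]}, taxon {bad[1]}")
        if not np.allclose(W, np.round(W)):
            bad = np.argwhere(~np.isclose(W, np.round(W)))[0]
            raise ValueError(f"non-integer count at sample {bad[0]}, taxon {bad[1]}")
        self.counts = W.astype(np.int64)
        n, m = self.counts.shape
        if self.sample_ids is None:
            self.sample_ids = [f"sample_{i}" for i in range(n)]
        if self.taxon_ids is None:
            self.taxon_ids = [f"taxon_{j}" for j in range(m)]
        self.sample_ids = _check_unique(self.sample_ids, "sample_ids")
        self.taxon_ids = _check_unique(self.taxon_ids, "taxon_ids")
        if len(self.sample_ids) != n or len(self.taxon_ids) != m:
            raise ValueError("label lengths do not match the count matrix shape")
        if (self.totals <= 0).any():
            i = int(np.argmax(self.totals <= 0))
            raise ValueError(f"sample {self.sample_ids[i]} has zero total count")

    @property
    def totals(self) -> np.ndarray:
        """Per-sample sequencing depths ``N_i`` (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class Hyperparams:
    """Per-taxon prior parameters ``(pi_j, alpha0_j, alpha1_j)``.

    ``pi_j`` is the prior probability of the high-abundance mode; ``alpha0_j``
    and ``alpha1_j`` are the two Dirichlet concentration modes.  The canonical
    ordering ``alpha0_j <= alpha1_j`` is an identifiability convention and is
    not enforced at construction (fitting restores it after each update).
    """

    pi: np.ndarray
    alpha0: np.ndarray
    alpha1: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        self.alpha0 = np.atleast_1d(np.asarray(self.alpha0, dtype=float))
        self.alpha1 = np.atleast_1d(np.asarray(self.alpha1, dtype=float))
        m = self.pi.shape[0]
        if self.alpha0.shape != (m,) or self.alpha1.shape != (m,):
            raise ValueError("pi, alpha0, alpha1 must share one length")
        for name, v in (("pi", self.pi), ("alpha0", self.alpha0), ("alpha1", self.alpha1)):
            if not np.isfinite(v).all():
                raise ValueError(f"{name} must be finite")
        if ((self.pi < 0) | (self.pi >= 1)).any():
            raise ValueError("pi must satisfy 0 <= pi_j < 1")
        if (self.alpha0 <= 0).any() or (self.alpha1 <= 0).any():
            raise ValueError("alpha modes must be strictly positive")

    @property
    def n_taxa(self) -> int:
        return self.pi.shape[0]

    def ordered(self) -> "Hyperparams":
        """Return a copy with the canonical ordering alpha0 <= alpha1."""
        swap = self.alpha0 > self.alpha1
        a0 = np.where(swap, self.alpha1, self.alpha0)
        a1 = np.where(swap, self.alpha0, self.alpha1)
        pi = np.where(swap, np.clip(1.0 - self.pi, 0.0, 1.0 - 1e-8), self.pi)
        return Hyperparams(pi=pi, alpha0=a0, alpha1=a1)


@dataclass
class VariationalState:
    """Mean-field posterior: Dirichlet parameters and mode responsibilities."""

    beta: np.ndarray
    gamma: np.ndarray
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.beta.shape != self.gamma.shape or self.beta.ndim != 2:
            raise ValueError("beta and gamma must be matrices of the same shape")
        if (self.beta <= 0).any():
            raise ValueError("beta must be strictly positive")
        if ((self.gamma < 0) | (self.gamma > 1)).any():
            raise ValueError("gamma must lie in [0, 1]")
        self.objective_trace = np.asarray(self.objective_trace, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape


@dataclass
class FitConfig:
    """Knobs of the variational EM fit.

    ``rel_tol`` is the relative change of the surrogate objective that stops
    the outer loop; ``alpha_bounds`` constrain the concentration modes during
    the numerical M-step (log parameterisation).
    """

    max_iter: int = 200
    rel_tol: float = 1e-6
    alpha_bounds: tuple[float, float] = (1e-6, 1e4)
    seed: int = 0
    init_strategy: str = "moment"
    inner_max_sweeps: int = 20
    inner_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.rel_tol < 0:
            raise ValueError("rel_tol must be >= 0")
        lo, hi = self.alpha_bounds
        if not (0 < lo < hi):
            raise ValueError("alpha_bounds must be a positive interval")
        if self.init_strategy not in ("moment", "random", "user"):
            raise ValueError("init_strategy must be 'moment', 'random' or 'user'")


@dataclass
class CompositionMatrix:
    """Relative abundances; every row lies on the probability simplex."""

    values: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    taxon_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        X = np.asarray(self.values, dtype=float)
        if X.ndim != 2:
            raise ValueError("values must be 2-D")
        if not np.isfinite(X).all():
            raise ValueError("values must be finite")
        if ((X < 0) | (X > 1)).any():
            raise ValueError("values must lie in [0, 1]")
        rs = X.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-8):
            raise ValueError("rows must sum to 1 within 1e-8")
        self.values = X
        n, m = X.shape
        if self.sample_ids is None:
            self.sample_ids = [f"sample_{i}" for i in range(n)]
        if self.taxon_ids is None:
            self.taxon_ids = [f"taxon_{j}" for j in range(m)]
        self.sample_ids = _check_unique(self.sample_ids, "sample_ids")
        self.taxon_ids = _check_unique(self.taxon_ids, "taxon_ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PosteriorSampleSet:
    """``L`` posterior composition draws, stacked ``(L, n, m)``; seed-tracked."""

    samples: np.ndarray
    seed: int
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    taxon_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        S = np.asarray(self.samples, dtype=float)
        if S.ndim != 3 or S.shape[0] < 1:
            raise ValueError("samples must have shape (L, n, m) with L >= 1")
        if not np.allclose(S.sum(axis=2), 1.0, atol=1e-8):
            raise ValueError("every draw must have rows on the simplex")
        self.samples = S

    @property
    def n_draws(self) -> int:
        return self.samples.shape[0]

    def draw(self, ell: int) -> CompositionMatrix:
        return CompositionMatrix(
            self.samples[ell], sample_ids=self.sample_ids, taxon_ids=self.taxon_ids
        )


@dataclass
class SimulationTruth:
    """Ground truth attached to a simulated count table."""

    composition: CompositionMatrix
    depths: np.ndarray
    hyperparams: Hyperparams | None = None
    delta: np.ndarray | None = None
    group: np.ndarray | None = None
    differential_set: np.ndarray | None = None
    log_fold: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.delta is not None:
            d = np.asarray(self.delta)
            if not np.isin(d, (0, 1)).all():
                raise ValueError("delta entries must be 0/1")
            self.delta = d.astype(np.int8)
        if self.group is not None:
            self.group = np.asarray(self.group).astype(np.int8)
        if self.differential_set is not None:
            ds = np.asarray(self.differential_set, dtype=int)
            m = self.composition.shape[1]
            if ((ds < 0) | (ds >= m)).any():
                raise ValueError("differential_set indices out of range")
            self.differential_set = ds
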