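"""Fifteen-metric battery comparing an estimated composition matrix to truth.

Three families of discrepancies, all oriented as "distance of the estimate
from the truth" and aggregated by unweighted means, so 0 means a perfect
reconstruction:

* matrix similarity — elementwise MSE, mean per-sample Euclidean distance,
  mean per-taxon Euclidean distance;
* sample-wise ecology — mean absolute difference of Shannon and Simpson
  diversity, mean paired Bray-Curtis, Kullback-Leibler (truth vs estimate),
  Jensen-Shannon and Hellinger distances;
* taxon-wise distribution shape — mean absolute difference of the Gini
  coefficient and of the coefficient of variation, mean Euclidean distance
  between (mean, sd) pairs, mean Kolmogorov-Smirnov and 1-Wasserstein
  distances between per-taxon empirical distributions, and the Frobenius
  distance between the two taxon-taxon correlation matrices.

Logarithms are natural throughout; estimated zeros are floored at 1e-12
inside the KL term to keep it finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, jensenshannon
from scipy.stats import wasserstein_distance
from scipy.special import rel_entr

from .containers import CompositionMatrix

__all__ = ["METRIC_NAMES", "MetricReport", "evaluate"]

METRIC_NAMES = (
    "mse",
    "sample_distance",
    "taxon_distance",
    "shannon",
    "simpson",
    "bray_curtis",
    "kl",
    "jensen_shannon",
    "hellinger",
    "gini",
    "mean_sd",
    "cv",
    "ks",
    "wasserstein",
    "correlation",
)

_EPS = 1e-12


@dataclass
class MetricReport:
    """Per-metric scores (smaller is better) plus run metadata."""

    scores: dict[str, float]
    n_samples: int
    n_taxa: int
    method: str = ""
    definitions: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metric": list(self.scores), "score": list(self.scores.values())}
        )

    def __getitem__(self, key: str) -> float:
        return self.scores[key]


_DEFINITIONS = {
    "mse": "mean over all cells of squared error",
    "sample_distance": "mean over samples of the Euclidean row distance",
    "taxon_distance": "mean over taxa of the Euclidean column distance",
    "shannon": "mean |difference| of per-sample Shannon diversity (nats)",
    "simpson": "mean |difference| of per-sample Simpson diversity",
    "bray_curtis": "mean paired Bray-Curtis dissimilarity across samples",
    "kl": "mean per-sample KL(truth || estimate), estimate floored at 1e-12",
    "jensen_shannon": "mean per-sample Jensen-Shannon divergence (nats)",
    "hellinger": "mean per-sample Hellinger distance",
    "gini": "mean |difference| of per-taxon Gini coefficients",
    "mean_sd": "mean Euclidean distance between per-taxon (mean, sd) pairs",
    "cv": "mean |difference| of per-taxon coefficients of variation",
    "ks": "mean per-taxon two-sample Kolmogorov-Smirnov statistic",
    "wasserstein": "mean per-taxon 1-Wasserstein distance across samples",
    "correlation": "Frobenius distance between taxon-taxon Pearson correlation matrices",
}


def _shannon(X: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(X > 0, X * np.log(np.clip(X, _EPS, None)), 0.0)
    return -t.sum(axis=1)


def _gini(col: np.ndarray) -> float:
    x = np.sort(np.asarray(col, dtype=float))
    n = x.size
    s = x.sum()
    if s == 0 or n < 2:
        return 0.0
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n * s))


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic on the pooled support (exact, ties handled)."""
    grid = np.concatenate([a, b])
    Fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    Fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.abs(Fa - Fb).max())


def _corr_matrix(X: np.ndarray, spearman: bool) -> np.ndarray:
    if spearman:
        from scipy.stats import rankdata

        X = rankdata(X, axis=0)
    sd = X.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    # constant taxa carry no correlation signal: zero them out consistently
    bad = sd == 0
    C[bad, :] = 0.0
    C[:, bad] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.nan_to_num(C)


def evaluate(
    est: CompositionMatrix,
    truth: CompositionMatrix,
    method: str = "",
    spearman: bool = False,
) -> MetricReport:
    """Compute all fifteen scores of ``est`` against ``truth``.

    Requires matching shapes and label order.  With fewer than two samples
    the correlation score is defined as 0 (no correlation signal exists).
    """
    if est.shape != truth.shape:
        raise ValueError("estimate and truth must have the same shape")
    if est.sample_ids != truth.sample_ids or est.taxon_ids != truth.taxon_ids:
        raise ValueError("estimate and truth must share sample and taxon labels")
    E, T = est.values, truth.values
    n, m = E.shape

    diff = E - T
    scores: dict[str, float] = {}
    scores["mse"] = float((diff**2).mean())
    scores["sample_distance"] = float(np.linalg.norm(diff, axis=1).mean())
    scores["taxon_distance"] = float(np.linalg.norm(diff, axis=0).mean())

    scores["shannon"] = float(np.abs(_shannon(E) - _shannon(T)).mean())
    scores["simpson"] = float(np.abs((1 - (E**2).sum(1)) - (1 - (T**2).sum(1))).mean())
    scores["bray_curtis"] = float(np.mean([braycurtis(E[i], T[i]) for i in range(n)]))
    scores["kl"] = float(rel_entr(T, np.clip(E, _EPS, None)).sum(axis=1).mean())
    scores["jensen_shannon"] = float(
        np.mean([jensenshannon(T[i], E[i], base=np.e) ** 2 for i in range(n)])
    )
    scores["hellinger"] = float(
        np.mean(np.sqrt(0.5 * ((np.sqrt(E) - np.sqrt(T)) ** 2).sum(axis=1)))
    )

    scores["gini"] = float(
        np.mean([abs(_gini(E[:, j]) - _gini(T[:, j])) for j in range(m)])
    )
    mean_sd_e = np.stack([E.mean(axis=0), E.std(axis=0)], axis=1)
    mean_sd_t = np.stack([T.mean(axis=0), T.std(axis=0)], axis=1)
    scores["mean_sd"] = float(np.linalg.norm(mean_sd_e - mean_sd_t, axis=1).mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        cv_e = np.where(E.mean(0) > 0, E.std(0) / E.mean(0), 0.0)
        cv_t = np.where(T.mean(0) > 0, T.std(0) / T.mean(0), 0.0)
    scores["cv"] = float(np.abs(cv_e - cv_t).mean())
    scores["ks"] = float(np.mean([_ks_statistic(E[:, j], T[:, j]) for j in range(m)]))
    scores["wasserstein"] = float(
        np.mean([wasserstein_distance(E[:, j], T[:, j]) for j in range(m)])
    )
    if n < 2:
        scores["correlation"] = 0.0
    else:
        scores["correlation"] = float(
            np.linalg.norm(_corr_matrix(E, spearman) - _corr_matrix(T, spearman))
        )

    assert set(scores) == set(METRIC_NAMES)
    return MetricReport(
        scores={k: scores[k] for k in METRIC_NAMES},
        n_samples=n,
        n_taxa=m,
        method=method,
        definitions=dict(_DEFINITIONS),
    )
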