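"""Delimited-text readers/writers and JSON model serialisation.

Tables are TSV by default (tab-delimited, UTF-8, '.' decimal), first column
row labels, header column labels; CSV is accepted on read by extension or an
explicit ``sep``.  Count tables are stored samples-as-rows internally; a
``transpose`` flag accepts taxa-as-rows files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CompositionMatrix, CountMatrix, Hyperparams, VariationalState

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_composition",
    "write_composition",
    "save_model",
    "load_model",
]


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_count_table(
    path: str | Path, transpose: bool = False, sep: str | None = None
) -> CountMatrix:
    """Read a labelled count table; ``transpose=True`` for taxa-as-rows files."""
    path = Path(path)
    use_sep = _sep_for(path, sep)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(use_sep)[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"duplicate column labels in {path}")
    df = pd.read_csv(path, sep=use_sep, index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate row labels in {path}")
    if transpose:
        df = df.T
    values = df.to_numpy()
    bad = ~np.isclose(values.astype(float), np.round(values.astype(float)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer cell at row '{df.index[i]}', column '{df.columns[j]}' in {path}"
        )
    neg = values.astype(float) < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"negative cell at row '{df.index[i]}', column '{df.columns[j]}' in {path}"
        )
    return CountMatrix(
        counts=values.astype(np.int64),
        sample_ids=[str(x) for x in df.index],
        taxon_ids=[str(x) for x in df.columns],
    )


def write_count_table(W: CountMatrix, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(W.counts, index=W.sample_ids, columns=W.taxon_ids).to_csv(path, sep=sep)


def read_composition(path: str | Path, sep: str | None = None) -> CompositionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    values = df.to_numpy(dtype=float)
    values = values / values.sum(axis=1, keepdims=True)
    return CompositionMatrix(
        values,
        sample_ids=[str(x) for x in df.index],
        taxon_ids=[str(x) for x in df.columns],
    )


def write_composition(X: CompositionMatrix, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(X.values, index=X.sample_ids, columns=X.taxon_ids).to_csv(
        path, sep=sep, float_format="%.10g"
    )


def save_model(
    path: str | Path,
    hp: Hyperparams,
    state: VariationalState,
    config: dict | None = None,
) -> None:
    """Serialise a fitted model to one structured JSON file."""
    payload = {
        "pi": hp.pi.tolist(),
        "alpha0": hp.alpha0.tolist(),
        "alpha1": hp.alpha1.tolist(),
        "beta": state.beta.tolist(),
        "gamma": state.gamma.tolist(),
        "objective_trace": state.objective_trace.tolist(),
        "converged": bool(state.converged),
        "n_iter": int(state.n_iter),
        "config": config or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[Hyperparams, VariationalState, dict]:
    payload = json.loads(Path(path).read_text())
    hp = Hyperparams(
        pi=np.asarray(payload["pi"]),
        alpha0=np.asarray(payload["alpha0"]),
        alpha1=np.asarray(payload["alpha1"]),
    )
    state = VariationalState(
        beta=np.asarray(payload["beta"]),
        gamma=np.asarray(payload["gamma"]),
        objective_trace=np.asarray(payload["objective_trace"]),
        converged=payload["converged"],
        n_iter=payload["n_iter"],
    )
    return hp, state, payload.get("config", {})
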