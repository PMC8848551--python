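"""Exact (ancestral) sampling of datasets from a Bayesian network model.

Rows are generated serially: nodes are visited in topological order and each
node's state is drawn from the conditional-table column selected by the
already-sampled states of its parents.  Categorical draws use inverse-CDF on
the column with state 0 first, so a run is reproducible bit-for-bit from the
generator stream.

One uniform variate is consumed per (row, node) cell.  ``sample_dataset``
draws the whole ``(N, n)`` block of variates in C (row-major) order, which
consumes the generator stream exactly as ``N`` successive ``sample_row``
calls would — the vectorised dataset path and the scalar row path are
therefore interchangeable under a shared seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cpt import BayesNetModel
from .errors import InvalidArgumentError

__all__ = ["Dataset", "sample_row", "sample_dataset"]


@dataclass
class Dataset:
    """A sampled dataset: ``values[i, j]`` is the 0-based state of node ``j``
    (model node order) in row ``i``."""

    values: np.ndarray
    columns: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise InvalidArgumentError("values must be (N, n_nodes)")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))


def _draw_states(cdf: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw: smallest state whose cumulative mass exceeds u.

    ``cdf`` has shape (arity, n_rows) — per-row cumulative columns; ``u`` is
    one uniform variate per row.  Clipped to the top state to guard against
    a cumulative sum that rounds fractionally below 1.
    """
    return np.minimum((u[None, :] >= cdf).sum(axis=0), cdf.shape[0] - 1)


def sample_row(model: BayesNetModel, rng: np.random.Generator) -> np.ndarray:
    """Draw one complete joint assignment by ancestral sampling.

    Consumes exactly one uniform variate per node, in topological order.
    """
    row = np.empty(model.n_nodes, dtype=np.int64)
    for v in model.structure.order:
        table = model.tables[v]
        pa = model.parents(v)
        col = table.column([row[p] for p in pa]) if pa else table.columns[:, 0]
        u = rng.random()
        row[v] = min(int((u >= np.cumsum(col)).sum()), model.arities[v] - 1)
    return row


def sample_dataset(
    model: BayesNetModel, n_rows: int, seed: int | np.random.Generator
) -> Dataset:
    """Draw ``n_rows`` independent rows under one seeded generator.

    Equivalent to ``n_rows`` successive :func:`sample_row` calls on the same
    generator, but vectorised per node over all rows.
    """
    if n_rows < 1:
        raise InvalidArgumentError("n_rows must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = model.n_nodes
    # One variate per (row, node) cell, row-major: identical stream order to
    # repeated sample_row calls.
    u = rng.random((n_rows, n))
    values = np.empty((n_rows, n), dtype=np.int64)
    for j, v in enumerate(model.structure.order):
        table = model.tables[v]
        pa = model.parents(v)
        if pa:
            col_idx = np.ravel_multi_index(
                tuple(values[:, p] for p in pa), table.ancestor_arities
            )
        else:
            col_idx = np.zeros(n_rows, dtype=np.intp)
        cdf = np.cumsum(table.columns, axis=0)[:, col_idx]
        values[:, v] = _draw_states(cdf, u[:, j])
    meta = {"n_rows": int(n_rows)}
    if not isinstance(seed, np.random.Generator):
        meta["seed"] = int(seed)
    return Dataset(values=values, columns=model.labels, meta=meta)
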