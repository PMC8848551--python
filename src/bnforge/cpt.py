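"""Conditional probability tables as simplex-column matrices.

A discrete child variable with ``n`` states, conditioned on a set of
ancestor variables with ``m`` joint events, is encoded as an ``n x m``
column-stochastic matrix ``D``: column ``i`` is the child's distribution
given ancestor joint event ``i``, a point on the ``(n-1)``-simplex.  The
matrix acts as a linear operator carrying any ancestor distribution
``P(Y)`` to the induced child marginal ``P(X) = D @ P(Y)``.

Dependence is a property of ``D`` alone: the child is conditionally
dependent on its ancestors if and only if ``D`` has rank at least two, and
the ancestor events that are *structurally* dependent (dependent under
every full-support ancestor distribution) are exactly the columns that are
vertices of the convex hull of the column set.  Sampling columns uniformly
from the simplex is sampling from a flat Dirichlet; pinning the number of
hull vertices (``n_vertex_columns``) controls how many structurally
dependent events the table encodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.optimize import linprog

from .errors import DegenerateDrawError, InvalidArgumentError
from .graphs import DagStructure

__all__ = [
    "ConditionalTable",
    "BayesNetModel",
    "sample_simplex",
    "ancestor_event_space",
    "build_cpt",
    "is_dependent",
    "dependence_oracle",
    "hull_vertices",
    "induced_marginal",
    "random_model",
]

_SIMPLEX_ATOL = 1e-12


def _as_alpha(alpha, k: int) -> np.ndarray:
    a = np.broadcast_to(np.asarray(alpha, dtype=float), (k,)).copy()
    if np.any(a <= 0):
        raise InvalidArgumentError("Dirichlet concentration must be positive")
    return a


def sample_simplex(k: int, alpha, rng: np.random.Generator) -> np.ndarray:
    """Draw one point on the ``(k-1)``-simplex from ``Dirichlet(alpha)``.

    With ``alpha`` all ones the draw is uniform on the simplex.  ``alpha``
    may be a scalar (shared concentration) or a length-``k`` vector.
    """
    if k < 1:
        raise InvalidArgumentError("simplex dimension k must be >= 1")
    if k == 1:
        _as_alpha(alpha, 1)
        return np.array([1.0])
    return rng.dirichlet(_as_alpha(alpha, k))


def ancestor_event_space(
    arities: Sequence[int],
) -> tuple[int, Iterator[tuple[int, ...]]]:
    """Joint event space of a set of ancestor variables.

    Returns the event count (product of arities; 1 for no ancestors) and an
    enumerator over joint assignments in canonical mixed-radix order, first
    ancestor most significant.  Two binary ancestors give four events, a
    binary and a tertiary one six.
    """
    arities = tuple(int(a) for a in arities)
    if any(a < 2 for a in arities):
        raise InvalidArgumentError("every ancestor arity must be >= 2")
    count = int(np.prod(arities, dtype=object)) if arities else 1

    def _enumerate() -> Iterator[tuple[int, ...]]:
        if not arities:
            yield ()
            return
        for idx in np.ndindex(*arities):
            yield tuple(int(i) for i in idx)

    return count, _enumerate()


@dataclass(frozen=True)
class ConditionalTable:
    """Column-stochastic conditional table ``P(child | ancestors)``.

    ``columns`` has shape ``(child_arity, m)`` where ``m`` is the product of
    ``ancestor_arities`` (1 for a root node, whose single column is its
    unconditional distribution).  Column ``i`` corresponds to ancestor joint
    event ``i`` under mixed-radix encoding, first ancestor most significant.
    """

    child_arity: int
    ancestor_arities: tuple[int, ...]
    columns: np.ndarray

    def __post_init__(self):
        cols = np.asarray(self.columns, dtype=float)
        object.__setattr__(self, "columns", cols)
        object.__setattr__(
            self, "ancestor_arities", tuple(int(a) for a in self.ancestor_arities)
        )
        m = int(np.prod(self.ancestor_arities)) if self.ancestor_arities else 1
        if cols.shape != (self.child_arity, m):
            raise InvalidArgumentError(
                f"columns shape {cols.shape} != ({self.child_arity}, {m})"
            )
        if np.any(cols < -_SIMPLEX_ATOL):
            raise InvalidArgumentError("table entries must be non-negative")
        sums = cols.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise InvalidArgumentError(
                f"column {bad} sums to {sums[bad]:.12g}, not 1"
            )

    @property
    def n_events(self) -> int:
        """Number of ancestor joint events (columns)."""
        return self.columns.shape[1]

    def column_index(self, assignment: Sequence[int]) -> int:
        """Mixed-radix index of an ancestor joint assignment."""
        assignment = tuple(int(v) for v in assignment)
        if len(assignment) != len(self.ancestor_arities):
            raise InvalidArgumentError(
                f"assignment length {len(assignment)} != "
                f"{len(self.ancestor_arities)} ancestors"
            )
        if not self.ancestor_arities:
            return 0
        for v, a in zip(assignment, self.ancestor_arities):
            if not 0 <= v < a:
                raise InvalidArgumentError(f"state {v} outside [0, {a})")
        return int(np.ravel_multi_index(assignment, self.ancestor_arities))

    def column(self, assignment: Sequence[int]) -> np.ndarray:
        """Child distribution given the ancestor joint assignment."""
        return self.columns[:, self.column_index(assignment)]


def build_cpt(
    child_arity: int,
    ancestor_arities: Sequence[int],
    alpha,
    rng: np.random.Generator,
    n_vertex_columns: int | None = None,
    max_retries: int = 100,
) -> ConditionalTable:
    """Construct a random conditional table with Dirichlet-sampled columns.

    By default every column is an independent ``Dirichlet(alpha)`` draw.
    With ``n_vertex_columns = k``, only ``k`` columns are independent draws
    and the remaining ``m - k`` are random convex combinations of those
    (flat-Dirichlet weights), so the table encodes at most ``k``
    structurally dependent ancestor events.

    Tables with ``m >= 2`` are verified conditionally dependent (rank >= 2);
    coincidentally rank-deficient draws — a probability-zero event for
    continuous draws, but floating point exists — are resampled up to
    ``max_retries`` times before a :class:`DegenerateDrawError`.
    """
    if child_arity < 2:
        raise InvalidArgumentError("child arity must be >= 2")
    m, _ = ancestor_event_space(ancestor_arities)
    if n_vertex_columns is not None:
        if n_vertex_columns < 2:
            raise InvalidArgumentError(
                "n_vertex_columns must be >= 2: a dependent table's hull "
                "has at least two vertices"
            )
        if n_vertex_columns > m:
            raise InvalidArgumentError(
                f"n_vertex_columns={n_vertex_columns} exceeds event count {m}"
            )
    a = _as_alpha(alpha, child_arity)

    for _ in range(max_retries + 1):
        if n_vertex_columns is None:
            cols = rng.dirichlet(a, size=m).T
        else:
            k = n_vertex_columns
            vertices = rng.dirichlet(a, size=k).T
            if m > k:
                weights = rng.dirichlet(np.ones(k), size=m - k).T
                cols = np.hstack([vertices, vertices @ weights])
            else:
                cols = vertices
        table = ConditionalTable(child_arity, tuple(ancestor_arities), cols)
        if m == 1 or is_dependent(table):
            return table
    raise DegenerateDrawError(
        f"failed to draw a dependent table after {max_retries} retries"
    )


def _rank_tol(columns: np.ndarray) -> float:
    s_max = np.linalg.norm(columns, 2)
    return max(columns.shape) * np.finfo(float).eps * s_max


def is_dependent(table: ConditionalTable, tol: float | None = None) -> bool:
    """Rank criterion for conditional dependence.

    The child is conditionally dependent on its ancestors iff the numerical
    column rank of the table is at least two.  ``tol`` is the singular-value
    cutoff; default ``max(n, m) * eps * sigma_max``.
    """
    cols = table.columns
    if tol is None:
        tol = _rank_tol(cols)
    rank = int(np.linalg.matrix_rank(cols, tol=tol))
    return rank >= 2


def dependence_oracle(
    table: ConditionalTable, pY: np.ndarray, tol: float = 1e-9
) -> bool:
    """Literal dependence criterion, used as a brute-force oracle.

    Forms the induced marginal ``P(X) = D @ pY`` and reports whether some
    column differs from it by more than ``tol`` in max-norm — the existence
    of at least one dependent ancestor event.  Requires a strictly positive
    (full-support) ancestor distribution.
    """
    pY = np.asarray(pY, dtype=float)
    if pY.shape != (table.n_events,):
        raise InvalidArgumentError(
            f"prior length {pY.shape} != event count {table.n_events}"
        )
    if np.any(pY <= 0):
        raise InvalidArgumentError(
            "the event-wise criterion requires a full-support ancestor prior"
        )
    px = table.columns @ pY
    return bool(np.max(np.abs(table.columns - px[:, None])) > tol)


def _distinct_column_groups(
    columns: np.ndarray, tol: float
) -> list[list[int]]:
    """Group column indices whose columns coincide within max-norm tol."""
    groups: list[list[int]] = []
    for j in range(columns.shape[1]):
        for g in groups:
            if np.max(np.abs(columns[:, j] - columns[:, g[0]])) <= tol:
                g.append(j)
                break
        else:
            groups.append([j])
    return groups


def _in_convex_hull(point: np.ndarray, others: np.ndarray, tol: float) -> bool:
    """Is ``point`` within ``tol`` (max-norm) of the hull of ``others``?

    Solved as the LP  min t  s.t.  |others @ w - point| <= t elementwise,
    sum(w) = 1, w >= 0.
    """
    n, k = others.shape
    if k == 0:
        return False
    # variables: w (k), t (1)
    c = np.zeros(k + 1)
    c[-1] = 1.0
    A_ub = np.zeros((2 * n, k + 1))
    A_ub[:n, :k] = others
    A_ub[n:, :k] = -others
    A_ub[:, -1] = -1.0
    b_ub = np.concatenate([point, -point])
    A_eq = np.zeros((1, k + 1))
    A_eq[0, :k] = 1.0
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=[1.0],
        bounds=[(0, None)] * k + [(0, None)],
        method="highs",
    )
    if not res.success:  # pragma: no cover - highs always solves this LP
        return False
    return res.fun <= tol


def hull_vertices(table: ConditionalTable, tol: float = 1e-9) -> set[int]:
    """Column indices that are vertices of the convex hull of the columns.

    A vertex column is one not expressible as a convex combination of the
    other *distinct* columns — a structurally dependent ancestor event
    (dependent under every full-support prior).  Duplicate columns are
    collapsed to one representative before the per-column linear-feasibility
    test; every duplicate of a vertex representative is reported as a
    vertex.  A single distinct column yields its lowest index only.
    """
    cols = table.columns
    groups = _distinct_column_groups(cols, tol)
    if len(groups) == 1:
        return {groups[0][0]}
    reps = np.column_stack([cols[:, g[0]] for g in groups])
    verts: set[int] = set()
    for i, g in enumerate(groups):
        others = np.delete(reps, i, axis=1)
        if not _in_convex_hull(reps[:, i], others, tol):
            verts.update(g)
    return verts


def induced_marginal(table: ConditionalTable, pY: np.ndarray) -> np.ndarray:
    """Marginal of the child under ancestor distribution ``pY``: ``D @ pY``.

    The result always lies in the convex hull of the table's columns.
    """
    pY = np.asarray(pY, dtype=float)
    if pY.shape != (table.n_events,):
        raise InvalidArgumentError(
            f"prior length {pY.shape} != event count {table.n_events}"
        )
    if np.any(pY < -_SIMPLEX_ATOL) or abs(pY.sum() - 1.0) > 1e-9:
        raise InvalidArgumentError("pY must lie on the probability simplex")
    return table.columns @ pY


@dataclass(frozen=True)
class BayesNetModel:
    """A discrete Bayesian network: structure, arities and one table per node.

    Every node's table is conditioned on its structural parents taken in
    canonical order (sorted by topological position); root nodes carry a
    single-column table holding their unconditional distribution.
    """

    structure: DagStructure
    arities: tuple[int, ...]
    tables: tuple[ConditionalTable, ...]
    labels: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.structure.n_nodes
        object.__setattr__(self, "arities", tuple(int(a) for a in self.arities))
        if len(self.arities) != n:
            raise InvalidArgumentError("one arity per node required")
        if any(a < 2 for a in self.arities):
            raise InvalidArgumentError("arities must be >= 2")
        if len(self.tables) != n:
            raise InvalidArgumentError("one table per node required")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"X{i}" for i in range(n))
            )
        if len(set(self.labels)) != n:
            raise InvalidArgumentError("node labels must be unique")
        for v in range(n):
            t = self.tables[v]
            expected = tuple(self.arities[p] for p in self.structure.parents(v))
            if t.child_arity != self.arities[v]:
                raise InvalidArgumentError(
                    f"table of node {v} has child arity {t.child_arity}, "
                    f"expected {self.arities[v]}"
                )
            if t.ancestor_arities != expected:
                raise InvalidArgumentError(
                    f"table of node {v} conditions on arities "
                    f"{t.ancestor_arities}, expected {expected}"
                )

    @property
    def n_nodes(self) -> int:
        return self.structure.n_nodes

    def parents(self, node: int) -> tuple[int, ...]:
        """Structural parents of ``node`` in canonical order."""
        return self.structure.parents(node)

    def n_joint_events(self) -> int:
        """Size of the full joint event space (product of arities)."""
        return int(np.prod(self.arities, dtype=object))


def random_model(
    n_nodes: int,
    arities,
    density,
    alpha,
    rng: np.random.Generator,
    *,
    labels: tuple[str, ...] = (),
    n_vertex_columns: int | None = None,
) -> BayesNetModel:
    """Draw a complete random model: structure plus all conditional tables.

    ``arities`` may be a scalar (shared by all nodes) or one value per node;
    ``density`` is a :class:`~bnforge.graphs.DensitySpec`.  Every table
    column (including root unconditional distributions) is a
    ``Dirichlet(alpha)`` draw.
    """
    from .graphs import sample_dag

    ar = tuple(
        int(a) for a in np.broadcast_to(np.asarray(arities, dtype=int), (n_nodes,))
    )
    dag = sample_dag(n_nodes, density, rng)
    tables = []
    for v in range(n_nodes):
        pa_ar = tuple(ar[p] for p in dag.parents(v))
        m = int(np.prod(pa_ar)) if pa_ar else 1
        k = n_vertex_columns if (pa_ar and n_vertex_columns and m >= n_vertex_columns) else None
        tables.append(build_cpt(ar[v], pa_ar, alpha, rng, n_vertex_columns=k))
    tables = tuple(tables)
    return BayesNetModel(structure=dag, arities=ar, tables=tables, labels=labels)
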