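"""Random DAG structures and the combinatorics of the model space.

A directed acyclic graph on ``n`` nodes with a fixed topological ordering is
an arbitrary subset of the ``D = n(n-1)/2`` ordered pairs running from an
earlier to a later node in that ordering — a triangular extraction from a
symmetric adjacency matrix.  Acyclicity is therefore structural: edges are
only ever created forward along the ordering, and no cycle check is needed.

The number of structures with exactly ``d`` edges is the binomial
coefficient ``C(D, d)``, so a uniform draw over all ``2**D`` structures is
strongly biased toward medium densities (``d`` near ``D/2``).  The helpers
here expose that density distribution exactly (arbitrary-precision
integers) and provide three sampling modes: uniform over all structures,
uniform over a fixed density stratum, and independent per-edge inclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal

import networkx as nx
import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "DagStructure",
    "DensitySpec",
    "max_density",
    "config_count",
    "density_pmf",
    "sample_dag",
    "to_networkx",
    "write_dot",
    "write_graphml",
]


@dataclass(frozen=True)
class DagStructure:
    """A DAG given by a topological ordering and forward edges.

    Parameters
    ----------
    n_nodes:
        Number of nodes; nodes are labelled ``0 .. n_nodes-1``.
    order:
        Permutation of the node labels giving the topological ordering.
    edges:
        Set of ordered pairs ``(ancestor, descendant)``; every edge must run
        from an earlier to a later node in ``order``.
    """

    n_nodes: int
    order: tuple[int, ...]
    edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.n_nodes < 1:
            raise InvalidArgumentError("n_nodes must be >= 1")
        if sorted(self.order) != list(range(self.n_nodes)):
            raise InvalidArgumentError(
                "order must be a permutation of 0..n_nodes-1"
            )
        pos = {node: i for i, node in enumerate(self.order)}
        for a, b in self.edges:
            if a == b:
                raise InvalidArgumentError(f"self-edge on node {a}")
            if pos[a] >= pos[b]:
                raise InvalidArgumentError(
                    f"edge ({a}, {b}) runs against the topological ordering"
                )

    @property
    def density(self) -> int:
        """Number of edges."""
        return len(self.edges)

    def position(self, node: int) -> int:
        """Index of ``node`` in the topological ordering."""
        return self.order.index(node)

    def parents(self, node: int) -> tuple[int, ...]:
        """Immediate ancestors of ``node``, sorted by topological position."""
        pos = {v: i for i, v in enumerate(self.order)}
        return tuple(
            sorted((a for a, b in self.edges if b == node), key=pos.__getitem__)
        )

    def children(self, node: int) -> tuple[int, ...]:
        """Immediate descendants of ``node``, sorted by topological position."""
        pos = {v: i for i, v in enumerate(self.order)}
        return tuple(
            sorted((b for a, b in self.edges if a == node), key=pos.__getitem__)
        )

    def roots(self) -> tuple[int, ...]:
        """Nodes with no parents, in topological order."""
        has_parent = {b for _, b in self.edges}
        return tuple(v for v in self.order if v not in has_parent)

    def terminals(self) -> tuple[int, ...]:
        """Nodes with no children, in topological order."""
        has_child = {a for a, _ in self.edges}
        return tuple(v for v in self.order if v not in has_child)


@dataclass(frozen=True)
class DensitySpec:
    """How densely to wire a random DAG.

    ``mode`` is one of:

    - ``"uniform"``: every one of the ``2**D`` edge subsets equiprobable
      (each potential edge included independently with probability 1/2);
    - ``"fixed"``: uniform over the ``C(D, d)`` subsets of exactly ``d``
      edges;
    - ``"prob"``: each potential edge included independently with
      probability ``p``.
    """

    mode: Literal["uniform", "fixed", "prob"]
    d: int | None = None
    p: float | None = None

    def __post_init__(self):
        if self.mode not in ("uniform", "fixed", "prob"):
            raise InvalidArgumentError(f"unknown density mode {self.mode!r}")
        if self.mode == "fixed":
            if self.d is None or self.d < 0:
                raise InvalidArgumentError("fixed mode requires d >= 0")
        if self.mode == "prob":
            if self.p is None or not (0.0 <= self.p <= 1.0):
                raise InvalidArgumentError("prob mode requires 0 <= p <= 1")


def max_density(n: int) -> int:
    """Maximum number of edges ``D = n(n-1)/2`` of a DAG on ``n`` nodes."""
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    return n * (n - 1) // 2


def config_count(n: int, d: int) -> int:
    """Exact number of DAG structures with ``n`` nodes and ``d`` edges.

    Computed as ``C(D, d)`` with ``D = max_density(n)`` in arbitrary-precision
    integer arithmetic (values like ``C(120, 60)`` overflow fixed width).
    """
    D = max_density(n)
    if not 0 <= d <= D:
        raise InvalidArgumentError(f"density d={d} outside [0, {D}]")
    return math.comb(D, d)


def density_pmf(n: int, d: int) -> float:
    """Probability that a uniformly drawn structure has exactly ``d`` edges.

    Equals ``C(D, d) / 2**D``; over all ``d`` these sum to one.
    """
    D = max_density(n)
    if not 0 <= d <= D:
        raise InvalidArgumentError(f"density d={d} outside [0, {D}]")
    # Exact rational reduced via Fraction-free float conversion: the float
    # of an integer ratio is correctly rounded in Python.
    return math.comb(D, d) / (1 << D)


def _potential_edges(order: tuple[int, ...]) -> list[tuple[int, int]]:
    return [
        (order[i], order[j])
        for i in range(len(order))
        for j in range(i + 1, len(order))
    ]


def sample_dag(
    n: int,
    spec: DensitySpec,
    rng: np.random.Generator,
    *,
    permute_labels: bool = False,
) -> DagStructure:
    """Draw a random DAG structure on ``n`` nodes.

    Edges are generated in the upper triangle under the identity ordering;
    with ``permute_labels`` a random label permutation is applied afterwards
    (the topological ordering is carried along, so acyclicity is preserved).

    Modes (see :class:`DensitySpec`): ``uniform`` makes all ``2**D``
    structures equiprobable, ``fixed`` is uniform over structures of exactly
    ``d`` edges, ``prob`` includes each potential edge independently with
    probability ``p``.
    """
    D = max_density(n)
    order = tuple(range(n))
    if permute_labels:
        order = tuple(int(v) for v in rng.permutation(n))
    potential = _potential_edges(order)

    if spec.mode == "fixed":
        if spec.d > D:
            raise InvalidArgumentError(
                f"fixed density d={spec.d} exceeds maximum D={D}"
            )
        idx = rng.choice(D, size=spec.d, replace=False) if spec.d else []
        chosen = [potential[i] for i in idx]
    else:
        p = 0.5 if spec.mode == "uniform" else spec.p
        mask = rng.random(D) < p
        chosen = [e for e, keep in zip(potential, mask) if keep]

    return DagStructure(n_nodes=n, order=order, edges=frozenset(chosen))


def to_networkx(dag: DagStructure, labels: tuple[str, ...] | None = None) -> nx.DiGraph:
    """Convert to a :class:`networkx.DiGraph` with string node labels."""
    labels = labels or tuple(f"X{i}" for i in range(dag.n_nodes))
    g = nx.DiGraph()
    g.add_nodes_from(labels[v] for v in dag.order)
    g.add_edges_from((labels[a], labels[b]) for a, b in sorted(dag.edges))
    return g


def write_dot(dag: DagStructure, path, labels: tuple[str, ...] | None = None) -> None:
    """Write the structure as a GraphViz DOT digraph."""
    labels = labels or tuple(f"X{i}" for i in range(dag.n_nodes))
    lines = ["digraph G {"]
    lines += [f'  "{labels[v]}";' for v in dag.order]
    lines += [f'  "{labels[a]}" -> "{labels[b]}";' for a, b in sorted(dag.edges)]
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_graphml(dag: DagStructure, path, labels: tuple[str, ...] | None = None) -> None:
    """Write the structure as GraphML (directed)."""
    nx.write_graphml(to_networkx(dag, labels), path)


def density_histogram(n: int) -> np.ndarray:
    """The full density probability vector ``d = 0..D`` (sums to one)."""
    D = max_density(n)
    return np.array([density_pmf(n, d) for d in range(D + 1)])


def iter_fixed_density_structures(n: int, d: int) -> Iterator[frozenset]:
    """Enumerate all edge sets of density ``d`` (tiny ``n`` only; used as a
    brute-force oracle in tests)."""
    from itertools import combinations

    for combo in combinations(_potential_edges(tuple(range(n))), d):
        yield frozenset(combo)
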