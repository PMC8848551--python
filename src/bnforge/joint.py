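"""Exact joint distributions, divergence, and sample-size diagnostics.

Because the network's joint probability factorises into the product of its
conditional tables, the full joint over all nodes can be computed exactly as
long as the event space (product of arities) stays enumerable.  Exactness at
desk scale is the design point: above the cap we raise rather than
approximate.  Eight tertiary nodes give 3**8 = 6561 joint events.

Events are encoded mixed-radix over node arities in model node order, first
node most significant; datasets sampled from a model are comparable to the
analytic joint through the same encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr
from scipy.stats import binom

from .cpt import BayesNetModel
from .errors import (
    BoundNotAttainedError,
    DataIntegrityError,
    EventSpaceTooLargeError,
    InvalidArgumentError,
)
from .sampling import Dataset

__all__ = [
    "JointTable",
    "enumerate_joint",
    "node_marginals",
    "ancestral_marginal",
    "empirical_joint",
    "jsd",
    "required_sample_size",
]

DEFAULT_EVENT_CAP = 10**7


@dataclass(frozen=True)
class JointTable:
    """Exact or empirical probability over the full joint event space.

    ``probs[e]`` is the probability of the joint assignment whose
    mixed-radix code is ``e`` (node arities in model order, first node most
    significant).
    """

    arities: tuple[int, ...]
    probs: np.ndarray

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        k = int(np.prod(self.arities, dtype=object))
        if probs.shape != (k,):
            raise InvalidArgumentError(
                f"probs length {probs.shape} != event count {k}"
            )
        if np.any(probs < -1e-12):
            raise InvalidArgumentError("probabilities must be non-negative")
        if abs(probs.sum() - 1.0) > 1e-10:
            raise InvalidArgumentError(
                f"joint table sums to {probs.sum():.12g}, not 1"
            )

    @property
    def n_events(self) -> int:
        return self.probs.shape[0]

    def event(self, code: int) -> tuple[int, ...]:
        """Decode an event index into a per-node assignment."""
        return tuple(int(s) for s in np.unravel_index(code, self.arities))

    def marginal(self, node: int) -> np.ndarray:
        """Marginal distribution of one node."""
        axes = tuple(i for i in range(len(self.arities)) if i != node)
        return self.probs.reshape(self.arities).sum(axis=axes)


def _check_cap(size: int, cap: int) -> None:
    if size > cap:
        raise EventSpaceTooLargeError(size, cap)


def _factorized_probs(
    model: BayesNetModel, nodes: tuple[int, ...], arities: tuple[int, ...]
) -> np.ndarray:
    """Joint probabilities over the given (ancestrally closed) node subset.

    Every node in ``nodes`` must have all its parents in ``nodes``; the
    joint over the subset then factorises exactly as the product of the
    nodes' own tables.
    """
    k = int(np.prod(arities))
    pos = {v: i for i, v in enumerate(nodes)}
    strides = np.ones(len(nodes), dtype=np.int64)
    for i in range(len(nodes) - 2, -1, -1):
        strides[i] = strides[i + 1] * arities[i + 1]
    codes = np.arange(k, dtype=np.int64)

    def state(v: int) -> np.ndarray:
        i = pos[v]
        return (codes // strides[i]) % arities[i]

    probs = np.ones(k)
    for v in nodes:
        table = model.tables[v]
        pa = model.parents(v)
        if pa:
            col = np.ravel_multi_index(
                tuple(state(p) for p in pa), table.ancestor_arities
            )
        else:
            col = np.zeros(k, dtype=np.intp)
        probs *= table.columns[state(v), col]
    return probs


def enumerate_joint(model: BayesNetModel, cap: int = DEFAULT_EVENT_CAP) -> JointTable:
    """Exact joint probability of every full assignment.

    Each event's probability is the product over nodes of the table entry
    selected by the assignment.  Raises
    :class:`~bnforge.errors.EventSpaceTooLargeError` above ``cap``.
    """
    k = model.n_joint_events()
    _check_cap(k, cap)
    nodes = tuple(range(model.n_nodes))
    probs = _factorized_probs(model, nodes, model.arities)
    return JointTable(arities=model.arities, probs=probs)


def node_marginals(model: BayesNetModel, cap: int = DEFAULT_EVENT_CAP) -> list[np.ndarray]:
    """Exact marginal distribution of every node, from the full joint."""
    jt = enumerate_joint(model, cap=cap)
    return [jt.marginal(v) for v in range(model.n_nodes)]


def _ancestral_closure(model: BayesNetModel, nodes) -> tuple[int, ...]:
    closure = set(nodes)
    frontier = list(nodes)
    while frontier:
        v = frontier.pop()
        for p in model.parents(v):
            if p not in closure:
                closure.add(p)
                frontier.append(p)
    return tuple(sorted(closure))


def ancestral_marginal(
    model: BayesNetModel, nodes, cap: int = DEFAULT_EVENT_CAP
) -> tuple[tuple[int, ...], np.ndarray]:
    """Exact joint marginal over a node subset via its ancestral closure.

    Enumerates only the closure (the subset plus all its ancestors) — the
    joint over a closed set factorises exactly — and marginalises down to
    the requested nodes.  Returns the nodes in sorted order together with
    their joint probability vector (mixed-radix encoded).

    This is the "propagate from the roots" route to marginals: it never
    touches nodes outside the ancestral closure, unlike marginalising the
    full joint.
    """
    nodes = tuple(sorted(set(int(v) for v in nodes)))
    if not all(0 <= v < model.n_nodes for v in nodes):
        raise InvalidArgumentError("node index out of range")
    if not nodes:
        return (), np.ones(1)
    closure = _ancestral_closure(model, nodes)
    cl_ar = tuple(model.arities[v] for v in closure)
    k = int(np.prod(cl_ar, dtype=object))
    _check_cap(k, cap)
    probs = _factorized_probs(model, closure, cl_ar)
    keep = tuple(closure.index(v) for v in nodes)
    axes = tuple(i for i in range(len(closure)) if i not in keep)
    marg = probs.reshape(cl_ar).sum(axis=axes) if axes else probs.reshape(cl_ar)
    # reshape keeps kept axes in closure (sorted) order == nodes order
    return nodes, marg.reshape(-1)


def empirical_joint(dataset: Dataset, model: BayesNetModel) -> JointTable:
    """Normalised event counts of a dataset over the model's event space.

    Events never observed get probability zero.  Dataset columns are
    matched to model nodes by label.
    """
    values = dataset.values
    if tuple(dataset.columns) != tuple(model.labels):
        try:
            perm = [dataset.columns.index(lab) for lab in model.labels]
        except ValueError as exc:
            raise DataIntegrityError(
                f"dataset columns {dataset.columns} do not match model "
                f"labels {model.labels}"
            ) from exc
        values = values[:, perm]
    for j, a in enumerate(model.arities):
        col = values[:, j]
        if col.min() < 0 or col.max() >= a:
            bad = int(np.argmax((col < 0) | (col >= a)))
            raise DataIntegrityError(
                f"row {bad}: state {col[bad]} of node {model.labels[j]} "
                f"outside [0, {a})"
            )
    k = model.n_joint_events()
    _check_cap(k, DEFAULT_EVENT_CAP)
    codes = np.ravel_multi_index(tuple(values.T), model.arities)
    counts = np.bincount(codes, minlength=k)
    return JointTable(arities=model.arities, probs=counts / values.shape[0])


def _prob_vector(p) -> np.ndarray:
    if isinstance(p, JointTable):
        return p.probs
    return np.asarray(p, dtype=float)


def jsd(p, q, base: float = 2.0) -> float:
    """Jensen-Shannon divergence between two distributions.

    ``JSD(p, q) = KL(p||m)/2 + KL(q||m)/2`` with ``m = (p+q)/2``; in base 2
    (the default) it is bounded by 1, reached for disjoint supports.
    ``0 log 0`` terms contribute zero.
    """
    pv, qv = _prob_vector(p), _prob_vector(q)
    if pv.shape != qv.shape:
        raise InvalidArgumentError(f"shape mismatch {pv.shape} vs {qv.shape}")
    for name, v in (("p", pv), ("q", qv)):
        if np.any(v < -1e-12) or abs(v.sum() - 1.0) > 1e-6:
            raise InvalidArgumentError(f"{name} is not a normalized distribution")
    m = 0.5 * (pv + qv)
    div_nats = 0.5 * rel_entr(pv, m).sum() + 0.5 * rel_entr(qv, m).sum()
    return float(max(div_nats, 0.0) / np.log(base))


def _exceedance_mc(
    p: np.ndarray, n: int, thr: float, rng: np.random.Generator, n_replicates: int
) -> float:
    draws = rng.multinomial(n, p, size=n_replicates)
    dev = np.abs(draws - n * p).max(axis=1)
    return float(np.mean(dev > thr))


def _exceedance_union(p: np.ndarray, n: int, thr: float) -> float:
    mu = n * p
    upper = binom.sf(np.floor(mu + thr), n, p)
    lower = binom.cdf(np.ceil(mu - thr) - 1.0, n, p)
    return float(min(1.0, (upper + lower).sum()))


def required_sample_size(
    p,
    delta: float,
    eps: float,
    method: str = "monte-carlo",
    rng: np.random.Generator | None = None,
    *,
    delta_mode: str = "fraction",
    n_replicates: int = 400,
    n_min: int = 1,
    n_cap: int = 2**24,
) -> int:
    """Smallest sample size keeping the worst event-count deviation small.

    Finds (on a doubling-then-bisection integer grid) the least ``N`` such
    that the estimated probability of ``max_i |N p_i - x_i|`` exceeding the
    tolerance is below ``eps``, where ``x`` are multinomial counts of ``N``
    draws from ``p``.

    ``delta_mode="fraction"`` (default) reads ``delta`` as a fraction of
    ``N`` (tolerance ``delta * N`` counts), which shrinks the allowed
    *relative* error and is satisfiable for any ``eps``;
    ``delta_mode="count"`` reads ``delta`` as an absolute count and raises
    :class:`~bnforge.errors.BoundNotAttainedError` when no ``N`` up to
    ``n_cap`` meets it (count deviations grow like sqrt(N), so small
    ``eps`` may be unattainable).

    ``method="monte-carlo"`` estimates the exceedance probability from
    ``n_replicates`` multinomial draws; ``method="union-bound"`` sums exact
    per-event binomial tails — conservative, hence never smaller.
    """
    pv = _prob_vector(p)
    if abs(pv.sum() - 1.0) > 1e-6 or np.any(pv < -1e-12):
        raise InvalidArgumentError("p is not a normalized distribution")
    if delta <= 0:
        raise InvalidArgumentError("delta must be positive")
    if not 0 < eps < 1:
        raise InvalidArgumentError("eps must lie in (0, 1)")
    if delta_mode not in ("fraction", "count"):
        raise InvalidArgumentError(f"unknown delta_mode {delta_mode!r}")
    if method not in ("monte-carlo", "union-bound"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    if method == "monte-carlo" and rng is None:
        raise InvalidArgumentError("monte-carlo method requires a seeded rng")

    def passes(n: int) -> bool:
        thr = delta * n if delta_mode == "fraction" else delta
        if method == "monte-carlo":
            est = _exceedance_mc(pv, n, thr, rng, n_replicates)
        else:
            est = _exceedance_union(pv, n, thr)
        return est < eps

    n = max(1, int(n_min))
    if passes(n):
        return n
    lo = n  # known failure
    while True:
        n *= 2
        if n > n_cap:
            raise BoundNotAttainedError(n_cap)
        if passes(n):
            break
        lo = n
    hi = n  # known pass
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if passes(mid):
            hi = mid
        else:
            lo = mid
    return hi
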