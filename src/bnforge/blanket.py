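"""Markov-blanket extraction and factored local inference.

The Markov blanket of a node ``X`` — its immediate ancestors ``a(X)``,
immediate descendants ``d(X)``, and co-ancestors ``ad(X)`` (the other
ancestors of its descendants) — renders ``X`` conditionally independent of
the rest of the network.  The joint over the blanket members factors as

    P(M) = P(a(X) u ad(X)) * P(X | a(X)) * prod_{Y in d(X)} P(Y | a(Y))

where the upstream block ``P(a(X) u ad(X))`` is computed exactly over its
ancestral closure.  Evaluating co-ancestors jointly (rather than one
``P(Z | a(Z))`` factor each) keeps the factorization exact even when
co-ancestors share out-of-blanket ancestors.  The one remaining structural
caveat — a co-ancestor that is itself a *deeper* descendant of ``X`` —
cannot be captured by any upstream/downstream split; in that case the
factored joint may deviate from the true blanket marginal, but conditionals
of the center given the periphery are still exact, because the upstream
block does not depend on the center's state and cancels in the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cpt import BayesNetModel
from .errors import InvalidArgumentError, UndefinedConditionalError
from .joint import DEFAULT_EVENT_CAP, ancestral_marginal

__all__ = [
    "Blanket",
    "BlanketDistribution",
    "blanket",
    "blanket_joint",
    "center_conditional",
    "periphery_inference",
    "is_locally_factorable",
]


@dataclass(frozen=True)
class Blanket:
    """Markov blanket membership of a center node.

    ``ancestors`` and ``descendants`` are the *immediate* ones only;
    ``co_ancestors`` are ancestors of the descendants excluding the center,
    its ancestors and its descendants.  ``members`` is the union including
    the center.
    """

    center: int
    ancestors: tuple[int, ...]
    descendants: tuple[int, ...]
    co_ancestors: tuple[int, ...]

    @property
    def members(self) -> tuple[int, ...]:
        return tuple(
            sorted(
                {self.center}
                | set(self.ancestors)
                | set(self.descendants)
                | set(self.co_ancestors)
            )
        )

    @property
    def periphery(self) -> tuple[int, ...]:
        """Members other than the center."""
        return tuple(v for v in self.members if v != self.center)


def _check_node(model: BayesNetModel, node: int) -> None:
    if not 0 <= node < model.n_nodes:
        raise InvalidArgumentError(f"unknown node {node}")


def blanket(model: BayesNetModel, center: int) -> Blanket:
    """Compute the Markov blanket of ``center``."""
    _check_node(model, center)
    a = set(model.structure.parents(center))
    d = set(model.structure.children(center))
    ad = set()
    for y in d:
        ad.update(model.structure.parents(y))
    ad -= {center} | a | d
    return Blanket(
        center=center,
        ancestors=tuple(sorted(a)),
        descendants=tuple(sorted(d)),
        co_ancestors=tuple(sorted(ad)),
    )


def _descendants_transitive(model: BayesNetModel, node: int) -> set[int]:
    out: set[int] = set()
    frontier = [node]
    while frontier:
        v = frontier.pop()
        for c in model.structure.children(v):
            if c not in out:
                out.add(c)
                frontier.append(c)
    return out


def is_locally_factorable(model: BayesNetModel, center: int) -> bool:
    """True when no co-ancestor of ``center`` is one of its descendants.

    Under this (generic) structural condition the factored blanket joint
    equals the exact marginal over the blanket members.
    """
    b = blanket(model, center)
    return not (set(b.co_ancestors) & _descendants_transitive(model, center))


class BlanketDistribution:
    """Factored joint distribution over a node's Markov blanket.

    Precomputes the exact upstream block ``P(a(X) u ad(X))`` once (over its
    ancestral closure), after which single-assignment joints and
    conditionals are table lookups and products.
    """

    def __init__(
        self, model: BayesNetModel, center: int, cap: int = DEFAULT_EVENT_CAP
    ):
        _check_node(model, center)
        self.model = model
        self.blanket = blanket(model, center)
        self.center = center
        b = self.blanket
        self._upstream_nodes = tuple(sorted(set(b.ancestors) | set(b.co_ancestors)))
        if self._upstream_nodes:
            _, self._upstream_probs = ancestral_marginal(
                model, self._upstream_nodes, cap=cap
            )
        else:
            self._upstream_probs = np.ones(1)
        self._upstream_arities = tuple(
            model.arities[v] for v in self._upstream_nodes
        )

    def _normalize_assignment(self, assignment: dict) -> dict[int, int]:
        label_to_node = {lab: i for i, lab in enumerate(self.model.labels)}
        out: dict[int, int] = {}
        for key, val in assignment.items():
            node = label_to_node.get(key, key) if isinstance(key, str) else key
            if isinstance(node, str) or not 0 <= node < self.model.n_nodes:
                raise InvalidArgumentError(f"unknown node {key!r}")
            val = int(val)
            if not 0 <= val < self.model.arities[node]:
                raise InvalidArgumentError(
                    f"state {val} of node {key!r} outside "
                    f"[0, {self.model.arities[node]})"
                )
            out[node] = val
        return out

    def joint(self, assignment: dict) -> float:
        """Factored joint probability of a full blanket-member assignment."""
        asg = self._normalize_assignment(assignment)
        if set(asg) != set(self.blanket.members):
            raise InvalidArgumentError(
                f"assignment must cover exactly the blanket members "
                f"{self.blanket.members}, got {tuple(sorted(asg))}"
            )
        prob = 1.0
        if self._upstream_nodes:
            code = int(
                np.ravel_multi_index(
                    tuple(asg[v] for v in self._upstream_nodes),
                    self._upstream_arities,
                )
            )
            prob *= float(self._upstream_probs[code])
        x = self.center
        prob *= float(
            self.model.tables[x].column(
                [asg[p] for p in self.model.parents(x)]
            )[asg[x]]
        )
        for y in self.blanket.descendants:
            prob *= float(
                self.model.tables[y].column(
                    [asg[p] for p in self.model.parents(y)]
                )[asg[y]]
            )
        return prob

    def joint_table(self) -> np.ndarray:
        """Factored joint over every blanket-member assignment.

        Shape: the member arities, axes in sorted member order.
        """
        members = self.blanket.members
        ar = tuple(self.model.arities[v] for v in members)
        k = int(np.prod(ar)) if ar else 1
        pos = {v: i for i, v in enumerate(members)}
        codes = np.arange(k, dtype=np.int64)
        strides = np.ones(len(members), dtype=np.int64)
        for i in range(len(members) - 2, -1, -1):
            strides[i] = strides[i + 1] * ar[i + 1]

        def state(v: int) -> np.ndarray:
            i = pos[v]
            return (codes // strides[i]) % ar[i]

        probs = np.ones(k)
        if self._upstream_nodes:
            up_code = np.ravel_multi_index(
                tuple(state(v) for v in self._upstream_nodes),
                self._upstream_arities,
            )
            probs *= self._upstream_probs[up_code]
        for v in (self.center, *self.blanket.descendants):
            table = self.model.tables[v]
            pa = self.model.parents(v)
            if pa:
                col = np.ravel_multi_index(
                    tuple(state(p) for p in pa), table.ancestor_arities
                )
            else:
                col = np.zeros(k, dtype=np.intp)
            probs *= table.columns[state(v), col]
        return probs.reshape(ar)

    def center_conditional(self, periphery: dict) -> np.ndarray:
        """Distribution of the center given a full periphery assignment."""
        asg = self._normalize_assignment(periphery)
        if set(asg) != set(self.blanket.periphery):
            raise InvalidArgumentError(
                f"periphery assignment must cover exactly "
                f"{self.blanket.periphery}, got {tuple(sorted(asg))}"
            )
        arity = self.model.arities[self.center]
        nums = np.array(
            [self.joint({**asg, self.center: x}) for x in range(arity)]
        )
        total = nums.sum()
        if total <= 0.0:
            raise UndefinedConditionalError(
                "periphery assignment has probability zero; the conditional "
                "is undefined"
            )
        return nums / total

    def center_conditional_table(self) -> np.ndarray:
        """Center conditional for every periphery assignment at once.

        Shape: member arities with the center axis last normalised; entries
        are NaN where the periphery assignment has probability zero.
        """
        members = self.blanket.members
        axis = members.index(self.center)
        jt = self.joint_table()
        denom = jt.sum(axis=axis, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = jt / denom
        return cond

    def periphery_inference(
        self, center_state: int, target: int, rest: dict
    ) -> np.ndarray:
        """Distribution of a periphery node given the center's state and
        the remaining periphery assignment."""
        if isinstance(target, str):
            target = {lab: i for i, lab in enumerate(self.model.labels)}.get(
                target, -1
            )
        if target not in self.blanket.periphery:
            raise InvalidArgumentError(
                f"target must be a periphery member of node {self.center}"
            )
        asg = self._normalize_assignment(rest)
        expected = set(self.blanket.periphery) - {target}
        if set(asg) != expected:
            raise InvalidArgumentError(
                f"rest must cover exactly {tuple(sorted(expected))}"
            )
        if not 0 <= center_state < self.model.arities[self.center]:
            raise InvalidArgumentError("center state out of range")
        arity = self.model.arities[target]
        nums = np.array(
            [
                self.joint({**asg, self.center: center_state, target: z})
                for z in range(arity)
            ]
        )
        total = nums.sum()
        if total <= 0.0:
            raise UndefinedConditionalError(
                "conditioning assignment has probability zero; the "
                "conditional is undefined"
            )
        return nums / total


def blanket_joint(model: BayesNetModel, b: Blanket, assignment: dict) -> float:
    """Factored joint probability of a blanket-member assignment."""
    dist = BlanketDistribution(model, b.center)
    return dist.joint(assignment)


def center_conditional(
    model: BayesNetModel, center: int, periphery: dict
) -> np.ndarray:
    """P(center | periphery assignment), via the factored blanket joint."""
    return BlanketDistribution(model, center).center_conditional(periphery)


def periphery_inference(
    model: BayesNetModel, center: int, center_state: int, target: int, rest: dict
) -> np.ndarray:
    """P(target periphery node | center state, remaining periphery)."""
    return BlanketDistribution(model, center).periphery_inference(
        center_state, target, rest
    )
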