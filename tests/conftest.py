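import numpy as np
import pytest

import bnforge as bf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def build_model():
    """Factory: explicit model from edges, arities and per-node tables.

    Uses the identity topological order; tables are given as
    (arity, n_parent_events) matrices, parents in canonical order.
    """

    def _build(edges, arities, tables):
        n = len(arities)
        dag = bf.DagStructure(
            n_nodes=n, order=tuple(range(n)), edges=frozenset(edges)
        )
        tabs = tuple(
            bf.ConditionalTable(
                child_arity=arities[v],
                ancestor_arities=tuple(arities[p] for p in dag.parents(v)),
                columns=np.asarray(tables[v], dtype=float),
            )
            for v in range(n)
        )
        return bf.BayesNetModel(
            structure=dag, arities=tuple(arities), tables=tabs
        )

    return _build


@pytest.fixture
def identity_chain(build_model):
    """A -> X -> D with identity 2x2 tables and root prior (0.3, 0.7)."""
    return build_model(
        edges=[(0, 1), (1, 2)],
        arities=(2, 2, 2),
        tables=[
            [[0.3], [0.7]],
            [[1.0, 0.0], [0.0, 1.0]],
            [[1.0, 0.0], [0.0, 1.0]],
        ],
    )


def random_small_model(seed, max_nodes=6, max_arity=3, edge_p=0.5):
    """A seeded random model for oracle sweeps (shared by unit and
    acceptance tests)."""
    r = np.random.default_rng(seed)
    n = int(r.integers(3, max_nodes + 1))
    arities = r.integers(2, max_arity + 1, size=n)
    return bf.random_model(
        n, arities, bf.DensitySpec("prob", p=edge_p), 1.0, r
    )
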