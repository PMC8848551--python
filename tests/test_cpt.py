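"""Conditional tables: simplex sampling, dependence theory, hull geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import bnforge as bf
from bnforge.cpt import _in_convex_hull


class TestSampleSimplex:
    def test_degenerate_dimension(self, rng):
        assert bf.sample_simplex(1, 1.0, rng) == pytest.approx([1.0])

    def test_normalization(self, rng):
        for k in (2, 3, 7):
            v = bf.sample_simplex(k, 1.0, rng)
            assert v.min() >= 0
            assert abs(v.sum() - 1.0) < 1e-12

    def test_flat_marginal_is_uniform_on_1_simplex(self, rng):
        draws = np.array(
            [bf.sample_simplex(2, (1.0, 1.0), rng)[0] for _ in range(20_000)]
        )
        assert stats.kstest(draws, "uniform").pvalue > 0.01

    def test_rejects_nonpositive_alpha(self, rng):
        with pytest.raises(bf.InvalidArgumentError):
            bf.sample_simplex(3, (1.0, 0.0, 1.0), rng)


class TestEventSpace:
    @pytest.mark.parametrize(
        "arities,count", [((2, 2), 4), ((2, 3), 6), ((), 1), ((3, 3), 9)]
    )
    def test_counts(self, arities, count):
        assert bf.ancestor_event_space(arities)[0] == count

    def test_mixed_radix_order_first_ancestor_most_significant(self):
        _, events = bf.ancestor_event_space((2, 3))
        assert list(events) == [
            (0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2)
        ]

    def test_rejects_unary_ancestor(self):
        with pytest.raises(bf.InvalidArgumentError):
            bf.ancestor_event_space((2, 1))

    @given(
        st.lists(st.integers(min_value=2, max_value=4), min_size=0, max_size=4)
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_column_index_is_a_bijection(self, arities):
        arities = tuple(arities)
        count, events = bf.ancestor_event_space(arities)
        table = bf.build_cpt(2, arities, 1.0, np.random.default_rng(0))
        codes = [table.column_index(e) for e in events]
        assert sorted(codes) == list(range(count))


class TestBuildCpt:
    def test_shape_contract(self, rng):
        t = bf.build_cpt(3, (3, 3), 1.0, rng)
        assert t.columns.shape == (3, 9)
        assert np.allclose(t.columns.sum(axis=0), 1.0, atol=1e-12)
        assert t.columns.min() >= 0

    def test_random_tables_are_dependent(self, rng):
        assert all(
            bf.is_dependent(bf.build_cpt(2, (2,), 1.0, rng))
            for _ in range(200)
        )

    def test_invalid_arguments(self, rng):
        with pytest.raises(bf.InvalidArgumentError):
            bf.build_cpt(1, (2,), 1.0, rng)
        with pytest.raises(bf.InvalidArgumentError):
            bf.build_cpt(2, (2, 2), 1.0, rng, n_vertex_columns=1)
        with pytest.raises(bf.InvalidArgumentError):
            bf.build_cpt(2, (2,), 1.0, rng, n_vertex_columns=3)

    def test_vertex_control_bounds_hull_size(self, rng):
        hits = 0
        n_builds = 300
        for _ in range(n_builds):
            t = bf.build_cpt(3, (2, 2), 1.0, rng, n_vertex_columns=2)
            v = bf.hull_vertices(t)
            assert len(v) <= 2
            hits += v == {0, 1}
        assert hits / n_builds >= 0.99


class TestDependence:
    def test_rank_one_table_is_independent(self):
        col = np.array([0.2, 0.8])
        t = bf.ConditionalTable(2, (2,), np.column_stack([col, col]))
        assert not bf.is_dependent(t)

    def test_identity_is_dependent(self):
        t = bf.ConditionalTable(2, (2,), np.eye(2))
        assert bf.is_dependent(t)

    def test_convex_combination_column_keeps_rank_two(self):
        c1, c2 = np.array([0.9, 0.1]), np.array([0.2, 0.8])
        t = bf.ConditionalTable(
            2, (3,), np.column_stack([c1, c2, 0.5 * (c1 + c2)])
        )
        assert bf.is_dependent(t)

    def test_oracle_trivial_cases(self):
        ident = bf.ConditionalTable(2, (2,), np.eye(2))
        assert bf.dependence_oracle(ident, np.array([0.5, 0.5]))
        col = np.array([0.4, 0.6])
        flat = bf.ConditionalTable(2, (2,), np.column_stack([col, col]))
        assert not bf.dependence_oracle(flat, np.array([0.3, 0.7]))

    def test_oracle_requires_full_support(self):
        ident = bf.ConditionalTable(2, (2,), np.eye(2))
        with pytest.raises(bf.InvalidArgumentError):
            bf.dependence_oracle(ident, np.array([1.0, 0.0]))

    def test_rank_criterion_agrees_with_oracle(self, rng):
        """Rank >= 2 iff some column deviates from the induced marginal,
        under every full-support prior (the dependence equivalence)."""
        for _ in range(200):
            n = int(rng.integers(2, 5))
            m = int(rng.integers(2, 9))
            if rng.random() < 0.3:  # rank-one (independent) instance
                col = rng.dirichlet(np.ones(n))
                cols = np.tile(col[:, None], (1, m))
            else:
                cols = rng.dirichlet(np.ones(n), size=m).T
            t = bf.ConditionalTable(n, (m,), cols)
            dep = bf.is_dependent(t)
            for _ in range(5):
                prior = rng.dirichlet(np.ones(m))
                prior = (prior + 1e-3) / (prior + 1e-3).sum()
                assert bf.dependence_oracle(t, prior) == dep


class TestHullVertices:
    def test_standard_basis_all_vertices(self):
        t = bf.ConditionalTable(3, (3,), np.eye(3))
        assert bf.hull_vertices(t) == {0, 1, 2}

    def test_midpoint_is_interior(self):
        v1, v2 = np.array([0.9, 0.1]), np.array([0.1, 0.9])
        t = bf.ConditionalTable(
            2, (3,), np.column_stack([v1, v2, 0.5 * (v1 + v2)])
        )
        assert bf.hull_vertices(t) == {0, 1}

    def test_all_identical_single_representative(self):
        col = np.array([0.5, 0.5])
        t = bf.ConditionalTable(2, (3,), np.tile(col[:, None], (1, 3)))
        assert bf.hull_vertices(t) == {0}

    def test_duplicates_of_vertex_all_reported(self):
        v1, v2 = np.array([0.8, 0.2]), np.array([0.3, 0.7])
        cols = np.column_stack([v1, v1, v2, 0.5 * (v1 + v2)])
        t = bf.ConditionalTable(2, (4,), cols)
        assert bf.hull_vertices(t) == {0, 1, 2}

    def test_rank_vertex_count_event_count_ordering(self, rng):
        """rank <= #dependent events (hull vertices) <= #events."""
        for _ in range(100):
            n = int(rng.integers(2, 5))
            m = int(rng.integers(2, 8))
            t = bf.build_cpt(n, (m,), 1.0, rng)
            r = np.linalg.matrix_rank(t.columns)
            d = len(bf.hull_vertices(t))
            assert r <= d <= m


class TestInducedMarginal:
    def test_identity_returns_prior(self):
        t = bf.ConditionalTable(2, (2,), np.eye(2))
        p = np.array([0.3, 0.7])
        assert np.allclose(bf.induced_marginal(t, p), p)

    def test_rank_one_returns_common_column(self, rng):
        col = rng.dirichlet(np.ones(3))
        t = bf.ConditionalTable(3, (4,), np.tile(col[:, None], (1, 4)))
        for _ in range(5):
            p = rng.dirichlet(np.ones(4))
            assert np.allclose(bf.induced_marginal(t, p), col)

    def test_marginal_lies_in_column_hull(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 5))
            m = int(rng.integers(2, 7))
            t = bf.build_cpt(n, (m,), 1.0, rng)
            p = rng.dirichlet(np.ones(m))
            px = bf.induced_marginal(t, p)
            assert _in_convex_hull(px, t.columns, 1e-7)

    def test_dimension_mismatch(self, rng):
        t = bf.build_cpt(2, (3,), 1.0, rng)
        with pytest.raises(bf.InvalidArgumentError):
            bf.induced_marginal(t, np.array([0.5, 0.5]))


class TestModelValidation:
    def test_mismatched_table_rejected(self):
        dag = bf.DagStructure(2, (0, 1), frozenset({(0, 1)}))
        root = bf.ConditionalTable(2, (), np.array([[0.5], [0.5]]))
        with pytest.raises(bf.InvalidArgumentError):
            bf.BayesNetModel(
                structure=dag, arities=(2, 2), tables=(root, root)
            )

    def test_random_model_tables_match_structure(self, rng):
        m = bf.random_model(6, 3, bf.DensitySpec("prob", p=0.6), 1.0, rng)
        for v in range(6):
            expected = tuple(3 for _ in m.parents(v))
            assert m.tables[v].ancestor_arities == expected
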