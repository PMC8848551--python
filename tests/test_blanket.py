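"""Markov blankets: membership, factored joints, local conditionals."""

import numpy as np
import pytest

import bnforge as bf
from bnforge.blanket import BlanketDistribution, is_locally_factorable
from conftest import random_small_model


def brute_conditional(model, center):
    """P(center | all other nodes) from the exhaustive joint (oracle)."""
    jt = bf.enumerate_joint(model)
    full = jt.probs.reshape(jt.arities)
    denom = full.sum(axis=center, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return full, full / denom


class TestMembership:
    def test_chain(self, identity_chain):
        b = bf.blanket(identity_chain, 1)
        assert b.ancestors == (0,)
        assert b.descendants == (2,)
        assert b.co_ancestors == ()
        assert b.members == (0, 1, 2)

    def test_collider_includes_co_ancestor(self, build_model):
        # X -> C <- Z : Z enters X's blanket as a co-ancestor
        model = build_model(
            edges=[(0, 2), (1, 2)],
            arities=(2, 2, 2),
            tables=[
                [[0.5], [0.5]],
                [[0.4], [0.6]],
                np.full((2, 4), 0.5),
            ],
        )
        b = bf.blanket(model, 0)
        assert b.co_ancestors == (1,)
        assert b.members == (0, 1, 2)

    def test_isolated_node(self, build_model):
        model = build_model(
            edges=[], arities=(2, 2),
            tables=[[[0.5], [0.5]], [[0.5], [0.5]]],
        )
        b = bf.blanket(model, 0)
        assert b.ancestors == b.descendants == b.co_ancestors == ()
        assert b.members == (0,)

    def test_unknown_node_rejected(self, identity_chain):
        with pytest.raises(bf.InvalidArgumentError):
            bf.blanket(identity_chain, 9)

    def test_center_never_in_its_own_sets(self):
        for seed in range(20):
            model = random_small_model(seed)
            for v in range(model.n_nodes):
                b = bf.blanket(model, v)
                assert v not in b.ancestors
                assert v not in b.descendants
                assert v not in b.co_ancestors


class TestBlanketJoint:
    def test_deterministic_chain_reduces_to_root_prior(self, identity_chain):
        b = bf.blanket(identity_chain, 1)
        prob = bf.blanket_joint(identity_chain, b, {0: 0, 1: 0, 2: 0})
        assert prob == pytest.approx(0.3, abs=1e-14)

    def test_matches_exhaustive_marginal_on_factorable_centers(self):
        """Factored blanket joint equals the marginal over the members
        whenever no co-ancestor is a descendant of the center."""
        checked = 0
        for seed in range(25):
            model = random_small_model(seed, max_nodes=5)
            jt = bf.enumerate_joint(model)
            full = jt.probs.reshape(jt.arities)
            for v in range(model.n_nodes):
                if not is_locally_factorable(model, v):
                    continue
                dist = BlanketDistribution(model, v)
                members = dist.blanket.members
                axes = tuple(
                    i for i in range(model.n_nodes) if i not in members
                )
                marg = full.sum(axis=axes) if axes else full
                assert np.allclose(dist.joint_table(), marg, atol=1e-10)
                checked += 1
        assert checked >= 40

    def test_normalizes_when_members_ancestrally_closed(self):
        for seed in range(25):
            model = random_small_model(seed, max_nodes=5)
            for v in range(model.n_nodes):
                dist = BlanketDistribution(model, v)
                members = set(dist.blanket.members)
                closed = all(
                    set(model.parents(u)) <= members for u in members
                )
                if closed:
                    assert dist.joint_table().sum() == pytest.approx(
                        1.0, abs=1e-10
                    )

    def test_incomplete_assignment_rejected(self, identity_chain):
        b = bf.blanket(identity_chain, 1)
        with pytest.raises(bf.InvalidArgumentError):
            bf.blanket_joint(identity_chain, b, {0: 0, 1: 0})


class TestCenterConditional:
    def test_deterministic_chain_point_mass(self, identity_chain):
        cond = bf.center_conditional(identity_chain, 1, {0: 1, 2: 1})
        assert np.allclose(cond, [0.0, 1.0], atol=1e-14)

    def test_markov_property_against_full_joint(self):
        """The factored blanket conditional equals the conditional given
        *all* other variables, for every positive assignment."""
        for seed in range(25):
            model = random_small_model(seed)
            full, brute = brute_conditional(model, 0)
            n = model.n_nodes
            for v in range(n):
                full, brute = brute_conditional(model, v)
                dist = BlanketDistribution(model, v)
                members = dist.blanket.members
                cond = dist.center_conditional_table()
                shape = [
                    model.arities[u] if u in members else 1 for u in range(n)
                ]
                cond_full = cond.reshape(shape)
                mask = full > 0
                diff = np.abs(
                    np.where(mask, brute - cond_full, 0.0)
                )
                assert np.nanmax(diff) < 1e-10

    def test_scalar_and_table_paths_agree(self):
        model = random_small_model(3)
        v = 0
        dist = BlanketDistribution(model, v)
        periphery = {u: 0 for u in dist.blanket.periphery}
        scalar = dist.center_conditional(periphery)
        table = dist.center_conditional_table()
        axis = dist.blanket.members.index(v)
        idx = tuple(
            0 if u != v else slice(None) for u in dist.blanket.members
        )
        assert np.allclose(scalar, table[idx], atol=1e-12)
        assert scalar.sum() == pytest.approx(1.0, abs=1e-12)

    def test_label_keys_and_int_keys_equivalent(self, identity_chain):
        a = bf.center_conditional(identity_chain, 1, {0: 1, 2: 1})
        b = bf.center_conditional(identity_chain, 1, {"X2": 1, "X0": 1})
        assert np.allclose(a, b)

    def test_zero_probability_periphery_raises(self, identity_chain):
        # (A=0, D=1) is impossible under the identity chain
        with pytest.raises(bf.UndefinedConditionalError):
            bf.center_conditional(identity_chain, 1, {0: 0, 2: 1})


class TestPeripheryInference:
    def test_bayes_inversion_of_root_table(self, build_model, rng):
        table = rng.dirichlet(np.ones(2), size=2).T
        prior = np.array([0.35, 0.65])
        model = build_model(
            edges=[(0, 1)], arities=(2, 2),
            tables=[prior[:, None], table],
        )
        # infer the ancestor A from the center X = 1
        post = bf.periphery_inference(model, 1, 1, 0, {})
        expected = table[1, :] * prior
        expected /= expected.sum()
        assert np.allclose(post, expected, atol=1e-12)

    def test_deterministic_invertible_chain_recovers_preimage(
        self, identity_chain
    ):
        post = bf.periphery_inference(identity_chain, 1, 0, 0, {2: 0})
        assert np.allclose(post, [1.0, 0.0], atol=1e-14)

    def test_result_normalized(self):
        model = random_small_model(8)
        for v in range(model.n_nodes):
            dist = BlanketDistribution(model, v)
            if not dist.blanket.periphery:
                continue
            target = dist.blanket.periphery[0]
            rest = {u: 0 for u in dist.blanket.periphery if u != target}
            try:
                post = dist.periphery_inference(0, target, rest)
            except bf.UndefinedConditionalError:
                continue
            assert post.sum() == pytest.approx(1.0, abs=1e-12)
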