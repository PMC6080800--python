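"""Mechanism-level integration: partitions, MIPs, MIC/MIE, concepts."""

from itertools import chain, combinations

import numpy as np
import pytest

import phikit as pk
from phikit.fixtures import FixtureSpec, random_network
from phikit.mechanism import _mip, mechanism_partitions, purview_reducible_by_cm
from phikit.repertoire import Direction
from phikit.tpm import all_states

from conftest import A, B, C


def powerset(xs):
    xs = tuple(xs)
    return chain.from_iterable(combinations(xs, r) for r in range(1, len(xs) + 1))


class TestMechanismPartitions:
    def test_single_node_pair_has_one_partition(self):
        parts = mechanism_partitions((0,), (0,))
        assert len(parts) == 1
        p = parts[0]
        assert {(p.mechanism1, p.purview1), (p.mechanism2, p.purview2)} == {
            ((), (0,)),
            ((0,), ()),
        }

    def test_partitions_satisfy_invariants(self):
        mech, purv = (0, 1), (0, 1, 2)
        for p in mechanism_partitions(mech, purv):
            assert tuple(sorted(p.mechanism1 + p.mechanism2)) == mech
            assert tuple(sorted(p.purview1 + p.purview2)) == purv
            assert not (set(p.mechanism1) & set(p.mechanism2))
            assert not (set(p.purview1) & set(p.purview2))
            assert (p.mechanism1, p.purview1) != ((), ())
            assert (p.mechanism2, p.purview2) != ((), ())

    def test_unordered_enumeration_count(self):
        # one mechanism node, two purview nodes: {∅/p, m/q}, {∅/q, m/p},
        # {∅/pq, m/∅} -- swapped part orders are the same partition
        assert len(mechanism_partitions((0,), (1, 2))) == 3

    def test_includes_worked_example_factorization(self):
        parts = mechanism_partitions((0, 1, 2), (0, 1, 2))
        keys = {
            frozenset(
                [(p.mechanism1, p.purview1), (p.mechanism2, p.purview2)]
            )
            for p in parts
        }
        assert frozenset([((), (1,)), ((0, 1, 2), (0, 2))]) in keys

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            mechanism_partitions((), (0,))
        with pytest.raises(ValueError):
            mechanism_partitions((0,), ())


class TestPartitionedRepertoire:
    def test_worked_effect_factorization(self, example_sub):
        part = pk.partitioned_repertoire(
            example_sub,
            Direction.EFFECT,
            pk.MechanismPartition((), (1,), (0, 1, 2), (0, 2)),
        )
        # point mass on A'C' = (0, 1) times Pr(B' ON) = 0.25
        marg = part.node_on_marginals()
        assert marg[A] == pytest.approx(0.0)
        assert marg[B] == pytest.approx(0.25)
        assert marg[C] == pytest.approx(1.0)

    def test_disconnected_network_partition_changes_nothing(self):
        rows = np.array([[0.2, 0.7]] * 4)  # no node listens to anything
        net = pk.Network(rows, cm=np.zeros((2, 2), dtype=int))
        sub = pk.Subsystem(net, (0, 0))
        from phikit.repertoire import repertoire

        for direction in Direction:
            unpart = repertoire(sub, direction, (0, 1), (0, 1))
            for partition in mechanism_partitions((0, 1), (0, 1)):
                part = pk.partitioned_repertoire(sub, direction, partition)
                np.testing.assert_allclose(part.tensor, unpart.tensor, atol=1e-12)


class TestBlockReducibility:
    def test_full_cm_never_reducible(self):
        cm = np.ones((3, 3), dtype=int)
        for direction in Direction:
            assert not purview_reducible_by_cm((0, 1), (1, 2), cm, direction)

    def test_parallel_edges_reducible(self):
        # a -> x and b -> y only: {a,x} and {b,y} are separate blocks
        cm = np.zeros((4, 4), dtype=int)
        cm[0, 2] = cm[1, 3] = 1
        assert purview_reducible_by_cm((0, 1), (2, 3), cm, Direction.EFFECT)

    def test_worked_example_not_reducible(self, example_net):
        for direction in Direction:
            assert not purview_reducible_by_cm(
                (0, 1, 2), (0, 1, 2), example_net.cm, direction
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_shortcut_soundness_by_full_evaluation(self, seed):
        """Whenever the cm says reducible, the full partition search agrees φ=0."""
        net = random_network(
            FixtureSpec(kind="random_boolean", n=3, density=0.4, seed=seed)
        )
        sub = pk.Subsystem(net, (0,) * 3)
        for direction in Direction:
            for mech in powerset(sub.nodes):
                for purv in powerset(sub.nodes):
                    if purview_reducible_by_cm(mech, purv, sub.cm, direction):
                        ria = _mip(sub, direction, mech, purv, cm_shortcut=False)
                        assert ria.phi == 0.0


class TestMips:
    def test_worked_effect_mip(self, example_sub):
        ria = pk.effect_mip(example_sub, (A, B, C), (A, B, C))
        assert ria.phi == pytest.approx(0.25)
        parts = {
            (ria.partition.mechanism1, ria.partition.purview1),
            (ria.partition.mechanism2, ria.partition.purview2),
        }
        assert parts == {((), (B,)), ((A, B, C), (A, C))}

    def test_disconnected_pair_has_zero_phi(self):
        rows = np.array([[0.2, 0.7]] * 4)
        net = pk.Network(rows, cm=np.zeros((2, 2), dtype=int))
        sub = pk.Subsystem(net, (0, 0))
        assert pk.effect_mip(sub, (0,), (1,)).phi == 0.0
        assert pk.cause_mip(sub, (0, 1), (0, 1)).phi == 0.0

    def test_copy_gate_phi_is_half(self):
        # node 1 copies node 0; the only partition noises the copy entirely
        rows = np.array([[0.5, s[0]] for s in all_states(2)])
        net = pk.Network(rows, cm=[[0, 1], [0, 0]])
        sub = pk.Subsystem(net, (1, 1))
        ria = pk.effect_mip(sub, (0,), (1,))
        assert ria.phi == pytest.approx(0.5)

    def test_mip_is_minimal_over_all_partitions(self, example_sub):
        from phikit.repertoire import repertoire

        for mech, purv in [((A,), (A, B)), ((B, C), (A, B)), ((A, B, C), (A, B, C))]:
            for direction in Direction:
                ria = _mip(example_sub, direction, mech, purv)
                unpart = repertoire(example_sub, direction, mech, purv)
                for partition in mechanism_partitions(mech, purv):
                    part = pk.partitioned_repertoire(example_sub, direction, partition)
                    d = round(pk.repertoire_distance(direction, unpart, part), 6)
                    assert ria.phi <= d + 1e-9


class TestMiceAndConcepts:
    def test_worked_mic_purview(self, example_sub):
        m = pk.mic(example_sub, (B, C))
        assert m.purview == (A, B)
        assert m.phi == pytest.approx(1 / 3, abs=1e-6)

    def test_isolated_node_has_no_irreducible_purview(self):
        rows = np.array([[0.5, s[1] and s[0]] for s in all_states(2)], dtype=float)
        net = pk.Network(rows, cm=[[0, 1], [0, 1]])
        # node 0 has no inputs: every cause purview is reducible
        sub = pk.Subsystem(net, (0, 0))
        assert pk.mic(sub, (0,)).phi == 0.0

    def test_mie_of_copy_chain_source(self):
        # 0 -> 1 -> 2 copy chain: node 0's effect lives on node 1
        rows = np.array([[0.5, s[0], s[1]] for s in all_states(3)])
        net = pk.Network(rows, cm=[[0, 1, 0], [0, 0, 1], [0, 0, 0]])
        sub = pk.Subsystem(net, (0, 0, 0))
        assert pk.mie(sub, (0,)).purview == (1,)

    def test_mice_is_maximal_over_purviews(self, example_sub):
        for mech in [(A,), (B, C), (A, B, C)]:
            best = pk.mic(example_sub, mech)
            for purv in powerset((A, B, C)):
                assert best.phi >= pk.cause_mip(example_sub, mech, purv).phi

    def test_worked_concept_census_members(self, example_sub):
        assert pk.concept(example_sub, (A, C)).phi == 0.0
        assert pk.concept(example_sub, (A,)).phi > 0

    def test_concept_phi_is_min_of_sides(self, example_sub):
        for mech in powerset((A, B, C)):
            c = pk.concept(example_sub, mech)
            assert c.phi == round(min(c.cause.phi, c.effect.phi), 6)
            assert bool(c) == (c.phi > 0)
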