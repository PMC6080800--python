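"""System-level integration: CES, Φ, cuts, complexes."""

import dataclasses

import numpy as np
import pytest

import phikit as pk
from phikit.fixtures import FixtureSpec, random_network
from phikit.network import SystemCut, apply_cut
from phikit.system import _strongly_connected, null_concept
from phikit.tpm import all_states

from conftest import A, B, C


def two_module_network():
    """Two independent 2-node copy loops (0<->1 and 2<->3)."""
    rows = np.array([[s[1], s[0], s[3], s[2]] for s in all_states(4)], dtype=float)
    cm = np.array(
        [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]]
    )
    return pk.Network(rows, cm=cm)


class TestCes:
    def test_worked_concept_census(self, example_sub):
        structure = pk.ces(example_sub)
        assert structure.mechanisms() == [
            (A,), (B,), (C,), (A, B), (B, C), (A, B, C)
        ]

    def test_disconnected_network_has_empty_ces(self):
        net = random_network(FixtureSpec(kind="random_boolean", n=3, density=0.0, seed=0))
        assert len(pk.ces(pk.Subsystem(net, (0, 0, 0)))) == 0

    def test_self_loop_copy_has_one_concept(self):
        net = pk.Network(np.array([[0.0], [1.0]]), cm=[[1]])
        structure = pk.ces(pk.Subsystem(net, (1,)))
        assert structure.mechanisms() == [(0,)]
        assert structure.concepts[0].phi == pytest.approx(0.5)

    def test_invariant_under_node_permutation(self, example_net):
        # relabel nodes by the cycle A->B->C->A and permute the TPM to match
        from phikit.tpm import multidim_to_sbn, state_to_index

        perm = [2, 0, 1]  # new index of each old node
        inv = [1, 2, 0]  # old index of each new node
        old_sbn = multidim_to_sbn(example_net.tpm)
        new_sbn = np.zeros_like(old_sbn)
        for new_state in all_states(3):
            old_state = tuple(new_state[perm[i]] for i in range(3))
            for k in range(3):
                new_sbn[state_to_index(new_state), k] = old_sbn[
                    state_to_index(old_state), inv[k]
                ]
        cm = example_net.cm[np.ix_(inv, inv)]
        permuted = pk.Network(new_sbn, cm=cm)
        state = tuple(pk.EXAMPLE_STATE[i] for i in inv)
        orig = pk.ces(pk.Subsystem(example_net, pk.EXAMPLE_STATE))
        new = pk.ces(pk.Subsystem(permuted, state))
        mapped = sorted(
            (tuple(sorted(perm[i] for i in c.mechanism)), c.phi) for c in orig
        )
        assert mapped == sorted((c.mechanism, c.phi) for c in new)


class TestSystemCuts:
    def test_counts(self, example_net):
        net2 = pk.Network(np.zeros((4, 2)))
        assert len(pk.system_cuts(pk.Subsystem(net2, (0, 0)))) == 2
        sub3 = pk.Subsystem(example_net, pk.EXAMPLE_STATE)
        assert len(pk.system_cuts(sub3)) == 6
        assert len(pk.system_cuts(sub3, cut_one=True)) == 6
        net4 = two_module_network()
        sub4 = pk.Subsystem(net4, (0,) * 4)
        assert len(pk.system_cuts(sub4)) == 14
        assert len(pk.system_cuts(sub4, cut_one=True)) == 8

    def test_single_node_subsystem_has_no_cuts(self, example_net):
        assert pk.system_cuts(pk.Subsystem(example_net, (1, 0, 0), (A,))) == []


class TestCesDistance:
    def test_identical_structures(self, example_sub):
        structure = pk.ces(example_sub)
        assert pk.ces_distance(structure, structure) == 0.0

    def test_worked_value_under_minimal_cut(self, example_sub):
        structure = pk.ces(example_sub)
        cut_sub = apply_cut(example_sub, SystemCut((A, B), (C,)))
        partitioned = pk.ces(cut_sub)
        assert round(pk.ces_distance(structure, partitioned), 2) == 1.92

    def test_phi_perturbation_transport_bound(self, example_sub):
        structure = pk.ces(example_sub)
        eps = 1e-3
        target = structure.concepts[0]
        weakened = dataclasses.replace(
            target,
            cause=dataclasses.replace(
                target.cause, ria=dataclasses.replace(target.cause.ria, phi=target.cause.phi - eps)
            ),
            effect=dataclasses.replace(
                target.effect, ria=dataclasses.replace(target.effect.ria, phi=target.effect.phi - eps)
            ),
        )
        perturbed = pk.CauseEffectStructure(
            (weakened,) + structure.concepts[1:], example_sub
        )
        d_null = pk.concept_distance(target, example_sub, null_concept(example_sub), example_sub)
        assert pk.ces_distance(structure, perturbed) <= eps * d_null + 1e-9

    def test_node_set_mismatch_rejected(self, example_net, example_sub):
        other = pk.ces(pk.Subsystem(example_net, (1, 0, 0), (A, B)))
        with pytest.raises(ValueError):
            pk.ces_distance(pk.ces(example_sub), other)


class TestSia:
    def test_worked_example(self, example_sub):
        analysis = pk.sia(example_sub)
        assert round(analysis.phi, 2) == 1.92
        assert analysis.cut == SystemCut((A, B), (C,))
        assert len(analysis.ces) == 6

    def test_feedforward_chain_short_circuits(self):
        rows = np.array([[0.5, s[0], s[1]] for s in all_states(3)])
        net = pk.Network(rows, cm=[[0, 1, 0], [0, 0, 1], [0, 0, 0]])
        analysis = pk.sia(pk.Subsystem(net, (0, 0, 0)))
        assert analysis.phi == 0.0
        assert analysis.cut is None

    def test_strong_connectivity_theorem(self):
        """Non-strongly-connected cm implies Φ = 0 even by exhaustive search."""
        found = 0
        seed = 0
        while found < 8:
            net = random_network(
                FixtureSpec(kind="random_boolean", n=3, density=0.5, seed=seed)
            )
            seed += 1
            sub = pk.Subsystem(net, (0,) * net.n)
            if _strongly_connected(sub):
                continue
            found += 1
            assert pk.sia(sub, connectivity_shortcut=False).phi == 0.0

    def test_cut_one_upper_bounds_exhaustive(self):
        for seed in (0, 3):
            net = random_network(
                FixtureSpec(kind="random_boolean", n=4, density=0.75, noise=0.1, seed=seed)
            )
            sub = pk.Subsystem(net, (0,) * 4)
            exhaustive = pk.sia(sub, connectivity_shortcut=False)
            approx = pk.sia(sub, pk.Config(cut_one=True), connectivity_shortcut=False)
            assert approx.phi >= exhaustive.phi - 1e-9

    def test_no_new_concepts_mode_runs(self, example_sub):
        analysis = pk.sia(example_sub, pk.Config(no_new_concepts=True))
        assert analysis.phi > 0

    def test_parallel_matches_serial(self, example_sub):
        serial = pk.sia(example_sub)
        parallel = pk.sia(example_sub, pk.Config(parallel=True))
        assert serial.phi == parallel.phi
        assert serial.cut == parallel.cut

    def test_result_roundtrip(self, tmp_path, example_sub):
        analysis = pk.sia(example_sub)
        path = tmp_path / "sia.json"
        pk.save_result(analysis.to_dict(), path)
        assert pk.load_result(path) == analysis.to_dict()


class TestComplexes:
    def test_worked_major_complex(self, example_net):
        analysis = pk.major_complex(example_net, pk.EXAMPLE_STATE)
        assert analysis.subsystem.nodes == (A, B, C)
        assert round(analysis.phi, 2) == 1.92

    def test_disconnected_network_returns_zero_phi_tiebreak(self):
        net = random_network(FixtureSpec(kind="random_boolean", n=3, density=0.0, seed=1))
        analysis = pk.major_complex(net, (0, 0, 0))
        assert analysis.phi == 0.0
        assert analysis.subsystem.nodes == (0, 1, 2)

    def test_two_independent_modules(self):
        net = two_module_network()
        major = pk.major_complex(net, (0, 0, 0, 0))
        assert major.subsystem.nodes in [(0, 1), (2, 3)]
        assert major.phi > 0
        found = pk.complexes(net, (0, 0, 0, 0))
        assert sorted(c.subsystem.nodes for c in found) == [(0, 1), (2, 3)]
        assert all(c.phi > 0 for c in found)
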