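from itertools import combinations

import numpy as np
import pytest

from iitcalc import (
    FUTURE,
    PAST,
    GateSpec,
    MechanismPartition,
    build_network,
    cause_repertoire,
    condition_on_background,
    effect_repertoire,
    expand_repertoire,
    marginalize,
    partitioned_repertoire,
    unconstrained_repertoire,
)
from iitcalc.fixtures import independent_pair
from oracles import oracle_cause, oracle_p_on

TOL = 1e-12


def test_or_gate_on_rules_out_all_off_cause(abc_cs):
    # A = OR(B, C) = 1 excludes the past BC = 00; the rest is uniform
    rep = cause_repertoire(abc_cs, (0,), (1, 2))
    assert np.allclose(rep.probs, [0, 1 / 3, 1 / 3, 1 / 3])


def test_xor_off_constrains_equal_inputs(abc_cs):
    # C = XOR(A, B) = 0 means A and B were equal
    rep = cause_repertoire(abc_cs, (2,), (0, 1))
    assert np.allclose(rep.probs, [0.5, 0, 0, 0.5])


def test_effect_of_partial_clamp_is_mixed(abc_cs):
    # B = AND(A, C): clamping A=1 and perturbing C uniformly gives P(B on)=1/2
    rep = effect_repertoire(abc_cs, (0,), (1,))
    assert np.allclose(rep.probs, [0.5, 0.5])


def test_unconstrained_repertoires(abc_cs):
    # OR gate with inputs perturbed into all 4 states is on 3 times out of 4
    rep = unconstrained_repertoire(abc_cs, (0,), FUTURE)
    assert np.allclose(rep.probs, [0.25, 0.75])
    # the unconstrained cause repertoire is uniform
    rep = unconstrained_repertoire(abc_cs, (0, 1, 2), PAST)
    assert np.allclose(rep.probs, 1 / 8)


def test_fully_clamped_deterministic_effect_is_point_mass(abc_cs):
    rep = effect_repertoire(abc_cs, (0, 1, 2), (0, 1, 2))
    assert sorted(rep.probs) == [0] * 7 + [1]


def test_effect_of_full_mechanism_equals_tpm_row(abc_cs, copy_ring_cs):
    for cs in (abc_cs, copy_ring_cs):
        full = tuple(range(cs.m))
        rep = effect_repertoire(cs, full, full)
        from iitcalc import state_index

        row = cs.state_by_state_tpm()[state_index(cs.local_state)]
        assert np.allclose(rep.probs, row, atol=TOL)


def test_single_node_cause_matches_bayes_rule(random_nets):
    """Cause repertoire of one node == Bayes on the conditioned TPM, uniform prior."""
    from iitcalc import state_index

    for net, state in random_nets:
        cs = condition_on_background(net, net.labels, state)
        T = cs.state_by_state_tpm()
        m = cs.m
        for i in range(m):
            rep = cause_repertoire(cs, (i,), tuple(range(m)))
            # P(past | node i = v) with uniform prior over past states
            v = cs.local_state[i]
            like = np.array(
                [
                    sum(T[s, t] for t in range(1 << m) if ((t >> i) & 1) == v)
                    for s in range(1 << m)
                ]
            )
            if like.sum() <= 1e-12:
                assert rep.is_undefined
            else:
                assert np.allclose(rep.probs, like / like.sum(), atol=1e-9)


def test_multi_node_cause_matches_loop_oracle(random_nets):
    for net, state in random_nets[:6]:
        cs = condition_on_background(net, net.labels, state)
        p_on = oracle_p_on(net, tuple(range(net.n)), state)
        nodes = tuple(range(cs.m))
        for M in combinations(nodes, 2):
            for Z in (nodes, nodes[:2], (nodes[-1],)):
                rep = cause_repertoire(cs, M, Z)
                ref = oracle_cause(p_on, cs.local_state, M, Z)
                if ref is None:
                    assert rep.is_undefined
                else:
                    assert np.allclose(rep.probs, ref, atol=1e-9)


def test_unreachable_mechanism_state_flags_undefined():
    # G = AND(A, B) with both inputs clamped off can never be on
    net = build_network(
        ["A", "B", "G"],
        [[0, 0, 1], [0, 0, 1], [0, 0, 0]],
        [GateSpec("OR"), GateSpec("OR"), GateSpec("AND")],
    )
    cs = condition_on_background(net, ("G",), (0, 0, 1))
    rep = cause_repertoire(cs, (0,), ())
    assert rep.is_undefined


def test_partitioned_repertoire_definitions(abc_cs):
    # [AB]/[] x []/[C]: unconstrained over C times the scalar p([] | AB)
    part = MechanismPartition((0, 1), (), (), (2,))
    for direction in (PAST, FUTURE):
        rep = partitioned_repertoire(abc_cs, part, direction)
        unc = unconstrained_repertoire(abc_cs, (2,), direction)
        assert np.allclose(rep.probs, unc.probs, atol=TOL)


def test_independent_pair_partition_is_lossless():
    net, state = independent_pair()
    cs = condition_on_background(net, net.labels, state)
    A, B = cs.local(["A", "B"])
    Ca, Cb = cs.local(["Ca", "Cb"])
    whole = cause_repertoire(cs, (A, B), (Ca, Cb))
    part = partitioned_repertoire(
        cs, MechanismPartition((A,), (Ca,), (B,), (Cb,)), PAST
    )
    assert np.allclose(whole.probs, part.probs, atol=TOL)


def test_expand_point_mass_fills_with_uniform_past(abc_cs):
    # a point mass on B=1 expanded to {B, C} on the past side: uniform over C
    from iitcalc import Repertoire

    rep_b = Repertoire(PAST, (1,), np.array([0.0, 1.0]))
    exp_past = expand_repertoire(abc_cs, rep_b, (1, 2))
    assert exp_past.direction == PAST
    # little-endian: B is bit 0, so the B=1 states are indices 1 and 3
    assert np.allclose(exp_past.probs, [0.0, 0.5, 0.0, 0.5], atol=TOL)
    assert np.allclose(marginalize(exp_past, (1,)).probs, rep_b.probs, atol=TOL)
    assert np.allclose(marginalize(exp_past, (2,)).probs, [0.5, 0.5], atol=TOL)
    # expanding to the identical node set is the identity
    rep = cause_repertoire(abc_cs, (2,), (1,))
    same = expand_repertoire(abc_cs, rep, (1,))
    assert np.allclose(same.probs, rep.probs, atol=TOL)


def test_expand_then_marginalize_round_trip(random_nets):
    for k, (net, state) in enumerate(random_nets[:8]):
        cs = condition_on_background(net, net.labels, state)
        nodes = tuple(range(cs.m))
        rng = np.random.default_rng(4242 + k)
        for direction in (PAST, FUTURE):
            M = tuple(sorted(rng.choice(nodes, size=2, replace=False)))
            Z = (int(rng.integers(cs.m)),)
            rep = (
                cause_repertoire(cs, M, Z)
                if direction == PAST
                else effect_repertoire(cs, M, Z)
            )
            if rep.is_undefined:
                continue
            expanded = expand_repertoire(cs, rep, nodes)
            back = marginalize(expanded, Z)
            assert np.allclose(back.probs, rep.probs, atol=1e-12)


def test_all_defined_repertoires_normalize(random_nets):
    for net, state in random_nets:
        cs = condition_on_background(net, net.labels, state)
        nodes = tuple(range(cs.m))
        for size_m in range(0, cs.m + 1):
            for M in combinations(nodes, size_m):
                for Z in (nodes, nodes[:1], ()):
                    for direction in (PAST, FUTURE):
                        rep = (
                            cause_repertoire(cs, M, Z)
                            if direction == PAST
                            else effect_repertoire(cs, M, Z)
                        )
                        if not rep.is_undefined:
                            assert np.isclose(rep.probs.sum(), 1.0, atol=1e-12)


def test_repertoires_invariant_under_relabeling(abc):
    """Permuting node order permutes repertoire states accordingly."""
    net, state = abc
    # permuted network: order (C, A, B)
    perm = (2, 0, 1)  # new index k holds old node perm[k]
    labels = tuple(net.labels[p] for p in perm)
    cm = np.array([[net.cm[perm[i], perm[j]] for j in range(3)] for i in range(3)])
    gates = tuple(net.gates[p] for p in perm)
    net2 = build_network(labels, cm, gates)
    state2 = tuple(state[p] for p in perm)
    cs1 = condition_on_background(net, net.labels, state)
    cs2 = condition_on_background(net2, labels, state2)
    inv = {p: k for k, p in enumerate(perm)}
    # mechanism {A}=old 0 -> new index inv[0]; purview old (1,2) -> new images
    rep1 = cause_repertoire(cs1, (0,), (1, 2))
    new_purview = tuple(sorted(inv[z] for z in (1, 2)))
    rep2 = cause_repertoire(cs2, (inv[0],), new_purview)
    # map each state of rep1's purview onto rep2's state ordering
    old_nodes = (1, 2)
    for s in range(4):
        bits = {old_nodes[k]: (s >> k) & 1 for k in range(2)}
        s2 = sum(bits[z] << new_purview.index(inv[z]) for z in old_nodes)
        assert np.isclose(rep1.probs[s], rep2.probs[s2], atol=1e-12)
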