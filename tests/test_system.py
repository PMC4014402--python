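from itertools import combinations

import numpy as np
import pytest

from iitcalc import (
    FUTURE,
    PAST,
    GateSpec,
    build_network,
    concept_space_dimension,
    conceptual_information,
    conceptual_structure,
    condition_on_background,
    cut_system,
    emd,
    find_complexes,
    mics_report,
    mics_signature,
    system_phi,
)
from iitcalc.fixtures import (
    abc_plus_sink,
    abcdef_network,
    condensation_network,
    copy_loop,
    homogeneous_network,
    modular_network,
    photodiode,
    random_network,
    specialized_network,
    unconscious_photodiode,
)
from iitcalc.system import SystemCut
from oracles import oracle_system_phi


def test_abc_has_six_concepts(abc_cs):
    const = conceptual_structure(abc_cs)
    mechanisms = {c.mechanism for c in const.concepts}
    assert mechanisms == {(0,), (1,), (2,), (0, 1), (1, 2), (0, 1, 2)}
    assert concept_space_dimension(abc_cs) == 16


def test_abc_mip_cuts_ab_to_c_and_destroys_four_concepts(abc_cs):
    result = system_phi(abc_cs)
    assert result.big_phi > 0.0
    assert result.mip == SystemCut((0, 1), (2,))
    intact = {c.mechanism for c in result.intact_concepts()}
    assert intact == {(0,), (1,)}
    assert len(result.destroyed_concepts()) == 4


def test_homogeneous_network_has_five_identical_first_order_concepts():
    net, state = homogeneous_network()
    cs = condition_on_background(net, net.labels, state)
    const = conceptual_structure(cs)
    assert len(const) == 5
    assert all(len(c.mechanism) == 1 for c in const.concepts)
    phis = [c.phi_max for c in const.concepts]
    assert np.allclose(phis, phis[0], atol=1e-9)
    # identical repertoires: by symmetry every concept sees the same arrays
    for c in const.concepts[1:]:
        assert np.allclose(
            c.cause.repertoire.probs, const.concepts[0].cause.repertoire.probs
        )
        assert np.allclose(
            c.effect.repertoire.probs, const.concepts[0].effect.repertoire.probs
        )


def test_inactive_copy_ring_still_forms_a_complex(copy_ring_cs):
    result = system_phi(copy_ring_cs)
    assert len(result.whole) > 0
    assert result.big_phi > 0.0


def test_conceptual_information_values(abc_cs):
    const = conceptual_structure(abc_cs)
    # independent summation oracle over the six concepts
    nc, ne = const.null_cause, const.null_effect
    expected = sum(
        c.phi_max * (emd(c.expanded_cause(), nc) + emd(c.expanded_effect(), ne))
        for c in const.concepts
    )
    assert conceptual_information(const) == pytest.approx(expected, abs=1e-12)
    # a single self-connected mechanism has one concept and much lower CI
    single = build_network(["A"], [[1]], [GateSpec("COPY")])
    scs = condition_on_background(single, ["A"], (1,))
    s_const = conceptual_structure(scs)
    assert len(s_const) == 1
    assert conceptual_information(s_const) < conceptual_information(const)
    # empty constellation: CI = 0
    from iitcalc.system import Constellation

    assert conceptual_information(Constellation(cs=abc_cs, concepts=())) == 0.0


def test_cut_with_no_crossing_connections_preserves_dynamics():
    # two disconnected COPY loops: the cut between them changes nothing
    net = build_network(
        ["A", "B", "C", "D"],
        [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]],
        [GateSpec("COPY")] * 4,
    )
    cs = condition_on_background(net, net.labels, (0, 0, 0, 0))
    cut = cut_system(cs, SystemCut((0, 1), (2, 3)))
    assert np.array_equal(cut.p_on, cs.p_on)
    result = system_phi(cs)
    assert result.big_phi == 0.0


def test_disconnected_triads_have_zero_phi():
    # two independent three-rings observed as one six-element set
    cm = np.zeros((6, 6), dtype=int)
    for i in range(3):
        cm[i, (i + 1) % 3] = 1
        cm[3 + i, 3 + (i + 1) % 3] = 1
    net = build_network(list("ABCDEF"), cm, [GateSpec("COPY")] * 6)
    cs = condition_on_background(net, net.labels, (0,) * 6)
    assert system_phi(cs).big_phi == 0.0


def test_candidates_with_sources_or_sinks_have_exactly_zero_phi():
    net, state = abc_plus_sink()
    cs = condition_on_background(net, net.labels, state)
    assert system_phi(cs).big_phi == 0.0
    # randomized: append a sink (or a source) to generator networks
    for seed in range(6):
        base, state = random_network(seed, n=3)
        n = base.n
        cm = np.zeros((n + 1, n + 1), dtype=int)
        cm[:n, :n] = base.cm
        if seed % 2 == 0:
            cm[0, n] = 1  # sink: reads node 0, outputs nothing
            gates = base.gates + (GateSpec("COPY"),)
        else:
            cm[n, 0] = 1  # source: drives node 0, reads nothing
            # node 0 gains an input, so give it an arity-agnostic gate
            gates = tuple(
                GateSpec("OR") if j in (0, n) else base.gates[j] for j in range(n + 1)
            )
        net2 = build_network(list(base.labels) + ["Z"], cm, gates)
        cs2 = condition_on_background(net2, net2.labels, tuple(state) + (0,))
        assert system_phi(cs2).big_phi == 0.0


def test_feedforward_layered_network_has_zero_phi_everywhere():
    # 2 -> 2 layered feed-forward net: every candidate subset has Phi = 0
    cm = np.zeros((4, 4), dtype=int)
    cm[0, 2] = cm[0, 3] = cm[1, 2] = cm[1, 3] = 1
    net = build_network(
        list("WXYZ"), cm, [GateSpec("OR"), GateSpec("OR"), GateSpec("OR"), GateSpec("AND")]
    )
    state = (0, 0, 0, 0)
    for size in (2, 3, 4):
        for subset in combinations(range(4), size):
            cs = condition_on_background(net, subset, state)
            assert system_phi(cs).big_phi == 0.0
    assert not find_complexes(net, state).complexes


def test_system_phi_matches_bruteforce_oracle():
    """Production big Phi == independent naive implementation on small systems."""
    cases = []
    net, state, subset = photodiode()
    cases.append((net, tuple(net.node_index(x) for x in subset), state))
    from iitcalc.fixtures import abc_network, input_only_element, output_only_element

    for builder in (abc_network, input_only_element, output_only_element):
        net, state = builder()
        cases.append((net, tuple(range(net.n)), state))
    net, state = copy_loop(4)
    cases.append((net, tuple(range(net.n)), state))
    net, state = abc_plus_sink()
    cases.append((net, tuple(range(net.n)), state))
    for net, subset, state in cases:
        cs = condition_on_background(net, subset, state)
        got = system_phi(cs).big_phi
        ref = oracle_system_phi(net, subset, state)
        assert got == pytest.approx(ref, abs=1e-9)


def test_specialized_network_beats_homogeneous_network():
    net_h, state_h = homogeneous_network()
    cs_h = condition_on_background(net_h, net_h.labels, state_h)
    res_h = system_phi(cs_h)
    net_s, state_s = specialized_network()
    cs_s = condition_on_background(net_s, net_s.labels, state_s)
    res_s = system_phi(cs_s)
    assert len(res_s.whole) > len(res_h.whole)
    assert res_s.big_phi > res_h.big_phi


def test_abcdef_complex_is_the_abc_core():
    net, state = abcdef_network()
    report = find_complexes(net, state)
    assert [e.labels for e in report.complexes] == [("A", "B", "C")]
    # overlapping two-element subsets with positive Phi were excluded
    assert all(set(s) & {"A", "B", "C"} for s, _ in report.excluded)


def test_modular_network_condenses_into_three_module_complexes():
    net, state = modular_network()
    report = find_complexes(net, state)
    subsets = sorted(e.labels for e in report.complexes)
    assert subsets == [("A", "B"), ("C", "D"), ("E", "F")]
    assert report.evaluated[tuple(range(6))] == 0.0  # the whole is not a complex


def test_condensation_into_major_and_minor_complexes():
    net, state = condensation_network()
    report = find_complexes(net, state)
    assert report.major is not None
    assert report.major.labels == ("A", "B", "C")
    minors = sorted(e.labels for e in report.minor)
    assert minors == [("D", "E"), ("F", "G")]
    # the strongly integrated superset ABCDE is excluded by overlap with ABC
    excluded = {s for s, p in report.excluded if p > 1e-10}
    assert ("A", "B", "C", "D", "E") in excluded
    # exclusion: complexes never overlap
    seen = set()
    for entry in report.complexes:
        assert not (set(entry.subset) & seen)
        seen |= set(entry.subset)


def test_connectivity_shortcut_matches_honest_evaluation():
    net, state = abc_plus_sink()
    fast = find_complexes(net, state, connectivity_shortcut=True)
    slow = find_complexes(net, state, connectivity_shortcut=False)
    assert [e.labels for e in fast.complexes] == [e.labels for e in slow.complexes]
    for subset, phi in slow.evaluated.items():
        assert fast.evaluated[subset] == pytest.approx(phi, abs=1e-9)


def test_complexes_never_overlap_on_random_networks():
    for seed in (11, 12, 13):
        net, state = random_network(seed, n=4)
        report = find_complexes(net, state)
        seen = set()
        for entry in report.complexes:
            assert len(entry.subset) >= 2
            assert not (set(entry.subset) & seen)
            seen |= set(entry.subset)


def test_photodiode_mics_reports_two_concepts_and_phi_one():
    net, state, subset = photodiode()
    report = find_complexes(net, state)
    assert report.major is not None
    assert set(report.major.labels) == {"D", "P"}
    assert report.major.phi == pytest.approx(1.0, abs=1e-6)
    payload = mics_report(report.major)
    assert payload["n_concepts"] == 2
    assert payload["big_phi"] == pytest.approx(1.0, abs=1e-6)
    assert payload["mip_cut"] is not None


def test_photodiode_mics_is_state_invariant_and_substrate_independent():
    signatures = []
    for dp in [(0, 0), (0, 1), (1, 0), (1, 1)]:
        net, state, subset = photodiode(dp_state=dp)
        cs = condition_on_background(net, subset, state)
        signatures.append(mics_signature(system_phi(cs)))
    assert len(set(signatures)) == 1
    # a thermistor with identical internal wiring generates the same MICS
    net, state, _ = photodiode()
    thermistor = build_network(
        ("T", "M", "X1", "X2"), net.cm, net.gates
    )
    cs_t = condition_on_background(thermistor, ("T", "M"), state)
    net_p, state_p, subset_p = photodiode()
    cs_p = condition_on_background(net_p, subset_p, state_p)
    assert mics_signature(system_phi(cs_t)) == mics_signature(system_phi(cs_p))
    # with identical wiring the repertoires coincide array for array
    cp = conceptual_structure(cs_p).concepts
    ct = conceptual_structure(cs_t).concepts
    for a, b in zip(cp, ct):
        assert a.mechanism == b.mechanism
        assert np.allclose(a.expanded_cause(), b.expanded_cause())
        assert np.allclose(a.expanded_effect(), b.expanded_effect())


def test_unconscious_photodiode_has_no_complex():
    net, state = unconscious_photodiode()
    report = find_complexes(net, state)
    assert not report.complexes
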