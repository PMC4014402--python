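"""Example networks: text-specified systems, stand-ins and random generators.

Builders return ``(Network, state)`` pairs.  Each catalog entry carries a
provenance label: ``text-exact`` networks are fully determined by their written
description; ``stand-in`` networks realise a described architecture whose exact
wiring was only ever shown graphically, so only their qualitative structure
(number and kind of complexes, existence of concepts) is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .network import GateSpec, Network, all_states, build_network, state_index


def _gate(kind: str, **kw) -> GateSpec:
    return GateSpec(kind=kind, **kw)


def _cm_from_edges(n: int, edges) -> np.ndarray:
    cm = np.zeros((n, n), dtype=int)
    for i, j in edges:
        cm[i, j] = 1
    return cm


def abc_network() -> tuple[Network, tuple[int, ...]]:
    """Three mutually connected gates: A=OR(B,C), B=AND(A,C), C=XOR(A,B).

    The canonical worked example; analysed in state (1, 0, 0).  Text-exact.
    """
    labels = ("A", "B", "C")
    cm = _cm_from_edges(3, [(1, 0), (2, 0), (0, 1), (2, 1), (0, 2), (1, 2)])
    gates = (_gate("OR"), _gate("AND"), _gate("XOR"))
    return build_network(labels, cm, gates), (1, 0, 0)


def abcdef_network() -> tuple[Network, tuple[int, ...]]:
    """The ABC core embedded among background elements D, E, F.

    D feeds A and is clamped off in the canonical background state 010, so A
    behaves as OR(B, C); the D/E/F wiring beyond that is a stand-in (D is a
    sourceless always-off element, E copies D, F copies E), chosen so that no
    candidate containing D, E or F is strongly integrated.
    """
    labels = ("A", "B", "C", "D", "E", "F")
    edges = [(1, 0), (2, 0), (0, 1), (2, 1), (0, 2), (1, 2), (3, 0), (3, 4), (4, 5)]
    cm = _cm_from_edges(6, edges)
    gates = (
        _gate("OR"),
        _gate("AND"),
        _gate("XOR"),
        _gate("OR"),  # no inputs: constantly off
        _gate("COPY"),
        _gate("COPY"),
    )
    return build_network(labels, cm, gates), (1, 0, 0, 0, 1, 0)


def photodiode(external: tuple[int, int] = (1, 0), dp_state: tuple[int, int] = (1, 1)):
    """Minimally conscious photodiode: detector D and predictor P.

    D is a linear threshold unit (threshold 2, all weights 1) over two external
    light inputs and the feedback from P; P copies D, acting as a one-step
    memory that predicts the next input.  The external inputs are background
    nodes clamped to ``external``; the candidate system is {D, P} in
    ``dp_state``.  Text-exact.

    Returns (network, state, subset_labels).
    """
    labels = ("D", "P", "I1", "I2")
    edges = [(1, 0), (2, 0), (3, 0), (0, 1)]
    cm = _cm_from_edges(4, edges)
    gates = (
        _gate("THRESHOLD", weights=(1.0, 1.0, 1.0), threshold=2.0),
        _gate("COPY"),
        _gate("OR"),  # external: sourceless, state set by the scenario
        _gate("OR"),
    )
    net = build_network(labels, cm, gates)
    state = (dp_state[0], dp_state[1], external[0], external[1])
    return net, state, ("D", "P")


def unconscious_photodiode() -> tuple[Network, tuple[int, ...]]:
    """Feed-forward photodiode: detector driven externally, output-only O.

    D has no inputs from the system and O does not feed back, so the pair forms
    no complex and generates no quale.  Text-exact.
    """
    labels = ("D", "O")
    cm = _cm_from_edges(2, [(0, 1)])
    gates = (_gate("OR"), _gate("COPY"))  # D sourceless here: externally driven
    return build_network(labels, cm, gates), (1, 1)


def homogeneous_network() -> tuple[Network, tuple[int, ...]]:
    """Five OR gates, all-to-all connected including self-loops; state all ON.

    Every element specifies the same cause-effect repertoire: five identical
    first-order concepts and no higher-order ones.  Text-exact.
    """
    n = 5
    labels = tuple("ABCDE")
    cm = np.ones((n, n), dtype=int)
    gates = tuple(_gate("OR") for _ in range(n))
    return build_network(labels, cm, gates), (1,) * n


def specialized_network() -> tuple[Network, tuple[int, ...]]:
    """Five majority gates, each with three afferents and three efferents.

    Each element's neighbourhood differs (circulant wiring, offsets 1..3), so
    every elementary concept is distinct and many higher-order concepts exist.
    Stand-in wiring for the described degree-3 specialised architecture.
    """
    n = 5
    labels = tuple("ABCDE")
    cm = np.zeros((n, n), dtype=int)
    for j in range(n):
        for off in (1, 2, 3):
            cm[(j + off) % n, j] = 1
    gates = tuple(_gate("MAJORITY") for _ in range(n))
    return build_network(labels, cm, gates), (1, 0, 0, 1, 0)


def modular_network() -> tuple[Network, tuple[int, ...]]:
    """Three two-gate modules (COPY + AND) with sparse cross-module links.

    Each module is a tight reciprocal pair and forms its own small complex; the
    cross-module connections run in one direction only, so the whole system is
    not a complex.  Stand-in wiring for the modular architecture.
    """
    labels = ("A", "B", "C", "D", "E", "F")
    # modules: (A,B), (C,D), (E,F); inter-module links feed-forward B->D->F
    edges = [
        (1, 0), (0, 1),  # A=COPY(B), B reads A
        (3, 2), (2, 3),  # C=COPY(D), D reads C
        (5, 4), (4, 5),  # E=COPY(F), F reads E
        (1, 3), (3, 5),  # B->D, D->F
    ]
    cm = _cm_from_edges(6, edges)
    gates = (
        _gate("COPY"),
        _gate("AND"),
        _gate("COPY"),
        _gate("AND"),
        _gate("COPY"),
        _gate("AND"),
    )
    # B and D clamped ON as background make the downstream ANDs transparent
    return build_network(labels, cm, gates), (0, 1, 0, 1, 0, 1)


def copy_loop(n: int = 4) -> tuple[Network, tuple[int, ...]]:
    """A directed ring of COPY gates, all elements OFF.

    An entirely inactive system that still forms a complex: each silent element
    irreducibly constrains its neighbours' past and future.  Text-exact for
    n = 4.
    """
    labels = tuple(chr(ord("A") + i) for i in range(n))
    edges = [(i, (i + 1) % n) for i in range(n)]
    cm = _cm_from_edges(n, edges)
    gates = tuple(_gate("COPY") for _ in range(n))
    return build_network(labels, cm, gates), (0,) * n


def input_only_element() -> tuple[Network, tuple[int, ...]]:
    """Element A reads the system but has no outputs to it (ei = 0 for A)."""
    labels = ("A", "B", "C")
    edges = [(1, 0), (2, 0), (2, 1), (1, 2)]
    cm = _cm_from_edges(3, edges)
    gates = (_gate("AND"), _gate("COPY"), _gate("COPY"))
    return build_network(labels, cm, gates), (1, 1, 1)


def output_only_element() -> tuple[Network, tuple[int, ...]]:
    """Element A drives the system but receives nothing from it (ci = 0)."""
    labels = ("A", "B", "C")
    edges = [(0, 1), (0, 2), (2, 1), (1, 2)]
    cm = _cm_from_edges(3, edges)
    gates = (_gate("OR"), _gate("OR"), _gate("OR"))
    return build_network(labels, cm, gates), (1, 1, 1)


def independent_pair() -> tuple[Network, tuple[int, ...]]:
    """Two mechanisms with disjoint causes and effects.

    The joint mechanism {A, B} can be partitioned without loss, so it
    generates no integrated information in either direction.  Stand-in for the
    independent-pair motif.
    """
    labels = ("A", "B", "Ca", "Cb", "Ea", "Eb")
    edges = [(2, 0), (3, 1), (0, 4), (1, 5), (4, 2), (5, 3)]
    cm = _cm_from_edges(6, edges)
    gates = tuple(_gate("COPY") for _ in range(6))
    return build_network(labels, cm, gates), (1, 1, 1, 1, 1, 1)


def integrated_pair() -> tuple[Network, tuple[int, ...]]:
    """A non-parity and a majority gate sharing three causes, with a joint AND
    effect.

    A turns on for an even number of active inputs, B for a majority; jointly
    on they specify "exactly two inputs were on", which goes beyond either part
    alone, and their joint effect drives the AND gate W.  The pair is therefore
    irreducible in both directions.  Stand-in for the integrated-pair motif.
    """
    labels = ("A", "B", "X", "Y", "Z", "W")
    edges = [
        (2, 0), (3, 0), (4, 0),
        (2, 1), (3, 1), (4, 1),
        (0, 5), (1, 5),
        (5, 2), (5, 3), (5, 4),
    ]
    cm = _cm_from_edges(6, edges)
    gates = (
        _gate("NONPARITY"),
        _gate("MAJORITY"),
        _gate("COPY"),
        _gate("COPY"),
        _gate("COPY"),
        _gate("AND"),
    )
    return build_network(labels, cm, gates), (1, 1, 1, 1, 0, 1)


def condensation_network() -> tuple[Network, tuple[int, ...]]:
    """A larger system that condenses into one major and two minor complexes.

    The ABC triad (major complex) interacts with a reciprocal pair DE through
    C -> D and D -> A; FG is an isolated reciprocal COPY pair (a minor complex
    with no interactions); H is a sourceless element feeding the feed-forward
    chain H -> K -> L, with K also driving B, so H, K and L can never join a
    complex.  ABCDE is strongly integrated but overlaps the stronger ABC.
    Stand-in wiring for the condensation architecture.
    """
    labels = ("A", "B", "C", "D", "E", "F", "G", "H", "K", "L")
    edges = [
        # ABC triad (A also reads D; B also reads K)
        (1, 0), (2, 0), (3, 0),
        (0, 1), (2, 1), (8, 1),
        (0, 2), (1, 2),
        # DE pair, coupled to the triad
        (2, 3), (4, 3), (3, 4),
        # FG isolated pair
        (6, 5), (5, 6),
        # feed-forward chain H -> K -> L
        (7, 8), (8, 9),
    ]
    cm = _cm_from_edges(10, edges)
    gates = (
        _gate("OR"),        # A = OR(B, C, D)
        _gate("AND"),       # B = AND(A, C, K)
        _gate("XOR"),       # C = XOR(A, B)
        _gate("OR"),        # D = OR(C, E)
        _gate("COPY"),      # E = COPY(D)
        _gate("COPY"),      # F = COPY(G)
        _gate("COPY"),      # G = COPY(F)
        _gate("OR"),        # H: sourceless
        _gate("COPY"),      # K = COPY(H)
        _gate("COPY"),      # L = COPY(K)
    )
    # Background K clamped ON so B behaves as AND(A, C); D clamped off for ABC.
    return build_network(labels, cm, gates), (1, 0, 0, 0, 1, 0, 0, 0, 1, 0)


def segment_dot_network() -> tuple[Network, tuple[int, ...]]:
    """Layered recurrent feature-detector system (qualitative stand-in).

    Ten elements: three ports-in reading external input, a hidden layer of
    linear threshold units with excitatory/inhibitory recurrent links, and two
    XOR ports-out.  Only the architecture (recurrent, specialised, strongly
    connected core) is meaningful; the exact wiring of the original is
    graphical.
    """
    labels = ("A", "B", "C", "D", "E", "G", "H", "I", "F", "J")
    n = 10
    cm = np.zeros((n, n), dtype=int)
    w: dict[tuple[int, int], float] = {}

    def connect(i, j, weight=1.0):
        cm[i, j] = 1
        w[(i, j)] = weight

    # ports-in A,B,C read feedback from hidden units
    connect(3, 0), connect(4, 1), connect(5, 2)
    # hidden LTUs D,E,G,H read the ports-in and each other
    connect(0, 3), connect(1, 3), connect(6, 3, -1.0)
    connect(1, 4), connect(2, 4), connect(6, 4, -1.0)
    connect(0, 5), connect(2, 5), connect(7, 5, -1.0)
    connect(3, 6), connect(4, 6), connect(5, 6, -1.0)
    connect(3, 7, -1.0), connect(4, 7), connect(5, 7)
    # ports-out F,J (XOR) read the hidden layer and feed back
    connect(6, 8), connect(7, 8)
    connect(6, 9), connect(7, 9)
    connect(8, 6), connect(9, 7)

    gates = []
    for j in range(n):
        inputs = tuple(int(i) for i in np.flatnonzero(cm[:, j]))
        if j in (8, 9):
            gates.append(_gate("XOR"))
        else:
            weights = tuple(w[(i, j)] for i in inputs)
            threshold = 1.0 if j in (0, 1, 2) else 2.0
            gates.append(_gate("THRESHOLD", weights=weights, threshold=threshold))
    state = (1, 1, 0, 1, 0, 0, 1, 0, 1, 1)
    return build_network(labels, cm, gates), state


def abc_plus_sink() -> tuple[Network, tuple[int, ...]]:
    """The ABC triad plus a sink S = COPY(C) with no outputs.

    Any candidate containing S has Phi = 0: the cut S -> rest severs nothing.
    """
    labels = ("A", "B", "C", "S")
    edges = [(1, 0), (2, 0), (0, 1), (2, 1), (0, 2), (1, 2), (2, 3)]
    cm = _cm_from_edges(4, edges)
    gates = (_gate("OR"), _gate("AND"), _gate("XOR"), _gate("COPY"))
    return build_network(labels, cm, gates), (1, 0, 0, 0)


def unfold_feedforward(net: Network, horizon: int) -> Network:
    """Time-unfolded feed-forward twin of a deterministic recurrent network.

    Every element is replicated once per layer t = 0..horizon; the layer-0
    copies are sourceless placeholders holding the initial state, and each
    deeper copy applies its element's gate to the previous layer.  Running the
    unfolded network for ``horizon`` steps from a state whose layer 0 encodes
    x0 leaves layer ``horizon`` equal to the recurrent network's state after
    ``horizon`` steps from x0, for every x0 — yet the construction contains no
    directed cycle and therefore supports no complex.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if not net.deterministic:
        raise ValueError("unfolding requires a deterministic network")
    n = net.n
    labels = []
    for t in range(horizon + 1):
        labels.extend(f"{lab}{t}" for lab in net.labels)
    N = n * (horizon + 1)
    cm = np.zeros((N, N), dtype=int)
    gates: list[GateSpec] = []
    for j in range(n):
        gates.append(_gate("OR"))  # layer 0: sourceless input holder
    for t in range(1, horizon + 1):
        for j in range(n):
            col = t * n + j
            for i in net.inputs_of(j):
                cm[(t - 1) * n + i, col] = 1
            gates.append(net.gates[j])
    return build_network(labels, cm, gates)


def random_network(
    seed: int, n: int = 3, p_edge: float = 0.5
) -> tuple[Network, tuple[int, ...]]:
    """Seeded random deterministic network for property tests.

    Erdos-Renyi directed connectivity, repaired so every node has at least one
    input and the graph is weakly connected; gates drawn uniformly from a fixed
    deterministic library compatible with each node's in-degree.  Bit-for-bit
    reproducible for a given (seed, n, p_edge).
    """
    rng = np.random.default_rng(seed)
    cm = (rng.random((n, n)) < p_edge).astype(int)
    for j in range(n):
        if cm[:, j].sum() == 0:
            cm[int(rng.integers(n)), j] = 1
    # ensure weak connectivity by chaining components
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((int(i), int(j)) for i in range(n) for j in range(n) if cm[i, j])
    comps = [sorted(c) for c in nx.connected_components(g)]
    for c1, c2 in zip(comps, comps[1:]):
        cm[c1[0], c2[0]] = 1
    multi = ("OR", "AND", "XOR", "MAJORITY", "NONPARITY")
    single = ("COPY", "NOT", "OR", "AND")
    gates = []
    for j in range(n):
        arity = int(cm[:, j].sum())
        library = single if arity == 1 else multi
        gates.append(_gate(str(rng.choice(library))))
    net = build_network([chr(ord("A") + i) for i in range(n)], cm, tuple(gates))
    state = tuple(int(v) for v in rng.integers(0, 2, size=n))
    return net, state


@dataclass(frozen=True)
class Fixture:
    """Catalog entry: a named builder with its provenance."""

    name: str
    provenance: str  # "text-exact" or "stand-in"
    description: str
    build: Callable[[], tuple]


def catalog_builders() -> dict[str, Fixture]:
    """All named fixtures, keyed by name."""
    entries = [
        Fixture("abc", "text-exact", "OR/AND/XOR triad, state 100", abc_network),
        Fixture(
            "abcdef",
            "stand-in",
            "ABC triad with background elements D, E, F",
            abcdef_network,
        ),
        Fixture(
            "photodiode",
            "text-exact",
            "threshold-2 detector with copy predictor",
            lambda: photodiode()[:2],
        ),
        Fixture(
            "unconscious_photodiode",
            "text-exact",
            "feed-forward detector/output pair",
            unconscious_photodiode,
        ),
        Fixture(
            "homogeneous",
            "text-exact",
            "five OR gates, all-to-all with self-loops",
            homogeneous_network,
        ),
        Fixture(
            "specialized",
            "stand-in",
            "five majority gates, circulant degree-3 wiring",
            specialized_network,
        ),
        Fixture(
            "modular",
            "stand-in",
            "three COPY+AND modules with one-way cross links",
            modular_network,
        ),
        Fixture(
            "copy_loop4", "text-exact", "four-COPY ring, all elements off", copy_loop
        ),
        Fixture(
            "input_only",
            "text-exact",
            "element with inputs from but no outputs to the system",
            input_only_element,
        ),
        Fixture(
            "output_only",
            "text-exact",
            "element with outputs to but no inputs from the system",
            output_only_element,
        ),
        Fixture(
            "independent_pair",
            "stand-in",
            "two mechanisms with disjoint causes and effects",
            independent_pair,
        ),
        Fixture(
            "integrated_pair",
            "stand-in",
            "non-parity + majority pair with shared causes and a joint effect",
            integrated_pair,
        ),
        Fixture(
            "condensation",
            "stand-in",
            "major ABC complex, DE and FG minor complexes, feed-forward fringe",
            condensation_network,
        ),
        Fixture(
            "segment_dot",
            "stand-in",
            "layered recurrent feature-detector system",
            segment_dot_network,
        ),
        Fixture(
            "abc_plus_sink",
            "stand-in",
            "ABC triad plus an output-less sink element",
            abc_plus_sink,
        ),
    ]
    return {f.name: f for f in entries}
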