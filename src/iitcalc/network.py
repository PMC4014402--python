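"""Discrete networks of binary mechanisms.

A network is a set of binary elements (logic gates, linear threshold units, or
explicit probability tables) wired by a directed connectivity matrix.  Each
element's update rule, applied synchronously to the previous network state,
induces a state-by-node transition probability matrix (TPM): the probability of
each element being ON at t+1 given the full network state at t.

State ordering convention
-------------------------
States are indexed little-endian: node 0 is the least significant bit, so the
state vector (1, 0, 0) has index 1.  Every repertoire, TPM row and CSV/JSON
export in this package uses this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STATE_ORDER = "little-endian (node index 0 is the least significant bit)"

GATE_KINDS = (
    "OR",
    "AND",
    "XOR",
    "COPY",
    "NOT",
    "MAJORITY",
    "PARITY",
    "NONPARITY",
    "THRESHOLD",
    "TABLE",
)


class NetworkError(ValueError):
    """Raised for invalid network, gate or state specifications."""


def state_index(values: Sequence[int]) -> int:
    """Map a binary state vector to its little-endian integer index."""
    idx = 0
    for k, v in enumerate(values):
        if v not in (0, 1):
            raise NetworkError(f"non-binary state entry {v!r} at position {k}")
        idx |= int(v) << k
    return idx


def index_state(index: int, n: int) -> tuple[int, ...]:
    """Inverse of :func:`state_index` for an ``n``-node system."""
    if not 0 <= index < (1 << n):
        raise NetworkError(f"state index {index} out of range for {n} nodes")
    return tuple((index >> k) & 1 for k in range(n))


def all_states(n: int) -> np.ndarray:
    """All 2**n binary states as an array of shape (2**n, n), row s = bits of s."""
    idx = np.arange(1 << n, dtype=np.int64)
    return (idx[:, None] >> np.arange(n)) & 1


@dataclass(frozen=True)
class GateSpec:
    """Update rule of one element.

    ``kind`` is one of the gate families in :data:`GATE_KINDS`.  ``weights`` and
    ``threshold`` apply to THRESHOLD gates (MAJORITY takes an implicit strict
    majority threshold); ``table`` is the explicit ON-probability lookup of a
    TABLE gate, one row per input state in little-endian order over the gate's
    inputs (sorted by node index).

    Conventions for degenerate arities: an OR with no inputs is constantly OFF,
    an AND with no inputs constantly ON (empty conjunction), XOR generalises to
    odd parity, NONPARITY to even parity, and MAJORITY with an even number k of
    inputs fires only for strictly more than k/2 active inputs.
    """

    kind: str
    weights: tuple[float, ...] | None = None
    threshold: float | None = None
    table: tuple[float, ...] | None = None

    def validate(self, arity: int) -> None:
        if self.kind not in GATE_KINDS:
            raise NetworkError(f"unknown gate kind {self.kind!r}")
        if self.kind in ("COPY", "NOT") and arity != 1:
            raise NetworkError(f"{self.kind} gate requires exactly 1 input, got {arity}")
        if self.kind == "THRESHOLD":
            if self.threshold is None:
                raise NetworkError("THRESHOLD gate requires a threshold")
            if self.weights is not None and len(self.weights) != arity:
                raise NetworkError(
                    f"THRESHOLD weights length {len(self.weights)} != in-degree {arity}"
                )
        if self.kind == "TABLE":
            if self.table is None:
                raise NetworkError("TABLE gate requires a table")
            if len(self.table) != (1 << arity):
                raise NetworkError(
                    f"TABLE row count {len(self.table)} != 2**in-degree = {1 << arity}"
                )
            if any(not 0.0 <= p <= 1.0 for p in self.table):
                raise NetworkError("TABLE probabilities must lie in [0, 1]")

    @property
    def deterministic(self) -> bool:
        if self.kind != "TABLE":
            return True
        return all(p in (0.0, 1.0) for p in self.table)

    def on_probability(self, inputs: np.ndarray) -> np.ndarray:
        """P(element ON at t+1) for each row of binary input states ``inputs``."""
        x = np.asarray(inputs, dtype=np.int64)
        k = x.shape[1]
        s = x.sum(axis=1)
        if self.kind == "OR":
            return (s > 0).astype(float)
        if self.kind == "AND":
            return (s == k).astype(float)
        if self.kind in ("XOR", "PARITY"):
            return (s % 2 == 1).astype(float)
        if self.kind == "NONPARITY":
            return (s % 2 == 0).astype(float)
        if self.kind == "COPY":
            return x[:, 0].astype(float)
        if self.kind == "NOT":
            return 1.0 - x[:, 0]
        if self.kind == "MAJORITY":
            return (2 * s > k).astype(float)
        if self.kind == "THRESHOLD":
            w = np.ones(k) if self.weights is None else np.asarray(self.weights, float)
            return (x @ w >= self.threshold - 1e-12).astype(float)
        if self.kind == "TABLE":
            idx = x @ (1 << np.arange(k, dtype=np.int64))
            return np.asarray(self.table, dtype=float)[idx]
        raise NetworkError(f"unknown gate kind {self.kind!r}")


@dataclass(frozen=True)
class Network:
    """A validated network: labels, connectivity, gates and derived node TPM.

    ``cm[i, j] == 1`` iff node i is an input of node j.  ``node_tpm`` has shape
    (2**n, n): entry [s, j] is P(node j ON at t+1 | full network state s at t).
    """

    labels: tuple[str, ...]
    cm: np.ndarray
    gates: tuple[GateSpec, ...]
    node_tpm: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.labels)

    def inputs_of(self, j: int) -> tuple[int, ...]:
        return tuple(int(i) for i in np.flatnonzero(self.cm[:, j]))

    def node_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise NetworkError(f"unknown node label {label!r}") from None

    @property
    def deterministic(self) -> bool:
        return all(g.deterministic for g in self.gates)

    def successor(self, state: Sequence[int]) -> tuple[int, ...]:
        """Deterministic one-step update (errors on stochastic networks)."""
        if not self.deterministic:
            raise NetworkError("successor() requires a deterministic network")
        row = self.node_tpm[state_index(state)]
        return tuple(int(v > 0.5) for v in row)


def build_network(
    labels: Sequence[str],
    cm: Sequence[Sequence[int]] | np.ndarray,
    gates: Sequence[GateSpec],
) -> Network:
    """Validate a network specification and derive its node TPM."""
    labels = tuple(str(x) for x in labels)
    if len(set(labels)) != len(labels):
        raise NetworkError("node labels must be unique")
    n = len(labels)
    cm = np.asarray(cm, dtype=np.int8)
    if cm.shape != (n, n):
        raise NetworkError(f"connectivity matrix shape {cm.shape} != ({n}, {n})")
    if not np.isin(cm, (0, 1)).all():
        raise NetworkError("connectivity matrix entries must be 0/1")
    if len(gates) != n:
        raise NetworkError(f"{len(gates)} gates for {n} nodes")
    gates = tuple(gates)
    for j, gate in enumerate(gates):
        gate.validate(arity=int(cm[:, j].sum()))

    states = all_states(n)
    node_tpm = np.empty((1 << n, n), dtype=float)
    for j, gate in enumerate(gates):
        inputs = np.flatnonzero(cm[:, j])
        node_tpm[:, j] = gate.on_probability(states[:, inputs])
    node_tpm.setflags(write=False)
    cm.setflags(write=False)
    return Network(labels=labels, cm=cm, gates=gates, node_tpm=node_tpm)


def state_by_state_tpm(net: Network) -> np.ndarray:
    """Full (2**n, 2**n) transition matrix over network states.

    Rows sum to one; for deterministic networks every row is a point mass on the
    successor state.  Node updates are conditionally independent given the past
    state, so the joint is the product of the per-node Bernoulli factors.
    """
    return _joint_from_node_probs(net.node_tpm)


def _joint_from_node_probs(p_on: np.ndarray) -> np.ndarray:
    n_states, m = p_on.shape
    bits = all_states(m)  # (2**m, m) bits of each successor state
    joint = np.ones((n_states, 1 << m), dtype=float)
    for j in range(m):
        col = p_on[:, j][:, None]
        joint *= np.where(bits[None, :, j] == 1, col, 1.0 - col)
    return joint


class CandidateSystem:
    """A subset of network nodes analysed with the rest frozen as background.

    The background nodes are clamped to their observed state on both sides of
    every transition; perturbations range only over subset states.  ``p_on`` has
    shape (2**m, m) for an m-node subset: P(subset node k ON at t+1 | subset
    state s at t, background clamped).  Unidirectional cuts are represented by
    replacing the cut connections with independent uniform noise directly in
    ``p_on`` (see :meth:`apply_cut`).
    """

    def __init__(
        self,
        network: Network,
        subset: tuple[int, ...],
        state: tuple[int, ...],
        p_on: np.ndarray,
        cm_local: np.ndarray,
        cut: tuple[tuple[int, ...], tuple[int, ...]] | None = None,
    ):
        self.network = network
        self.subset = subset
        self.state = state
        self.p_on = p_on
        self.cm_local = cm_local
        self.cut = cut
        self._cache: dict = {}

    @property
    def m(self) -> int:
        return len(self.subset)

    @property
    def subset_labels(self) -> tuple[str, ...]:
        return tuple(self.network.labels[i] for i in self.subset)

    @property
    def local_state(self) -> tuple[int, ...]:
        return tuple(self.state[i] for i in self.subset)

    def local(self, nodes: Iterable[int | str]) -> tuple[int, ...]:
        """Map network node indices or labels to sorted local (subset) indices."""
        out = []
        for node in nodes:
            i = self.network.node_index(node) if isinstance(node, str) else int(node)
            if i not in self.subset:
                raise NetworkError(
                    f"node {node!r} is not part of the candidate system"
                )
            out.append(self.subset.index(i))
        return tuple(sorted(out))

    def state_by_state_tpm(self) -> np.ndarray:
        """Conditioned (2**m, 2**m) TPM over subset states."""
        return _joint_from_node_probs(self.p_on)

    def apply_cut(
        self, from_part: tuple[int, ...], to_part: tuple[int, ...]
    ) -> "CandidateSystem":
        """Noise every connection from ``from_part`` to ``to_part`` (local idx).

        Each cut connection is replaced by an independent uniform binary noise
        source: the target node's conditional ON-probability is averaged over
        all values of its cut inputs.
        """
        from_part = tuple(sorted(from_part))
        to_part = tuple(sorted(to_part))
        if not from_part or not to_part:
            raise NetworkError("both parts of a cut must be nonempty")
        if set(from_part) & set(to_part):
            raise NetworkError("cut parts must be disjoint")
        if set(from_part) | set(to_part) != set(range(self.m)):
            raise NetworkError("cut parts must cover the candidate system")
        m = self.m
        p_cut = np.array(self.p_on)
        shape = (2,) * m
        for j in to_part:
            cut_inputs = [i for i in from_part if self.cm_local[i, j]]
            if not cut_inputs:
                continue
            arr = p_cut[:, j].reshape(shape)  # axis a <-> node m-1-a
            axes = tuple(m - 1 - i for i in cut_inputs)
            arr = arr.mean(axis=axes, keepdims=True)
            p_cut[:, j] = np.broadcast_to(arr, shape).ravel()
        p_cut.setflags(write=False)
        return CandidateSystem(
            network=self.network,
            subset=self.subset,
            state=self.state,
            p_on=p_cut,
            cm_local=self.cm_local,
            cut=(from_part, to_part),
        )


def condition_on_background(
    net: Network,
    subset: Iterable[int | str],
    state: Sequence[int],
) -> CandidateSystem:
    """Freeze the complement of ``subset`` at its state values and condition.

    Background nodes keep their observed values at both t-1 and t0; the
    returned candidate system's transition probabilities range only over subset
    states.
    """
    idx = tuple(
        sorted(net.node_index(x) if isinstance(x, str) else int(x) for x in subset)
    )
    if not idx:
        raise NetworkError("candidate subset must be nonempty")
    if len(set(idx)) != len(idx):
        raise NetworkError("duplicate nodes in candidate subset")
    state = tuple(int(v) for v in state)
    if len(state) != net.n or any(v not in (0, 1) for v in state):
        raise NetworkError("state must be a binary vector over all network nodes")

    m = len(idx)
    base = sum(state[i] << i for i in range(net.n) if i not in idx)
    weights = np.array([1 << i for i in idx], dtype=np.int64)
    rows = base + all_states(m) @ weights
    p_on = np.ascontiguousarray(net.node_tpm[rows][:, list(idx)])
    p_on.setflags(write=False)
    cm_local = np.ascontiguousarray(net.cm[np.ix_(idx, idx)]).astype(bool)
    return CandidateSystem(net, idx, state, p_on, cm_local)
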