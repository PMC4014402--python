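"""Cause and effect repertoires of mechanisms over purviews.

A mechanism is a subset of candidate-system nodes clamped to its current state;
a purview is the subset of nodes whose past (cause) or future (effect) states
the mechanism constrains.  Repertoires are probability distributions over the
purview's 2**|Z| states obtained by uniform maximum-entropy perturbation of all
non-clamped inputs, with background nodes held at their observed state.

Conventions (fixed for reproducibility):

* The effect repertoire is the product over purview nodes of each node's
  ON-probability given the mechanism state, with every non-mechanism input —
  including candidate-system nodes outside the mechanism — marginalised as an
  independent uniform noise source.
* The cause repertoire is the normalised product over mechanism nodes of the
  probability of each node's current value given a purview state, with
  non-purview inputs marginalised uniformly ("virtual element" independence).
  A zero normaliser means the mechanism state is unreachable; the repertoire is
  then flagged undefined and contributes no cause information downstream.
* Purviews and repertoire state indices follow the little-endian node order of
  :mod:`iitcalc.network` (bit k of a purview state is the k-th purview node in
  ascending local index order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import CandidateSystem, NetworkError

PAST = "past"
FUTURE = "future"

_UNDEF_TOL = 1e-12


@dataclass(frozen=True)
class Repertoire:
    """Distribution over the 2**|purview| states of a purview.

    ``probs`` is ``None`` when the repertoire is undefined (unreachable
    mechanism state on the cause side).  An empty purview yields the scalar
    distribution [1].
    """

    direction: str
    purview: tuple[int, ...]
    probs: np.ndarray | None

    @property
    def is_undefined(self) -> bool:
        return self.probs is None


@dataclass(frozen=True)
class MechanismPartition:
    """A bipartition of (mechanism, purview) into two independent parts.

    Connections between the parts are injected with independent noise: the
    partitioned repertoire is the tensor product of the parts' repertoires.
    """

    mechanism1: tuple[int, ...]
    purview1: tuple[int, ...]
    mechanism2: tuple[int, ...]
    purview2: tuple[int, ...]

    def describe(self, labels) -> str:
        def fmt(nodes):
            return "".join(labels[i] for i in nodes) or "[]"

        return (
            f"{fmt(self.mechanism1)}/{fmt(self.purview1)} x "
            f"{fmt(self.mechanism2)}/{fmt(self.purview2)}"
        )


def _mask(nodes: tuple[int, ...]) -> int:
    mask = 0
    for i in nodes:
        mask |= 1 << i
    return mask


def _node_marginal(
    cs: CandidateSystem,
    node: int,
    keep: tuple[int, ...],
    fixed: dict[int, int],
) -> np.ndarray:
    """Marginal ON-probability of ``node`` at t+1 over states of ``keep``.

    Inputs listed in ``fixed`` are clamped; all remaining candidate nodes are
    averaged uniformly.  Returns an array over the 2**|keep| little-endian
    states of ``keep`` (a scalar array of length 1 when ``keep`` is empty).
    """
    m = cs.m
    arr = cs.p_on[:, node].reshape((2,) * m)  # axis a <-> local node m-1-a
    index = [slice(None)] * m
    for i, v in fixed.items():
        index[m - 1 - i] = v
    arr = arr[tuple(index)]
    remaining = [i for i in range(m - 1, -1, -1) if i not in fixed]
    mean_axes = tuple(a for a, i in enumerate(remaining) if i not in keep)
    if mean_axes:
        arr = arr.mean(axis=mean_axes)
    # Remaining axes are the keep nodes in descending order; C-order ravel makes
    # the smallest node the fastest (least significant) bit.
    return np.asarray(arr).reshape(-1)


def effect_repertoire(
    cs: CandidateSystem, mechanism: tuple[int, ...], purview: tuple[int, ...]
) -> Repertoire:
    """Distribution of future purview states constrained by the mechanism.

    An empty mechanism gives the unconstrained effect repertoire (all inputs
    perturbed uniformly); an empty purview gives the scalar distribution [1].
    """
    mechanism = tuple(sorted(mechanism))
    purview = tuple(sorted(purview))
    key = ("rep", FUTURE, _mask(mechanism), _mask(purview))
    hit = cs._cache.get(key)
    if hit is not None:
        return hit
    fixed = {i: cs.local_state[i] for i in mechanism}
    probs = np.ones(1)
    for j in purview:  # ascending: each new node becomes the current high bit
        p1 = float(_node_marginal(cs, j, (), fixed)[0])
        probs = np.concatenate(((1.0 - p1) * probs, p1 * probs))
    rep = Repertoire(FUTURE, purview, probs)
    cs._cache[key] = rep
    return rep


def cause_repertoire(
    cs: CandidateSystem, mechanism: tuple[int, ...], purview: tuple[int, ...]
) -> Repertoire:
    """Distribution of past purview states constrained by the mechanism.

    An empty mechanism gives the unconstrained cause repertoire (uniform).  If
    no past purview state is compatible with the mechanism's current state under
    the clamped background, the repertoire is undefined.
    """
    mechanism = tuple(sorted(mechanism))
    purview = tuple(sorted(purview))
    key = ("rep", PAST, _mask(mechanism), _mask(purview))
    hit = cs._cache.get(key)
    if hit is not None:
        return hit
    if not mechanism:
        probs = np.full(1 << len(purview), 1.0 / (1 << len(purview)))
        rep = Repertoire(PAST, purview, probs)
        cs._cache[key] = rep
        return rep
    probs = np.ones(1 << len(purview))
    for i in mechanism:
        vec = _node_marginal(cs, i, purview, {})  # P(node i ON | purview state)
        probs *= vec if cs.local_state[i] == 1 else 1.0 - vec
    total = probs.sum()
    if total <= _UNDEF_TOL:
        rep = Repertoire(PAST, purview, None)
    else:
        rep = Repertoire(PAST, purview, probs / total)
    cs._cache[key] = rep
    return rep


def repertoire(
    cs: CandidateSystem,
    mechanism: tuple[int, ...],
    purview: tuple[int, ...],
    direction: str,
) -> Repertoire:
    if direction == PAST:
        return cause_repertoire(cs, mechanism, purview)
    if direction == FUTURE:
        return effect_repertoire(cs, mechanism, purview)
    raise NetworkError(f"unknown direction {direction!r}")


def unconstrained_repertoire(
    cs: CandidateSystem, purview: tuple[int, ...], direction: str
) -> Repertoire:
    """Repertoire with no mechanism constraint (the "null" repertoire p^uc).

    Uniform on the cause side; the product of input-perturbed node marginals on
    the effect side.
    """
    return repertoire(cs, (), purview, direction)


_combine_index_cache: dict = {}


def _combine_indices(p1: tuple[int, ...], p2: tuple[int, ...]):
    key = (p1, p2)
    hit = _combine_index_cache.get(key)
    if hit is not None:
        return hit
    purview = tuple(sorted(p1 + p2))
    L = len(purview)
    idx = np.arange(1 << L)
    idx1 = np.zeros(1 << L, dtype=np.int64)
    idx2 = np.zeros(1 << L, dtype=np.int64)
    pos1 = {node: k for k, node in enumerate(p1)}
    pos2 = {node: k for k, node in enumerate(p2)}
    for k, node in enumerate(purview):
        bit = (idx >> k) & 1
        if node in pos1:
            idx1 |= bit << pos1[node]
        else:
            idx2 |= bit << pos2[node]
    result = (purview, idx1, idx2)
    if len(_combine_index_cache) > 4096:
        _combine_index_cache.clear()
    _combine_index_cache[key] = result
    return result


def _combine(
    r1: Repertoire, r2: Repertoire, direction: str
) -> Repertoire:
    """Tensor product of two repertoires over disjoint purviews."""
    purview, idx1, idx2 = _combine_indices(r1.purview, r2.purview)
    if r1.is_undefined or r2.is_undefined:
        return Repertoire(direction, purview, None)
    return Repertoire(direction, purview, r1.probs[idx1] * r2.probs[idx2])


def partitioned_repertoire(
    cs: CandidateSystem, partition: MechanismPartition, direction: str
) -> Repertoire:
    """Repertoire specified by the two parts treated independently.

    Each part with an empty mechanism contributes the unconstrained repertoire
    over its purview part; an empty purview part contributes the scalar [1].
    """
    r1 = repertoire(cs, partition.mechanism1, partition.purview1, direction)
    r2 = repertoire(cs, partition.mechanism2, partition.purview2, direction)
    return _combine(r1, r2, direction)


def expand_repertoire(
    cs: CandidateSystem, rep: Repertoire, target: tuple[int, ...]
) -> Repertoire:
    """Extend a repertoire to a superset purview.

    Nodes outside the original purview are filled with the unconstrained
    repertoire of the same direction, so marginalising the result back over the
    original purview recovers it exactly.
    """
    target = tuple(sorted(target))
    if not set(rep.purview) <= set(target):
        raise NetworkError("expansion target must contain the purview")
    if rep.is_undefined:
        return Repertoire(rep.direction, target, None)
    rest = tuple(i for i in target if i not in rep.purview)
    if not rest:
        return Repertoire(rep.direction, target, rep.probs)
    unc = unconstrained_repertoire(cs, rest, rep.direction)
    return _combine(rep, unc, rep.direction)


def marginalize(rep: Repertoire, onto: tuple[int, ...]) -> Repertoire:
    """Marginal of a repertoire onto a sub-purview (sums out the rest)."""
    onto = tuple(sorted(onto))
    if not set(onto) <= set(rep.purview):
        raise NetworkError("marginal target must be a subset of the purview")
    if rep.is_undefined:
        return Repertoire(rep.direction, onto, None)
    L = len(rep.purview)
    arr = rep.probs.reshape((2,) * L)  # axis a <-> purview bit L-1-a
    keep_axes = {L - 1 - rep.purview.index(i) for i in onto}
    sum_axes = tuple(a for a in range(L) if a not in keep_axes)
    if sum_axes:
        arr = arr.sum(axis=sum_axes)
    return Repertoire(rep.direction, onto, arr.reshape(-1))
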