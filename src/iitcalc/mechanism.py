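"""Mechanism-level information, integration and exclusion.

For a mechanism M in its current state within a candidate system:

* cause/effect information (ci / ei) is the EMD between the constrained and the
  unconstrained repertoire over a purview; cei = min(ci, ei).
* integrated information (small phi) is the EMD between the whole repertoire
  and the repertoire of the minimum information partition (MIP), the bipartition
  of (mechanism, purview) that makes the least difference.
* exclusion keeps only the maximally irreducible cause and effect: the purviews
  maximising phi over the power set of the candidate system (the MICE).  A
  mechanism whose phi^Max = min(phi_cause, phi_effect) is positive is a concept.

Partition and purview enumeration orders are fixed and documented so results
are bit-for-bit reproducible: partitions are sorted by smaller-part size then
lexicographically by part masks; purviews are enumerated largest-first and then
lexicographically, and a candidate purview replaces the incumbent only with
strictly larger phi, so ties go to the largest purview (and then to the
earliest in enumeration order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .metrics import emd
from .network import CandidateSystem
from .repertoires import (
    FUTURE,
    PAST,
    MechanismPartition,
    Repertoire,
    _mask,
    expand_repertoire,
    partitioned_repertoire,
    repertoire,
    unconstrained_repertoire,
)

#: Comparison precision for phi values; EMD solves are exact to ~1e-12.
PRECISION = 1e-10


@dataclass(frozen=True)
class InformationValues:
    """Cause information, effect information and their minimum (cei)."""

    ci: float
    ei: float

    @property
    def cei(self) -> float:
        return min(self.ci, self.ei)


@dataclass(frozen=True)
class CoreRepertoire:
    """A maximally irreducible cause or effect: purview, repertoire, phi, MIP."""

    direction: str
    purview: tuple[int, ...]
    repertoire: Repertoire
    phi: float
    mip: MechanismPartition | None


@dataclass
class Concept:
    """A mechanism with its maximally irreducible cause-effect repertoire.

    ``phi_max`` is the minimum of the cause- and effect-side phi values; a
    concept exists only when it is positive.  ``expanded_cause``/``expanded_
    effect`` give the MICE repertoires expanded over the candidate system's
    full state space, as needed for distances in concept space.
    """

    cs: CandidateSystem
    mechanism: tuple[int, ...]
    mechanism_state: tuple[int, ...]
    cause: CoreRepertoire
    effect: CoreRepertoire
    phi_max: float
    _expanded: dict = field(default_factory=dict, repr=False)

    @property
    def mechanism_labels(self) -> tuple[str, ...]:
        return tuple(self.cs.subset_labels[i] for i in self.mechanism)

    def _expand(self, core: CoreRepertoire) -> np.ndarray:
        key = core.direction
        if key not in self._expanded:
            full = tuple(range(self.cs.m))
            rep = core.repertoire
            if rep.is_undefined:
                # unreachable cause: carries no mass anywhere; represent as the
                # unconstrained repertoire so distances are well defined
                rep = unconstrained_repertoire(self.cs, core.purview, core.direction)
            self._expanded[key] = expand_repertoire(self.cs, rep, full).probs
        return self._expanded[key]

    def expanded_cause(self) -> np.ndarray:
        return self._expand(self.cause)

    def expanded_effect(self) -> np.ndarray:
        return self._expand(self.effect)


def cause_effect_information(
    cs: CandidateSystem,
    mechanism,
    purview_past,
    purview_future,
) -> InformationValues:
    """ci/ei/cei of a mechanism over a pair of purviews.

    An undefined cause repertoire (unreachable mechanism state) contributes
    ci = 0.
    """
    M = cs.local(mechanism) if _needs_local(mechanism) else tuple(sorted(mechanism))
    Zp = cs.local(purview_past) if _needs_local(purview_past) else tuple(sorted(purview_past))
    Zf = cs.local(purview_future) if _needs_local(purview_future) else tuple(sorted(purview_future))
    cause = repertoire(cs, M, Zp, PAST)
    if cause.is_undefined:
        ci = 0.0
    else:
        ci = emd(cause.probs, unconstrained_repertoire(cs, Zp, PAST).probs)
    effect = repertoire(cs, M, Zf, FUTURE)
    ei = emd(effect.probs, unconstrained_repertoire(cs, Zf, FUTURE).probs)
    return InformationValues(ci=ci, ei=ei)


def _needs_local(nodes) -> bool:
    return any(isinstance(x, str) for x in nodes)


_partition_cache: dict = {}


def mip_bipartitions(mechanism: tuple[int, ...], purview: tuple[int, ...]):
    """All valid bipartitions of (mechanism, purview), deterministic order.

    Each part pairs a mechanism subset with a purview subset; the two mechanism
    subsets partition the mechanism and likewise for the purview.  A part may be
    empty on one side but not on both, and the identity partition is excluded.
    Unordered duplicates are removed; the list is sorted by the size of the
    smaller part, then lexicographically by the part masks.
    """
    hit = _partition_cache.get((mechanism, purview))
    if hit is not None:
        return hit
    parts = []
    M, Z = mechanism, purview
    for km in range(len(M) + 1):
        for m1 in combinations(M, km):
            m2 = tuple(i for i in M if i not in m1)
            for kz in range(len(Z) + 1):
                for z1 in combinations(Z, kz):
                    z2 = tuple(i for i in Z if i not in z1)
                    if not m1 and not z1:
                        continue
                    if not m2 and not z2:
                        continue
                    key1 = (_mask(m1), _mask(z1))
                    key2 = (_mask(m2), _mask(z2))
                    if key1 > key2:
                        continue  # unordered: keep one orientation
                    parts.append(MechanismPartition(m1, z1, m2, z2))
    parts.sort(
        key=lambda p: (
            min(len(p.mechanism1) + len(p.purview1), len(p.mechanism2) + len(p.purview2)),
            _mask(p.mechanism1),
            _mask(p.purview1),
        )
    )
    if len(_partition_cache) > 4096:
        _partition_cache.clear()
    _partition_cache[(mechanism, purview)] = parts
    return parts


def phi_mip(
    cs: CandidateSystem,
    mechanism,
    purview,
    direction: str,
) -> tuple[float, MechanismPartition | None]:
    """Integrated information of a mechanism over one purview and direction.

    phi is the minimum over all valid bipartitions of the EMD between the whole
    repertoire and the partitioned repertoire; the minimising partition (MIP) is
    returned alongside.  The first minimiser in the documented enumeration order
    wins ties.
    """
    M = cs.local(mechanism) if _needs_local(mechanism) else tuple(sorted(mechanism))
    Z = cs.local(purview) if _needs_local(purview) else tuple(sorted(purview))
    key = ("phi", direction, _mask(M), _mask(Z))
    hit = cs._cache.get(key)
    if hit is not None:
        return hit
    result = _phi_mip_uncached(cs, M, Z, direction)
    cs._cache[key] = result
    return result


def _phi_mip_uncached(cs, M, Z, direction):
    if not M:
        return 0.0, None
    if not Z:
        return 0.0, None
    whole = repertoire(cs, M, Z, direction)
    if whole.is_undefined:
        return 0.0, None
    # no connections between mechanism and purview in the causal direction
    # => the total partition reproduces the whole repertoire exactly
    cm = cs.cm_local
    if direction == FUTURE:
        linked = any(cm[i, j] for i in M for j in Z)
    else:
        linked = any(cm[j, i] for i in M for j in Z)
    if not linked:
        return 0.0, MechanismPartition(M, (), (), Z)
    best = np.inf
    best_partition = None
    for partition in mip_bipartitions(M, Z):
        part = partitioned_repertoire(cs, partition, direction)
        if part.is_undefined:
            continue
        d = emd(whole.probs, part.probs)
        if d <= PRECISION:
            return 0.0, partition
        if d < best - PRECISION:
            best = d
            best_partition = partition
    if best_partition is None:  # pragma: no cover - defensive
        return 0.0, None
    return float(best), best_partition


def core_repertoire(
    cs: CandidateSystem, mechanism, direction: str
) -> CoreRepertoire:
    """Maximally irreducible cause or effect of a mechanism (MICE search).

    Maximises phi over every purview in the power set of the candidate system.
    The empty purview is the phi = 0 baseline; since purviews are enumerated
    largest-first and replacement requires strictly larger phi, equal phi values
    resolve in favour of the largest purview.
    """
    M = cs.local(mechanism) if _needs_local(mechanism) else tuple(sorted(mechanism))
    key = ("core", direction, _mask(M))
    hit = cs._cache.get(key)
    if hit is not None:
        return hit
    nodes = tuple(range(cs.m))
    best = CoreRepertoire(
        direction=direction,
        purview=(),
        repertoire=Repertoire(direction, (), np.ones(1)),
        phi=0.0,
        mip=None,
    )
    # Rank purviews by their information (EMD from the unconstrained
    # repertoire), an upper bound on phi: the total partition is a valid
    # bipartition whose repertoire is the unconstrained one.  Scanning highest
    # bound first locks in a large incumbent early and prunes most phi solves.
    ranked = []
    for rank, Z in enumerate(
        Z
        for size in range(cs.m, 0, -1)
        for Z in combinations(nodes, size)
    ):
        whole = repertoire(cs, M, Z, direction)
        if whole.is_undefined:
            continue
        unconstrained = unconstrained_repertoire(cs, Z, direction)
        bound = emd(whole.probs, unconstrained.probs)
        if bound > PRECISION:
            ranked.append((-bound, rank, Z, whole))
    ranked.sort()
    best_rank = -1
    for neg_bound, rank, Z, whole in ranked:
        if -neg_bound < best.phi - PRECISION:
            break  # no remaining purview can match the incumbent
        phi, mip = phi_mip(cs, M, Z, direction)
        if phi <= PRECISION:
            continue
        # strict improvement, or an equal phi from an earlier purview in the
        # documented (largest-first, then lexicographic) enumeration order
        if phi > best.phi + PRECISION or (
            phi >= best.phi - PRECISION and (best_rank == -1 or rank < best_rank)
        ):
            best = CoreRepertoire(direction, Z, whole, float(phi), mip)
            best_rank = rank
    cs._cache[key] = best
    return best


def make_concept(cs: CandidateSystem, mechanism) -> Concept | None:
    """Build the concept of a mechanism, or None when it is reducible.

    The concept exists iff phi^Max = min(phi over the core cause, phi over the
    core effect) is positive: a mechanism must have both an irreducible cause
    and an irreducible effect to exist intrinsically.
    """
    M = cs.local(mechanism) if _needs_local(mechanism) else tuple(sorted(mechanism))
    if not M:
        raise ValueError("mechanism must be nonempty")
    cause = core_repertoire(cs, M, PAST)
    if cause.phi <= PRECISION:
        return None
    effect = core_repertoire(cs, M, FUTURE)
    phi_max = min(cause.phi, effect.phi)
    if phi_max <= PRECISION:
        return None
    return Concept(
        cs=cs,
        mechanism=M,
        mechanism_state=tuple(cs.local_state[i] for i in M),
        cause=cause,
        effect=effect,
        phi_max=float(phi_max),
    )


def concepts_match(c1: Concept, c2: Concept, atol: float = 1e-9) -> bool:
    """Whether two concepts are the same point in concept space.

    Used to decide if a concept survives a system cut intact: same mechanism,
    same phi^Max, and the same expanded cause and effect repertoires.
    """
    return (
        c1.mechanism == c2.mechanism
        and abs(c1.phi_max - c2.phi_max) <= atol
        and np.allclose(c1.expanded_cause(), c2.expanded_cause(), atol=atol)
        and np.allclose(c1.expanded_effect(), c2.expanded_effect(), atol=atol)
    )
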