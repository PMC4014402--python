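"""System-level analysis: constellations, big Phi, complexes, condensation.

A candidate system's conceptual structure (constellation) is the set of
concepts of every mechanism in its power set.  Integrated conceptual
information Phi is the extended-EMD distance between the whole constellation
and the constellation of the minimally different unidirectional cut.  A complex
is a candidate set that is a local maximum of Phi among overlapping candidates;
a network condenses into non-overlapping major and minor complexes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .mechanism import PRECISION, Concept, concepts_match, make_concept
from .metrics import constellation_distance, emd
from .network import CandidateSystem, Network, NetworkError, condition_on_background
from .repertoires import FUTURE, PAST, unconstrained_repertoire

log = logging.getLogger(__name__)


@dataclass
class Constellation:
    """All concepts of a candidate system, with the null-concept repertoires.

    The null concept is the unconstrained cause-effect repertoire of the
    candidate set (uniform over past states; input-perturbed product over
    future states) with phi = 0.
    """

    cs: CandidateSystem
    concepts: tuple[Concept, ...]

    @property
    def null_cause(self) -> np.ndarray:
        full = tuple(range(self.cs.m))
        return unconstrained_repertoire(self.cs, full, PAST).probs

    @property
    def null_effect(self) -> np.ndarray:
        full = tuple(range(self.cs.m))
        return unconstrained_repertoire(self.cs, full, FUTURE).probs

    def __len__(self) -> int:
        return len(self.concepts)


@dataclass(frozen=True)
class SystemCut:
    """A unidirectional partition: connections from -> to are noised."""

    from_part: tuple[int, ...]
    to_part: tuple[int, ...]

    def describe(self, labels) -> str:
        return "".join(labels[i] for i in self.from_part) + " -> " + "".join(
            labels[i] for i in self.to_part
        )


@dataclass
class PhiSystem:
    """Big Phi of a candidate system with its MIP cut and both constellations."""

    cs: CandidateSystem
    big_phi: float
    mip: SystemCut | None
    whole: Constellation
    partitioned: Constellation

    def intact_concepts(self, atol: float = 1e-7) -> tuple[Concept, ...]:
        """Concepts of the whole that survive the MIP cut unchanged."""
        survivors = []
        for c in self.whole.concepts:
            for c2 in self.partitioned.concepts:
                if concepts_match(c, c2, atol=atol):
                    survivors.append(c)
                    break
        return tuple(survivors)

    def destroyed_concepts(self, atol: float = 1e-7) -> tuple[Concept, ...]:
        """Concepts reduced to zero or altered away from their intact form."""
        intact = {c.mechanism for c in self.intact_concepts(atol=atol)}
        return tuple(c for c in self.whole.concepts if c.mechanism not in intact)


def concept_space_dimension(cs: CandidateSystem) -> int:
    """Dimension of concept space: one axis per past and per future state."""
    return 2 * (1 << cs.m)


def conceptual_structure(cs: CandidateSystem) -> Constellation:
    """Concepts of every nonempty mechanism subset with positive phi^Max."""
    nodes = tuple(range(cs.m))
    concepts = []
    for size in range(1, cs.m + 1):
        for mechanism in combinations(nodes, size):
            concept = make_concept(cs, mechanism)
            if concept is not None:
                concepts.append(concept)
    return Constellation(cs=cs, concepts=tuple(concepts))


def conceptual_information(constellation: Constellation) -> float:
    """CI: phi-weighted summed distance of all concepts from the null concept."""
    nc = constellation.null_cause
    ne = constellation.null_effect
    total = 0.0
    for c in constellation.concepts:
        total += c.phi_max * (
            emd(c.expanded_cause(), nc) + emd(c.expanded_effect(), ne)
        )
    return total


def cut_system(cs: CandidateSystem, cut: SystemCut) -> CandidateSystem:
    """Candidate system with the cut's crossing connections noised."""
    return cs.apply_cut(cut.from_part, cut.to_part)


def _system_cuts(m: int):
    """All unidirectional bipartite cuts, ordered by (|from|, lexicographic)."""
    nodes = tuple(range(m))
    for size in range(1, m):
        for from_part in combinations(nodes, size):
            to_part = tuple(i for i in nodes if i not in from_part)
            yield SystemCut(from_part, to_part)


def _cut_crosses(cs: CandidateSystem, cut: SystemCut) -> bool:
    return any(cs.cm_local[i, j] for i in cut.from_part for j in cut.to_part)


def system_phi(cs: CandidateSystem) -> PhiSystem:
    """Integrated conceptual information of a candidate system.

    Every bipartition is evaluated in both directions (each ordered cut appears
    once); Phi is the minimum extended-EMD distance between the whole
    constellation and the constellation recomputed on the cut dynamics.  A cut
    that severs no connections leaves the dynamics bit-identical, so Phi is then
    exactly zero — this resolves disconnected, source/sink and feed-forward
    candidates without search.
    """
    if cs.m < 2:
        raise NetworkError("big Phi requires at least 2 elements")
    whole = conceptual_structure(cs)
    for cut in _system_cuts(cs.m):
        if not _cut_crosses(cs, cut):
            partitioned = conceptual_structure(cut_system(cs, cut))
            return PhiSystem(cs, 0.0, cut, whole, partitioned)
    if not whole.concepts:
        # no concepts: nothing for a cut to destroy
        first = next(_system_cuts(cs.m))
        return PhiSystem(cs, 0.0, first, whole, conceptual_structure(cut_system(cs, first)))
    nc, ne = whole.null_cause, whole.null_effect
    best = np.inf
    best_cut = None
    best_const = None
    for cut in _system_cuts(cs.m):
        cut_const = conceptual_structure(cut_system(cs, cut))
        d = constellation_distance(whole.concepts, cut_const.concepts, nc, ne)
        log.debug("cut %s -> distance %.6f", cut, d)
        if d < best - PRECISION:
            best, best_cut, best_const = d, cut, cut_const
            if best <= PRECISION:
                break
    return PhiSystem(cs, float(max(best, 0.0)), best_cut, whole, best_const)


@dataclass
class ComplexEntry:
    """A complex: node subset, its Phi^Max and its MICS."""

    subset: tuple[int, ...]
    labels: tuple[str, ...]
    phi: float
    result: PhiSystem

    @property
    def mics(self) -> Constellation:
        return self.result.whole


@dataclass
class ComplexReport:
    """Condensation of a network into non-overlapping complexes.

    ``complexes`` are pairwise non-overlapping, in order of selection (the
    major complex first); ``excluded`` lists positive-Phi candidates ruled out
    because they overlap a stronger complex; ``evaluated`` maps every candidate
    subset to its Phi.
    """

    network: Network
    state: tuple[int, ...]
    complexes: list[ComplexEntry] = field(default_factory=list)
    excluded: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    evaluated: dict[tuple[int, ...], float] = field(default_factory=dict)

    @property
    def major(self) -> ComplexEntry | None:
        return self.complexes[0] if self.complexes else None

    @property
    def minor(self) -> list[ComplexEntry]:
        return self.complexes[1:]


def _strongly_connected(net: Network, subset: tuple[int, ...]) -> bool:
    g = nx.DiGraph()
    g.add_nodes_from(subset)
    for i in subset:
        for j in subset:
            if i != j and net.cm[i, j]:
                g.add_edge(i, j)
    return nx.is_strongly_connected(g)


def find_complexes(
    net: Network,
    state,
    connectivity_shortcut: bool = True,
    progress: bool = False,
) -> ComplexReport:
    """Condense a network into its major and minor complexes.

    Phi is evaluated for every candidate subset of two or more elements, with
    the complement frozen as background.  Candidates whose induced digraph is
    not strongly connected provably have Phi = 0 (some ordered cut crosses no
    connections) and are skipped unless ``connectivity_shortcut`` is disabled.
    Complexes are selected greedily: the global Phi maximum is a complex, every
    overlapping candidate is excluded, and the procedure repeats on the rest.
    Ties go to the larger candidate, then to lexicographic order.
    """
    state = tuple(int(v) for v in state)
    nodes = tuple(range(net.n))
    candidates = []
    for size in range(net.n, 1, -1):
        candidates.extend(combinations(nodes, size))

    report = ComplexReport(network=net, state=state)
    results: dict[tuple[int, ...], PhiSystem] = {}
    iterator = candidates
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm

            iterator = tqdm(candidates, desc="candidates")
        except ImportError:
            pass
    for subset in iterator:
        if connectivity_shortcut and not _strongly_connected(net, subset):
            report.evaluated[subset] = 0.0
            continue
        cs = condition_on_background(net, subset, state)
        result = system_phi(cs)
        results[subset] = result
        report.evaluated[subset] = result.big_phi
        log.debug("candidate %s Phi=%.6f", subset, result.big_phi)

    remaining = [s for s in candidates if report.evaluated[s] > PRECISION]
    # greedy exclusion: global maximum first; ties to larger sets, then lexicographic
    while remaining:
        best = max(remaining, key=lambda s: (report.evaluated[s], len(s), [-i for i in s]))
        entry = ComplexEntry(
            subset=best,
            labels=tuple(net.labels[i] for i in best),
            phi=report.evaluated[best],
            result=results[best],
        )
        report.complexes.append(entry)
        overlapped = [s for s in remaining if s != best and set(s) & set(best)]
        for s in overlapped:
            report.excluded.append(
                (tuple(net.labels[i] for i in s), report.evaluated[s])
            )
        remaining = [s for s in remaining if s != best and not (set(s) & set(best))]
    report.complexes.sort(key=lambda e: -e.phi)
    return report


def mics_signature(result: PhiSystem, ndigits: int = 7):
    """State-symmetry-invariant shape of a MICS.

    Captures Phi, and per concept the mechanism size, phi^Max, the distances of
    its cause/effect repertoires to the null concept, and the sorted pairwise
    concept distances.  Two constellations with equal signatures are the same
    shape in qualia space even when their repertoires are mirrored by a global
    state flip.
    """
    const = result.whole
    nc, ne = const.null_cause, const.null_effect
    per_concept = sorted(
        (
            len(c.mechanism),
            round(c.phi_max, ndigits),
            round(emd(c.expanded_cause(), nc), ndigits),
            round(emd(c.expanded_effect(), ne), ndigits),
        )
        for c in const.concepts
    )
    from .metrics import concept_distance

    pairwise = sorted(
        round(concept_distance(c1, c2), ndigits)
        for i, c1 in enumerate(const.concepts)
        for c2 in const.concepts[i + 1 :]
    )
    return (round(result.big_phi, ndigits), tuple(per_concept), tuple(pairwise))


def mics_report(entry: ComplexEntry) -> dict:
    """Structured quale report for one complex: concepts, Phi^Max, CI, MIP."""
    from .network import STATE_ORDER

    const = entry.mics
    cs = const.cs
    concepts = []
    for c in const.concepts:
        concepts.append(
            {
                "mechanism": list(c.mechanism_labels),
                "state": list(c.mechanism_state),
                "phi_max": c.phi_max,
                "core_cause": {
                    "purview": [cs.subset_labels[i] for i in c.cause.purview],
                    "phi": c.cause.phi,
                    "repertoire": list(map(float, c.cause.repertoire.probs))
                    if not c.cause.repertoire.is_undefined
                    else None,
                },
                "core_effect": {
                    "purview": [cs.subset_labels[i] for i in c.effect.purview],
                    "phi": c.effect.phi,
                    "repertoire": list(map(float, c.effect.repertoire.probs)),
                },
            }
        )
    return {
        "schema_version": 1,
        "state_ordering": STATE_ORDER,
        "complex": list(entry.labels),
        "state": [cs.state[i] for i in cs.subset],
        "big_phi": entry.phi,
        "conceptual_information": conceptual_information(const),
        "mip_cut": entry.result.mip.describe(cs.subset_labels)
        if entry.result.mip
        else None,
        "n_concepts": len(const),
        "concepts": concepts,
    }
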