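# iitcalc

Integrated information theory (IIT 3.0) calculus for small discrete networks.

`iitcalc` answers, for a network of binary mechanisms (logic gates, linear
threshold units, or explicit probability tables) in a given state, the
questions the IIT 3.0 formalism poses: which mechanisms specify irreducible
causes and effects within the system (*concepts*), how irreducible the
resulting conceptual structure is as a whole (*integrated conceptual
information* Φ), which sets of elements form *complexes*, and how a larger
system *condenses* into a major complex and minor complexes.  It is written for
researchers in computational neuroscience and consciousness science who want an
exact, fully inspectable implementation of the calculus at desk scale (up to
roughly half a dozen elements per candidate system), with brute-force
reference implementations in the test suite for every nontrivial quantity.

## The calculus in brief

A network is specified by a binary connectivity matrix and one update rule per
element; perturbing the elements through all their states yields the
transition probability matrix.  For a candidate set of elements (the rest of
the network is frozen as *background*), a mechanism *M* in its current state
specifies over a purview *Z*:

* a **cause repertoire** p_cause(Z | M = m) — the normalised product over
  mechanism elements of the probability of each element's current value given
  a past purview state, all non-purview inputs perturbed uniformly; and an
  **effect repertoire** p_effect(Z | M = m) — the product over purview elements
  of each element's ON-probability with the mechanism clamped.
* **cause/effect information**: ci = D(p_cause ‖ p^uc_cause),
  ei = D(p_effect ‖ p^uc_effect), cei = min(ci, ei), where p^uc is the
  unconstrained repertoire and D is the earth mover's distance under the
  Hamming metric between binary states.
* **integrated information** φ = D(whole repertoire ‖ repertoire of the
  minimum information partition), minimised over all bipartitions of
  (mechanism, purview) and taken as min(φ_cause, φ_effect) over the best
  (maximally irreducible) purviews.  A mechanism with φ^Max > 0 is a
  **concept**.
* at the system level, the set of all concepts is the **conceptual
  structure**; its distance to the structure of the minimally different
  unidirectional cut — an extended EMD that transports φ-mass between concepts
  and the null concept — is **Φ**.  A candidate set that is a local maximum of
  Φ among overlapping sets is a **complex**, and its constellation is the
  maximally irreducible conceptual structure (MICS).

All transportation problems are solved exactly (a JIT-compiled min-cost-flow
solver, with a linear-programming fallback).

## Worked example

The canonical three-gate system — A = OR(B, C), B = AND(A, C), C = XOR(A, B),
every pair reciprocally connected, current state A, B, C = 1, 0, 0:

```
$ phi fixtures dump abc > abc.json
$ phi concepts abc.json
candidate ABC  state 100
mechanism      phi_max  core cause  core effect
A             0.166667  BC          B
B             0.166667  AC          A
C             0.250000  AB          AB
AB            0.250000  ABC         C
BC            0.333333  AB          A
ABC           0.500000  ABC         AC
CI = 2.111111

$ phi system abc.json
candidate ABC: Phi = 1.916667
MIP cut: AB -> C
concepts: 6 (2 intact under the MIP cut)

$ phi complexes abc.json
major complex ABC: Phi = 1.916667
excluded AC (Phi = 1.000000, overlaps a complex)
excluded BC (Phi = 1.000000, overlaps a complex)
```

Six of the seven nonempty mechanisms are concepts — the pair AC is reducible
(its joint effect can be partitioned without loss, so it specifies nothing
over and above A and C separately).  Each concept is listed with its
irreducibility φ^Max and the purviews of its core cause and core effect; CI is
the φ-weighted summed distance of all concepts from the null concept.  The
system's minimum information partition severs the connections from AB to C:
that cut leaves the first-order concepts A and B untouched and destroys the
other four, and the φ-weighted cost of that destruction is Φ = 1.917.  In the
complex search, ABC outcompetes its overlapping subsets and is the (major)
complex.

The same analyses are available as a library (`build_network`,
`condition_on_background`, `conceptual_structure`, `system_phi`,
`find_complexes`, ...), and `phi condense` emits the full quale report (every
concept with its repertoires, Φ^Max, CI and the MIP cut) as JSON.  Networks
are interchanged as JSON (connectivity + gates + state) or as state-by-node
TPM CSV files; all state indexing is little-endian (node 0 is the least
significant bit), as recorded in every export.

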