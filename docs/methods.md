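# Methods

This note records the model conventions, numerical choices and design
decisions behind `iitcalc`, in the order the computation proceeds.

## Networks, states and background conditions

Elements are binary and update synchronously in discrete time.  Each element's
rule is one of: OR, AND, XOR (odd parity, any arity), PARITY/NONPARITY, COPY,
NOT, strict MAJORITY (an even number k of inputs fires only above k/2 — "the
majority" is read strictly), a linear THRESHOLD unit with per-input weights,
or an explicit TABLE of ON-probabilities per input state.  All non-TABLE gates
are deterministic; noisy mechanisms enter only through TABLE rules.
Degenerate arities follow the usual identities (empty OR is constantly off,
empty AND constantly on); self-loops are allowed.

State indexing is **little-endian** throughout — node index 0 is the least
significant bit of a state index — and every JSON/CSV export records this
string.  The per-node TPM (shape 2^n × n) is derived once at network build
time by evaluating each gate over all past states; the state-by-state TPM is
the product of the per-node Bernoulli factors, since node updates are
conditionally independent given the past state.

A candidate system is a subset of nodes with the complement frozen as
background: background nodes keep their observed values on both sides of every
transition and are never perturbed.  Conditioning is implemented by selecting
the TPM rows with background bits clamped, so choosing the full network as the
candidate reproduces the unconditioned TPM bit for bit.

## Repertoires

Interventions use the uniform (maximum-entropy) perturbation prior.  The
conventions, fixed for reproducibility:

* **Effect repertoire**: product over purview nodes of each node's
  ON-probability given the mechanism clamped to its current state, with every
  non-mechanism input — including candidate nodes outside the mechanism —
  marginalised as an independent uniform noise source.
* **Cause repertoire**: normalised product over mechanism nodes of the
  probability of each node's current value given the purview state, with
  non-purview inputs marginalised uniformly.  The per-node product implements
  independent "virtual" inputs, discounting correlations that are due to
  shared non-mechanism sources.  A zero normaliser (the mechanism state is
  unreachable under the clamped background) flags the repertoire undefined;
  undefined cause repertoires contribute ci = 0 and φ = 0 downstream.
* The unconstrained cause repertoire is uniform; the unconstrained effect
  repertoire is the input-perturbed product of node marginals (not uniform).
* An empty purview yields the scalar distribution [1]; an empty mechanism
  yields the unconstrained repertoire.
* Expansion to a larger purview multiplies in the unconstrained repertoire of
  the added nodes, so marginalising back recovers the original exactly.

Partitioned repertoires are tensor products of the parts' repertoires,
assembled in the global little-endian node order; cutting a connection is thus
equivalent to injecting independent noise on it.

## Distances

The ground metric between purview states is the **Hamming distance**; the
source text motivates state sensitivity without naming a metric, and Hamming
is the canonical choice for binary elements.  The earth mover's distance is
solved exactly: shared mass is cancelled first (valid for any metric ground
distance), single-source/single-sink cases are closed-form, and the remainder
goes to a successive-shortest-path min-cost-flow solver JIT-compiled with
numba (exact for these problem sizes; a scipy HiGHS linear-programming solve
is the fallback and the test-suite cross-check).  Values below 1e-12 are
clamped to zero; φ comparisons use a precision of 1e-10.

Concept-to-concept distance is the cause-side EMD plus the effect-side EMD
after expanding both concepts over the candidate's full past and future state
spaces (two separate EMDs rather than one in the joint space, matching the
summed form of the source definitions).  The constellation distance is a
general transportation problem: φ-mass may move between any pair of concepts
at their concept distance, with surplus/deficit exchanged with the null
concept (the unconstrained cause-effect repertoire of the uncut candidate).
The general form was chosen over a concepts-to-null-only form because it
subsumes the destroyed-concepts special case, which the tests verify it
reproduces.

## Mechanism level

φ over a purview is minimised over all bipartitions of (mechanism, purview):
each part pairs a mechanism subset with a purview subset, a part may be empty
on one side but not both, and the identity partition is excluded.  Candidate
partition distances are compared **un-normalised** (raw EMD); the available
text never normalises, and this choice is flagged here because other
formulations do.  Partitions are enumerated in a fixed order (smaller-part
size, then part masks) and the first minimiser wins ties, so results are
bit-for-bit reproducible.

The core cause/effect search maximises φ over the power set of purviews.  The
empty purview is the φ = 0 baseline.  Purviews are enumerated largest-first,
then lexicographically, and a candidate must *strictly* beat the incumbent, so
equal φ values resolve in favour of the largest purview (the rule for a unit
with strong and weak inputs, where the strong pair and larger supersets tie).
Internally the scan is ordered by each purview's information — an upper bound
on its φ, since the total partition produces the unconstrained repertoire —
which prunes most partition searches without affecting the result; a concept's
φ^Max is min(cause, effect).  When every purview gives φ = 0 the core purview
is reported as empty; the mechanism is not a concept and the choice is
cosmetic.  Repertoires, φ values and core searches are memoised per candidate
system; caching is semantically transparent (keys are the full argument
tuples) and the brute-force parity tests run with no caching at all.

## System level

Unidirectional cuts noise every connection from one part to its complement;
both directions of every bipartition are evaluated (each ordered cut once) and
Φ is the minimum constellation distance between the whole constellation and
the constellation **recomputed from scratch on the cut dynamics**.  Concepts
of a cut system are expanded with the cut system's own unconstrained
repertoires; the null concept reference is the uncut candidate's.

A cut that crosses no connections leaves the conditioned dynamics
bit-identical, so Φ = 0 exactly.  This is a theorem of the formalism, not an
approximation, and it resolves three families at once: disconnected
candidates, candidates containing an element with no inputs from (or no
outputs to) the rest, and every acyclic (feed-forward) candidate — if the
induced digraph is not strongly connected, some ordered cut along its
condensation order crosses nothing.  `system_phi` checks this before
searching; `find_complexes` skips candidates whose induced digraph is not
strongly connected (a flag disables the shortcut, and the honest brute-force
oracle in the tests confirms parity).

Complex search evaluates Φ for every candidate subset of two or more elements
(single elements cannot be partitioned), each conditioned on its own
background.  Local-maximum semantics are implemented greedily: the global Φ
maximum is a complex, all overlapping candidates are excluded, and the
procedure repeats on the remainder; ties go to the larger candidate, then to
lexicographic order.  This reproduces simultaneous major/minor complexes and
guarantees reported complexes never overlap.  "Identical MICS" claims (e.g.
across the four states of the photodiode, or between the photodiode and a
thermistor with the same wiring) are compared via a constellation signature —
Φ, per-concept mechanism size, φ^Max and distances to the null concept, and
the sorted pairwise concept distances — because a global state flip mirrors
the repertoire arrays while preserving the constellation's shape.

## Fixtures and the random generator

Fixtures marked *text-exact* are fully determined by their written
description: the OR/AND/XOR triad in state 100, the photodiode (threshold-2
detector with a COPY predictor and two external inputs as background, analysed
with exactly one external input on), the all-to-all five-OR network with
self-loops in the all-on state, the four-COPY ring with all elements off, and
the input-only/output-only motifs.  Fixtures marked *stand-in* realise
architectures whose exact wiring was only ever shown graphically (the modular,
specialised, condensation and segment/dot systems, and the
independent/integrated pair motifs); their wirings are frozen in
`fixtures.py` and only qualitative structure is asserted — counts and kinds of
complexes, existence or reducibility of particular mechanisms — never their
numeric φ/Φ values.  Two stand-in choices worth noting: the modular network's
cross-module links run one way (so the whole system is provably not a
complex, preserving the tested claim that only the three modules are), and
the condensation network couples its DE pair to the ABC triad through C→D and
D→A with a sourceless feed-forward fringe (H→K→L), so ABCDE is strongly
integrated yet excluded by the stronger ABC.

The feed-forward unfolding replicates every element once per layer over a
horizon k; layer 0 holds the initial state, deeper layers apply the original
gates to the previous layer.  For an autonomous network the initial state is
the entire input, so the exhaustive input-output equivalence check ranges over
all 2^n initial states and compares layer k after k steps with the recurrent
trajectory.  The construction is acyclic by construction and therefore
supports no complex.

The random generator draws Erdős–Rényi directed connectivity (repaired to
guarantee at least one input per node and weak connectivity) and uniform gate
choices from a fixed deterministic library, and is bit-reproducible from its
seed.  It emulates the study conditions — small, binary, synchronous,
deterministic networks exhaustively perturbable through all states — and none
of the features of real neural data: continuous variables, stochastic
dynamics, partial observability, unknown update grain.  Passing tests
therefore validate the calculus, not its applicability to recorded data.

## Problem sizes and limitations

Everything is exact and exhaustive, so cost grows as roughly 4^n per mechanism
search and catastrophically with candidate size at the system level; the
package is comfortable at up to 5–6 element candidates (the test suite's
largest honest Φ computations are 5-node systems, and the largest brute-force
oracle parity runs are 4-node), and is not intended beyond a dozen elements.
Only bipartitions of mechanisms are considered (all source definitions and
examples are bipartitions); multi-valued elements, non-uniform intervention
priors, observational repertoires and spatio-temporal grain optimisation are
out of scope.
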