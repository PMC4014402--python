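"""Independent brute-force reference implementations used by the tests.

Everything here recomputes quantities from first principles with naive loops
and no caching, sharing nothing with the production code paths except the
network data structures (labels, connectivity, gate truth tables):

* per-node conditional probabilities by evaluating gates state by state;
* cause/effect repertoires by explicit enumeration over past states;
* small phi by enumerating every ordered bipartition of (mechanism, purview);
* core purviews by exhaustive power-set search with the documented tie-break;
* big Phi by evaluating every ordered unidirectional cut honestly;
* EMD via an exhaustive linear-programming transportation solve (scipy HiGGS)
  and, for the inner loops of the phi/Phi oracles, a hand-written pure-Python
  successive-shortest-path min-cost flow.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import linprog

PAST, FUTURE = "past", "future"


# ---------------------------------------------------------------------------
# exact transportation solvers


def lp_transport(supply, demand, cost) -> float:
    """Exhaustive transportation solve as a dense LP (HiGHS)."""
    supply = np.asarray(supply, float)
    demand = np.asarray(demand, float)
    cost = np.asarray(cost, float)
    m, n = cost.shape
    A = np.zeros((m + n, m * n))
    for i in range(m):
        A[i, i * n : (i + 1) * n] = 1.0
    for j in range(n):
        A[m + j, j::n] = 1.0
    rhs = np.concatenate([supply, demand])
    res = linprog(cost.ravel(), A_eq=A, b_eq=rhs, method="highs")
    assert res.success, res.message
    return float(res.fun)


def py_transport(supply, demand, cost) -> float:
    """Pure-Python successive-shortest-path min-cost flow (exact)."""
    a = [float(x) for x in supply]
    b = [float(x) for x in demand]
    m, n = len(a), len(b)
    flow = [[0.0] * n for _ in range(m)]
    total = sum(b)
    value = 0.0
    while total > 1e-12:
        INF = float("inf")
        ds = [0.0 if a[i] > 1e-15 else INF for i in range(m)]
        root = [a[i] > 1e-15 for i in range(m)]
        dt = [INF] * n
        pt = [-1] * n
        ps = [-1] * m
        for _ in range(m + n + 1):
            changed = False
            for i in range(m):
                if ds[i] < INF:
                    for j in range(n):
                        nd = ds[i] + cost[i][j]
                        if nd < dt[j] - 1e-15:
                            dt[j], pt[j] = nd, i
                            changed = True
            for j in range(n):
                if dt[j] < INF:
                    for i in range(m):
                        if flow[i][j] > 1e-15 and dt[j] - cost[i][j] < ds[i] - 1e-15:
                            ds[i] = dt[j] - cost[i][j]
                            ps[i] = j
                            root[i] = False
                            changed = True
            if not changed:
                break
        best = min(
            (j for j in range(n) if b[j] > 1e-15), key=lambda j: dt[j], default=None
        )
        assert best is not None
        # bottleneck
        bott = b[best]
        j = best
        while True:
            i = pt[j]
            if root[i]:
                bott = min(bott, a[i])
                break
            j = ps[i]
            bott = min(bott, flow[i][j])
        j = best
        while True:
            i = pt[j]
            flow[i][j] += bott
            value += bott * cost[i][j]
            if root[i]:
                a[i] -= bott
                break
            j = ps[i]
            flow[i][j] -= bott
            value -= bott * cost[i][j]
        b[best] -= bott
        total -= bott
    return value


def hamming(x: int, y: int) -> int:
    return bin(x ^ y).count("1")


def oracle_emd(p, q) -> float:
    """Exhaustive EMD over full supports (no cancellation), via the LP solver."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    n_states = len(p)
    cost = [[float(hamming(x, y)) for y in range(n_states)] for x in range(n_states)]
    return lp_transport(p, q, cost)


def fast_oracle_emd(p, q) -> float:
    """EMD with shared mass cancelled first (metric identity), for inner loops."""
    diff = [float(pi - qi) for pi, qi in zip(p, q)]
    pos = [(i, d) for i, d in enumerate(diff) if d > 1e-12]
    neg = [(i, -d) for i, d in enumerate(diff) if d < -1e-12]
    if not pos or not neg:
        return 0.0
    if len(pos) == 1:
        i = pos[0][0]
        return sum(mass * hamming(i, j) for j, mass in neg)
    if len(neg) == 1:
        j = neg[0][0]
        return sum(mass * hamming(i, j) for i, mass in pos)
    cost = [[float(hamming(i, j)) for j, _ in neg] for i, _ in pos]
    return py_transport([m for _, m in pos], [m for _, m in neg], cost)


# ---------------------------------------------------------------------------
# naive candidate-system dynamics


def oracle_p_on(net, subset, state) -> np.ndarray:
    """Conditioned per-node ON probabilities, by gate evaluation per state."""
    subset = tuple(sorted(subset))
    m = len(subset)
    p = np.zeros((1 << m, m))
    for s in range(1 << m):
        full = list(state)
        for k, i in enumerate(subset):
            full[i] = (s >> k) & 1
        for k, j in enumerate(subset):
            ins = net.inputs_of(j)
            row = np.array([[full[i] for i in ins]], dtype=int)
            p[s, k] = float(net.gates[j].on_probability(row)[0])
    return p


def oracle_joint_tpm(net, subset, state) -> np.ndarray:
    """Conditioned state-by-state TPM by multiplying per-node factors."""
    p = oracle_p_on(net, subset, state)
    m = p.shape[1]
    T = np.ones((1 << m, 1 << m))
    for s in range(1 << m):
        for t in range(1 << m):
            for k in range(m):
                bit = (t >> k) & 1
                T[s, t] *= p[s, k] if bit else 1.0 - p[s, k]
    return T


def oracle_cut_p_on(p_on, cm_local, from_part, to_part) -> np.ndarray:
    m = p_on.shape[1]
    out = p_on.copy()
    for j in to_part:
        cut_in = [i for i in from_part if cm_local[i, j]]
        if not cut_in:
            continue
        for s in range(1 << m):
            vals = []
            for assign in range(1 << len(cut_in)):
                s2 = s
                for b, i in enumerate(cut_in):
                    s2 = (s2 & ~(1 << i)) | (((assign >> b) & 1) << i)
                vals.append(p_on[s2, j])
            out[s, j] = sum(vals) / len(vals)
    return out


# ---------------------------------------------------------------------------
# naive repertoires


def oracle_cause(p_on, local_state, M, Z):
    """Normalised product over mechanism nodes, explicit state loops."""
    m = p_on.shape[1]
    if not M:
        return np.full(1 << len(Z), 1.0 / (1 << len(Z)))
    probs = np.ones(1 << len(Z))
    for zi in range(1 << len(Z)):
        val = 1.0
        for i in M:
            tot, cnt = 0.0, 0
            for s in range(1 << m):
                if all(((s >> z) & 1) == ((zi >> k) & 1) for k, z in enumerate(Z)):
                    tot += p_on[s, i]
                    cnt += 1
            pi = tot / cnt
            val *= pi if local_state[i] == 1 else 1.0 - pi
        probs[zi] = val
    t = probs.sum()
    if t <= 1e-12:
        return None
    return probs / t


def oracle_effect(p_on, local_state, M, Z):
    """Product over purview nodes of the mechanism-clamped marginals."""
    m = p_on.shape[1]
    probs = np.ones(1 << len(Z))
    for k, j in enumerate(Z):
        tot, cnt = 0.0, 0
        for s in range(1 << m):
            if all(((s >> i) & 1) == local_state[i] for i in M):
                tot += p_on[s, j]
                cnt += 1
        pj = tot / cnt
        for zi in range(1 << len(Z)):
            probs[zi] *= pj if (zi >> k) & 1 else 1.0 - pj
    return probs


def oracle_repertoire(p_on, local_state, M, Z, direction):
    if direction == PAST:
        return oracle_cause(p_on, local_state, M, Z)
    return oracle_effect(p_on, local_state, M, Z)


def oracle_combine(Z1, r1, Z2, r2):
    Z = tuple(sorted(Z1 + Z2))
    if r1 is None or r2 is None:
        return Z, None
    out = np.zeros(1 << len(Z))
    for zi in range(1 << len(Z)):
        i1 = i2 = 0
        for k, node in enumerate(Z):
            bit = (zi >> k) & 1
            if node in Z1:
                i1 |= bit << Z1.index(node)
            else:
                i2 |= bit << Z2.index(node)
        out[zi] = r1[i1] * r2[i2]
    return Z, out


def oracle_expand(p_on, local_state, Z, probs, target, direction):
    rest = tuple(i for i in target if i not in Z)
    if not rest:
        return probs
    unc = oracle_repertoire(p_on, local_state, (), rest, direction)
    _, out = oracle_combine(Z, probs, rest, unc)
    return out


# ---------------------------------------------------------------------------
# naive phi / core / concept / big Phi


def oracle_phi(p_on, local_state, M, Z, direction) -> float:
    """Small phi by enumerating every ordered bipartition (no shortcuts)."""
    if not M or not Z:
        return 0.0
    whole = oracle_repertoire(p_on, local_state, M, Z, direction)
    if whole is None:
        return 0.0
    best = np.inf
    for km in range(len(M) + 1):
        for m1 in combinations(M, km):
            m2 = tuple(i for i in M if i not in m1)
            for kz in range(len(Z) + 1):
                for z1 in combinations(Z, kz):
                    z2 = tuple(i for i in Z if i not in z1)
                    if (not m1 and not z1) or (not m2 and not z2):
                        continue
                    r1 = oracle_repertoire(p_on, local_state, m1, z1, direction)
                    r2 = oracle_repertoire(p_on, local_state, m2, z2, direction)
                    _, part = oracle_combine(z1, r1, z2, r2)
                    if part is None:
                        continue
                    d = fast_oracle_emd(whole, part)
                    if d < best:
                        best = d
    return float(best)


def oracle_core(p_on, local_state, M, direction):
    """Exhaustive purview search; largest purview wins phi ties."""
    m = p_on.shape[1]
    best_phi, best_Z = 0.0, ()
    for size in range(m, 0, -1):
        for Z in combinations(range(m), size):
            phi = oracle_phi(p_on, local_state, M, Z, direction)
            if phi > best_phi + 1e-10:
                best_phi, best_Z = phi, Z
    return best_phi, best_Z


def oracle_concepts(p_on, local_state):
    """All concepts (phi_max > 0) of a candidate system, naive search."""
    m = p_on.shape[1]
    full = tuple(range(m))
    concepts = []
    for size in range(1, m + 1):
        for M in combinations(range(m), size):
            phi_c, Zc = oracle_core(p_on, local_state, M, PAST)
            if phi_c <= 1e-10:
                continue
            phi_e, Ze = oracle_core(p_on, local_state, M, FUTURE)
            phi = min(phi_c, phi_e)
            if phi <= 1e-10:
                continue
            cause = oracle_cause(p_on, local_state, M, Zc)
            effect = oracle_effect(p_on, local_state, M, Ze)
            concepts.append(
                {
                    "mechanism": M,
                    "phi": phi,
                    "cause": oracle_expand(p_on, local_state, Zc, cause, full, PAST),
                    "effect": oracle_expand(p_on, local_state, Ze, effect, full, FUTURE),
                }
            )
    return concepts


def oracle_constellation_distance(c1, c2, null_cause, null_effect) -> float:
    def dist(a, b):
        return fast_oracle_emd(a["cause"], b["cause"]) + fast_oracle_emd(
            a["effect"], b["effect"]
        )

    def dist_null(a):
        return fast_oracle_emd(a["cause"], null_cause) + fast_oracle_emd(
            a["effect"], null_effect
        )

    if not c1 and not c2:
        return 0.0
    if not c2:
        return sum(a["phi"] * dist_null(a) for a in c1)
    if not c1:
        return sum(b["phi"] * dist_null(b) for b in c2)
    m, n = len(c1), len(c2)
    cost = [[0.0] * (n + 1) for _ in range(m + 1)]
    for i, a in enumerate(c1):
        for j, b in enumerate(c2):
            cost[i][j] = dist(a, b)
        cost[i][n] = dist_null(a)
    for j, b in enumerate(c2):
        cost[m][j] = dist_null(b)
    supply = [a["phi"] for a in c1] + [sum(b["phi"] for b in c2)]
    demand = [b["phi"] for b in c2] + [sum(a["phi"] for a in c1)]
    return py_transport(supply, demand, cost)


def oracle_system_phi(net, subset, state) -> float:
    """Big Phi by honest evaluation of every ordered unidirectional cut."""
    subset = tuple(sorted(subset))
    m = len(subset)
    p_on = oracle_p_on(net, subset, state)
    local_state = tuple(state[i] for i in subset)
    cm_local = np.zeros((m, m), dtype=bool)
    for a, i in enumerate(subset):
        for b, j in enumerate(subset):
            cm_local[a, b] = bool(net.cm[i, j])
    whole = oracle_concepts(p_on, local_state)
    full = tuple(range(m))
    null_cause = oracle_repertoire(p_on, local_state, (), full, PAST)
    null_effect = oracle_repertoire(p_on, local_state, (), full, FUTURE)
    best = np.inf
    nodes = tuple(range(m))
    for size in range(1, m):
        for from_part in combinations(nodes, size):
            to_part = tuple(i for i in nodes if i not in from_part)
            cut_p = oracle_cut_p_on(p_on, cm_local, from_part, to_part)
            cut_concepts = oracle_concepts(cut_p, local_state)
            d = oracle_constellation_distance(
                whole, cut_concepts, null_cause, null_effect
            )
            if d < best:
                best = d
    return float(best)
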