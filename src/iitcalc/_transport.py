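"""Exact transportation solver (successive shortest augmenting paths).

Solves min sum_ij f_ij * cost_ij subject to row sums a and column sums b,
f >= 0, on a dense bipartite graph.  Augmenting along shortest paths in the
residual network (Bellman-Ford, since residual arcs may have negative cost)
from a zero flow is the classical successive-shortest-path algorithm and yields
an exact optimum; every augmentation exhausts at least one remaining supply or
demand, so at most m + n - 1 augmentations are needed.

Returns -1.0 if the iteration guard trips (numerically degenerate input); the
caller then falls back to a linear-programming solve.
"""

import numpy as np
from numba import njit

_INF = 1e30
_TOL = 1e-14


@njit(cache=True)
def transport_cost(a, b, cost):  # pragma: no cover - compiled
    m = a.shape[0]
    n = b.shape[0]
    flow = np.zeros((m, n))
    rem_a = a.copy()
    rem_b = b.copy()
    total = 0.0
    for j in range(n):
        total += rem_b[j]
    value = 0.0
    guard = 4 * (m + n) + 16

    while total > 1e-12:
        guard -= 1
        if guard < 0:
            return -1.0
        dist_s = np.full(m, _INF)
        dist_t = np.full(n, _INF)
        pred_t = np.full(n, -1, dtype=np.int64)  # source feeding sink j
        pred_s = np.full(m, -1, dtype=np.int64)  # sink feeding source i backward
        for i in range(m):
            if rem_a[i] > _TOL:
                dist_s[i] = 0.0
                pred_s[i] = -2  # root
        for _ in range(m + n + 1):
            changed = False
            for i in range(m):
                di = dist_s[i]
                if di < _INF:
                    for j in range(n):
                        nd = di + cost[i, j]
                        if nd < dist_t[j] - 1e-15:
                            dist_t[j] = nd
                            pred_t[j] = i
                            changed = True
            for j in range(n):
                dj = dist_t[j]
                if dj < _INF:
                    for i in range(m):
                        if flow[i, j] > _TOL:
                            nd = dj - cost[i, j]
                            if nd < dist_s[i] - 1e-15:
                                dist_s[i] = nd
                                pred_s[i] = j
                                changed = True
            if not changed:
                break
        best = -1
        best_d = _INF
        for j in range(n):
            if rem_b[j] > _TOL and dist_t[j] < best_d:
                best_d = dist_t[j]
                best = j
        if best < 0:
            return -1.0
        # bottleneck along the augmenting path
        bottleneck = rem_b[best]
        j = best
        steps = 0
        while True:
            steps += 1
            if steps > m + n + 2:
                return -1.0
            i = pred_t[j]
            if pred_s[i] == -2:
                if rem_a[i] < bottleneck:
                    bottleneck = rem_a[i]
                break
            j = pred_s[i]
            if flow[i, j] < bottleneck:
                bottleneck = flow[i, j]
        # augment
        j = best
        steps = 0
        while True:
            steps += 1
            if steps > m + n + 2:
                return -1.0
            i = pred_t[j]
            flow[i, j] += bottleneck
            value += bottleneck * cost[i, j]
            if pred_s[i] == -2:
                rem_a[i] -= bottleneck
                break
            j = pred_s[i]
            flow[i, j] -= bottleneck
            value -= bottleneck * cost[i, j]
        rem_b[best] -= bottleneck
        total -= bottleneck
    if value < 0.0:
        value = 0.0
    return value
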