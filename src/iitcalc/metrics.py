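"""Earth mover's distance on binary state spaces and between constellations.

The ground metric between two purview states is their Hamming distance: moving
probability mass between states that differ in two elements costs twice as much
as between states differing in one.  Distances between whole constellations of
concepts use an extended EMD whose ground metric is the concept-to-concept
distance (cause-side EMD plus effect-side EMD over the full candidate space),
with surplus or deficit phi-mass exchanged with the null concept.

Transportation problems are solved exactly.  The production path is a
successive-shortest-path min-cost-flow solver JIT-compiled with numba; if numba
is unavailable at import time the package falls back to the HiGHS linear
programming solver in scipy.  Degeneracies are resolved at a tolerance of 1e-9.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-12

_hamming_cache: dict[int, np.ndarray] = {}
_emd_cache: dict = {}
_EMD_CACHE_MAX = 1 << 20


def hamming_ground_matrix(n_nodes: int) -> np.ndarray:
    """Pairwise Hamming distances between the 2**n little-endian states."""
    ground = _hamming_cache.get(n_nodes)
    if ground is None:
        idx = np.arange(1 << n_nodes, dtype=np.int64)
        xor = idx[:, None] ^ idx[None, :]
        ground = np.zeros(xor.shape, dtype=float)
        for k in range(n_nodes):
            ground += (xor >> k) & 1
        ground.setflags(write=False)
        _hamming_cache[n_nodes] = ground
    return ground


try:  # pragma: no cover - exercised implicitly by every test
    from ._transport import transport_cost as _transport_numba

    # warm the JIT once at import so first use is not charged compile time
    _transport_numba(
        np.array([0.5, 0.5]), np.array([0.25, 0.75]), np.array([[0.0, 1.0], [1.0, 0.0]])
    )
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _transport_numba = None
    HAVE_NUMBA = False


def _transport_linprog(a: np.ndarray, b: np.ndarray, cost: np.ndarray) -> float:
    """Exact transportation LP via scipy's HiGHS solver (fallback path)."""
    from scipy.optimize import linprog
    from scipy.sparse import coo_matrix

    m, n = cost.shape
    rows, cols, data = [], [], []
    for i in range(m):
        for j in range(n):
            k = i * n + j
            rows.append(i)
            cols.append(k)
            data.append(1.0)
            rows.append(m + j)
            cols.append(k)
            data.append(1.0)
    A = coo_matrix((data, (rows, cols)), shape=(m + n, m * n))
    rhs = np.concatenate([a, b])
    res = linprog(cost.ravel(), A_eq=A, b_eq=rhs, method="highs")
    if not res.success:  # pragma: no cover - transportation LPs are feasible
        raise RuntimeError(f"transportation solve failed: {res.message}")
    return float(res.fun)


def transport(a: np.ndarray, b: np.ndarray, cost: np.ndarray) -> float:
    """Minimal cost of moving supplies ``a`` onto demands ``b``.

    ``a`` and ``b`` must have equal totals (up to numerical noise); ``cost``
    holds nonnegative pairwise unit transport costs.
    """
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    cost = np.ascontiguousarray(cost, dtype=float)
    if a.sum() <= EPS or b.sum() <= EPS:
        return 0.0
    if _transport_numba is not None:
        value = _transport_numba(a, b, cost)
        if value >= 0.0:
            return float(value)
    return _transport_linprog(a, b, cost)


def emd(p: np.ndarray, q: np.ndarray, ground: np.ndarray | None = None) -> float:
    """Earth mover's distance between two distributions on the same space.

    With ``ground`` omitted the space is taken to be the binary states of
    log2(len(p)) elements under the Hamming metric.  Shared mass is cancelled
    first (valid for any metric ground distance), which makes comparisons of
    nearly identical repertoires essentially free.
    """
    if not isinstance(p, np.ndarray):
        p = np.asarray(p, dtype=float)
    if not isinstance(q, np.ndarray):
        q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"mismatched supports: {p.shape} vs {q.shape}")
    diff = p - q
    pos = np.flatnonzero(diff > EPS)
    if pos.size == 0:
        return 0.0
    neg = np.flatnonzero(diff < -EPS)
    if neg.size == 0:
        return 0.0
    use_cache = ground is None
    if ground is None:
        n_nodes = int(round(np.log2(len(p))))
        if (1 << n_nodes) != len(p):
            raise ValueError("distribution length is not a power of two")
        ground = hamming_ground_matrix(n_nodes)
    a = diff[pos]
    b = -diff[neg]
    sub = ground[np.ix_(pos, neg)]
    if pos.size == 1:
        return float(b @ sub[0])
    if neg.size == 1:
        return float(a @ sub[:, 0])
    key = None
    if use_cache:
        key = (
            pos.tobytes(),
            neg.tobytes(),
            np.round(a, 12).tobytes(),
            np.round(b, 12).tobytes(),
            len(p),
        )
        hit = _emd_cache.get(key)
        if hit is not None:
            return hit
    value = transport(a, b, sub)
    if value < 1e-12:
        value = 0.0
    if key is not None:
        if len(_emd_cache) > _EMD_CACHE_MAX:
            _emd_cache.clear()
        _emd_cache[key] = value
    return value


def concept_distance(c1, c2) -> float:
    """Distance between two concepts in concept space.

    Both concepts are expanded over the candidate system's full past and future
    state spaces; the distance is the cause-side EMD plus the effect-side EMD.
    """
    return emd(c1.expanded_cause(), c2.expanded_cause()) + emd(
        c1.expanded_effect(), c2.expanded_effect()
    )


def _distance_to_null(concept, null_cause: np.ndarray, null_effect: np.ndarray) -> float:
    return emd(concept.expanded_cause(), null_cause) + emd(
        concept.expanded_effect(), null_effect
    )


def constellation_distance(
    concepts1,
    concepts2,
    null_cause: np.ndarray,
    null_effect: np.ndarray,
) -> float:
    """Extended EMD between two constellations of concepts.

    The phi-mass of each concept in the first constellation must be transported
    onto the concepts of the second; the ground distance between concepts is
    :func:`concept_distance`, and surplus/deficit mass is exchanged with the
    null concept (the unconstrained cause-effect repertoire) at each concept's
    distance from it.  When the second constellation is empty this reduces to
    the phi-weighted sum of distances from each concept to the null concept.
    """
    concepts1 = list(concepts1)
    concepts2 = list(concepts2)
    phi1 = np.array([c.phi_max for c in concepts1], dtype=float)
    phi2 = np.array([c.phi_max for c in concepts2], dtype=float)
    if not concepts1 and not concepts2:
        return 0.0
    null1 = np.array([_distance_to_null(c, null_cause, null_effect) for c in concepts1])
    null2 = np.array([_distance_to_null(c, null_cause, null_effect) for c in concepts2])
    if not concepts2:
        return float(phi1 @ null1)
    if not concepts1:
        return float(phi2 @ null2)
    m, n = len(concepts1), len(concepts2)
    cost = np.zeros((m + 1, n + 1))
    for i, c1 in enumerate(concepts1):
        for j, c2 in enumerate(concepts2):
            cost[i, j] = concept_distance(c1, c2)
    cost[:m, n] = null1
    cost[m, :n] = null2
    supply = np.concatenate([phi1, [phi2.sum()]])
    demand = np.concatenate([phi2, [phi1.sum()]])
    value = transport(supply, demand, cost)
    return 0.0 if value < 1e-12 else float(value)
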