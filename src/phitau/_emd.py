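"""Exact earth mover's distance for small discrete spaces.

Repertoire comparisons and constellation distances in the Φ computation need
the exact EMD between probability (or φ-mass) vectors over at most a handful
of points.  This module solves the underlying transportation problem exactly
with a successive-shortest-path min-cost-flow routine; state spaces never
exceed 2³ points plus a null node, so the dense O(V²) implementation is both
exact and fast.  The solver is cross-checked against an independent linear
program in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["transport_cost", "emd", "hamming_matrix", "hamming_emd"]

_MASS_EPS = 1e-12


@njit(cache=True)
def _transport(a, b, D):  # pragma: no cover - exercised via transport_cost
    m = a.shape[0]
    n = b.shape[0]
    ra = a.copy()
    rb = b.copy()
    f = np.zeros((m, n))
    pu = np.zeros(m)
    pv = np.zeros(n)
    total = 0.0
    INF = 1e18
    while True:
        rem = 0.0
        for i in range(m):
            rem += ra[i]
        if rem <= _MASS_EPS:
            break
        # Dijkstra on the residual bipartite graph with reduced costs.
        dist = np.full(m + n, INF)
        visited = np.zeros(m + n, dtype=np.bool_)
        parent = np.full(m + n, -1, dtype=np.int64)
        for i in range(m):
            if ra[i] > _MASS_EPS:
                dist[i] = 0.0
        for _ in range(m + n):
            u = -1
            best = INF
            for v in range(m + n):
                if not visited[v] and dist[v] < best:
                    best = dist[v]
                    u = v
            if u == -1:
                break
            visited[u] = True
            if u < m:
                for j in range(n):
                    rc = D[u, j] + pu[u] - pv[j]
                    if rc < 0.0:
                        rc = 0.0
                    nd = dist[u] + rc
                    if nd < dist[m + j] - 1e-15:
                        dist[m + j] = nd
                        parent[m + j] = u
            else:
                j = u - m
                for i in range(m):
                    if f[i, j] > _MASS_EPS:
                        rc = pv[j] - pu[i] - D[i, j]
                        if rc < 0.0:
                            rc = 0.0
                        nd = dist[u] + rc
                        if nd < dist[i] - 1e-15:
                            dist[i] = nd
                            parent[i] = m + j
        # Closest sink with unmet demand.
        t = -1
        best = INF
        for j in range(n):
            if rb[j] > _MASS_EPS and dist[m + j] < best:
                best = dist[m + j]
                t = j
        if t == -1:
            break  # residual mass below tolerance / numerically disconnected
        for i in range(m):
            pu[i] += dist[i] if dist[i] < best else best
        for j in range(n):
            pv[j] += dist[m + j] if dist[m + j] < best else best
        # Bottleneck along the shortest augmenting path.
        amt = rb[t]
        node = m + t
        while parent[node] != -1:
            p = parent[node]
            if node < m and f[node, p - m] < amt:
                amt = f[node, p - m]
            node = p
        if ra[node] < amt:
            amt = ra[node]
        ra[node] -= amt
        rb[t] -= amt
        node = m + t
        while parent[node] != -1:
            p = parent[node]
            if node >= m:
                f[p, node - m] += amt
                total += amt * D[p, node - m]
            else:
                f[node, p - m] -= amt
                total -= amt * D[node, p - m]
            node = p
    return total


def transport_cost(supply: np.ndarray, demand: np.ndarray, costs: np.ndarray) -> float:
    """Minimum cost of moving ``supply`` onto ``demand`` under unit ``costs``.

    ``sum(supply)`` and ``sum(demand)`` must agree (to numerical tolerance).
    """
    a = np.ascontiguousarray(supply, dtype=np.float64)
    b = np.ascontiguousarray(demand, dtype=np.float64)
    if a.min() < 0.0 or b.min() < 0.0:
        a = np.maximum(a, 0.0)
        b = np.maximum(b, 0.0)
    D = np.ascontiguousarray(costs, dtype=np.float64)
    if abs(a.sum() - b.sum()) > 1e-9 * max(1.0, a.sum()):
        raise ValueError("supply and demand masses differ")
    return float(_transport(a, b, D))


def emd(p: np.ndarray, q: np.ndarray, costs: np.ndarray) -> float:
    """EMD between two equal-mass distributions under a ground metric."""
    return transport_cost(p, q, costs)


_HAMMING: dict[int, np.ndarray] = {}


def hamming_matrix(n_bits: int) -> np.ndarray:
    """Pairwise Hamming distances between little-endian states on n_bits."""
    if n_bits not in _HAMMING:
        states = np.arange(2**n_bits)
        xor = states[:, None] ^ states[None, :]
        D = np.zeros_like(xor, dtype=np.float64)
        for b in range(n_bits):
            D += (xor >> b) & 1
        _HAMMING[n_bits] = D
    return _HAMMING[n_bits]


def hamming_emd(p: np.ndarray, q: np.ndarray) -> float:
    """EMD between distributions over binary states, Hamming ground metric."""
    n_states = len(p)
    n_bits = int(n_states).bit_length() - 1
    if 2**n_bits != n_states or len(q) != n_states:
        raise ValueError("distributions must have equal power-of-two length")
    return transport_cost(p, q, hamming_matrix(n_bits))
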